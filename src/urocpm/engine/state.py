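"""The mutable world object: lattice label field plus the cell table.

The cell table is stored as flat numpy arrays indexed by lattice label so the
compiled kernel can address them directly; :class:`CellRecord` is a
convenience snapshot of one row.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass

import numpy as np

from urocpm import constants as C
from urocpm.engine import kernel


class IntegrityError(RuntimeError):
    """Lattice and cell table disagree."""


@dataclass
class CellRecord:
    """Read-only snapshot of one biological cell."""

    id: int
    type: int
    actual_volume: int
    target_volume: float
    actual_surface: int
    target_surface: float
    age_days: float
    touches_bm: bool
    touches_medium: bool


class SimulationState:
    """Lattice label field + cell table + clock + kernel parameter arrays.

    Labels: 0 = medium, 1 = frozen basal membrane, >= 2 = cells.  The x axis
    is periodic, y is fixed.  Invariant: ``va[label]`` equals the label's
    pixel count at all times (checked by :meth:`check_integrity`).
    """

    _INITIAL_CAPACITY = 256

    def __init__(self, config, seed: int = 0):
        self.config = config
        lat = config.lattice
        self.width_px = lat.width_px
        self.height_px = lat.height_px
        self.px_per_um = lat.px_per_um
        self.bm_rows = lat.bm_rows

        self.labels = np.zeros((self.height_px, self.width_px), dtype=np.int64)
        self.labels[: self.bm_rows, :] = C.BM_LABEL

        cap = self._INITIAL_CAPACITY
        self.ctype = np.zeros(cap, dtype=np.int64)
        self.ctype[C.BM_LABEL] = C.BM
        self.alive = np.zeros(cap, dtype=bool)
        self.va = np.zeros(cap, dtype=np.int64)
        self.vt = np.zeros(cap, dtype=np.float64)
        self.sa = np.zeros(cap, dtype=np.int64)
        self.st = np.zeros(cap, dtype=np.float64)
        self.age = np.zeros(cap, dtype=np.float64)
        self.touch_m = np.zeros(cap, dtype=bool)
        self.touch_b = np.zeros(cap, dtype=bool)
        self.med_faces = np.zeros(cap, dtype=np.int64)
        self.next_label = C.FIRST_CELL_LABEL

        tp = config.type_params_arrays()
        self.lambda_volume = tp["lambda_volume"]
        self.lambda_surface = tp["lambda_surface"]
        self.v_min_px = tp["v_min_px"]
        self.v_max_px = tp["v_max_px"]
        self.growth_rate = tp["growth_rate"]
        self.apoptosis_chance = tp["apoptosis_chance"]
        self.jmat = config.contact_matrix()
        self.jmat_eff = config.engine.lambda_adhesion * self.jmat
        self.temperature = config.engine.temperature
        self.mcs_per_day = config.engine.mcs_per_day

        self.mcs_count = 0
        self.seed = seed
        self.rng = np.random.default_rng(seed)

    # ---- clock ----

    @property
    def time_days(self) -> float:
        return self.mcs_count / self.mcs_per_day

    # ---- cell table management ----

    @property
    def capacity(self) -> int:
        return self.ctype.shape[0]

    def _grow_tables(self, need: int) -> None:
        cap = self.capacity
        new_cap = cap
        while new_cap <= need:
            new_cap *= 2
        for name in ("ctype", "alive", "va", "vt", "sa", "st", "age", "touch_m", "touch_b", "med_faces"):
            arr = getattr(self, name)
            new = np.zeros(new_cap, dtype=arr.dtype)
            new[:cap] = arr
            setattr(self, name, new)

    def new_cell(self, cell_type: int, target_volume: float = 0.0) -> int:
        label = self.next_label
        self.next_label += 1
        if label >= self.capacity:
            self._grow_tables(label)
        self.ctype[label] = cell_type
        self.alive[label] = True
        self.va[label] = 0
        self.vt[label] = target_volume
        self.sa[label] = 0
        self.st[label] = self.config.target_surface_px(target_volume)
        self.age[label] = 0.0
        return label

    def remove_cell(self, label: int) -> None:
        """Remove a cell record; any remaining pixels become medium."""
        if self.va[label] > 0:
            self.labels[self.labels == label] = C.MEDIUM_LABEL
            self.va[label] = 0
        self.alive[label] = False
        self.ctype[label] = C.MEDIUM

    def cell_ids(self) -> np.ndarray:
        return np.flatnonzero(self.alive)

    def n_cells(self) -> int:
        return int(self.alive.sum())

    def cell(self, label: int) -> CellRecord:
        if not self.alive[label]:
            raise KeyError(f"no live cell with label {label}")
        return CellRecord(
            id=int(label),
            type=int(self.ctype[label]),
            actual_volume=int(self.va[label]),
            target_volume=float(self.vt[label]),
            actual_surface=int(self.sa[label]),
            target_surface=float(self.st[label]),
            age_days=float(self.age[label]),
            touches_bm=bool(self.touch_b[label]),
            touches_medium=bool(self.touch_m[label]),
        )

    def cells(self):
        return [self.cell(i) for i in self.cell_ids()]

    def counts_by_type(self) -> dict:
        out = {t: 0 for t in C.CELL_TYPES}
        ids = self.cell_ids()
        for t in C.CELL_TYPES:
            out[t] = int(np.count_nonzero(self.ctype[ids] == t))
        return out

    def set_type(self, label: int, cell_type: int) -> None:
        """Switch a cell's type.

        Energy weights switch with the type; the volume target is clamped
        into the new type's [Vmin, Vmax] (a differentiating cell assumes at
        least the adult minimum size of its new type), and the surface
        target follows the volume target.
        """
        self.ctype[label] = cell_type
        lo = self.v_min_px[cell_type]
        hi = self.v_max_px[cell_type]
        self.vt[label] = min(max(self.vt[label], lo), hi)
        self.st[label] = self.config.target_surface_px(self.vt[label])

    # ---- geometry refresh & integrity ----

    def refresh_geometry(self, prune: bool = True) -> None:
        """Recompute volumes, surfaces and contact flags from the lattice.

        With ``prune``, cells whose pixel count dropped to zero are removed
        from the table.
        """
        kernel.scan_geometry(self.labels, self.va, self.sa, self.touch_m, self.touch_b, self.med_faces)
        if prune:
            dead = np.flatnonzero(self.alive & (self.va == 0))
            for label in dead:
                self.alive[label] = False
                self.ctype[label] = C.MEDIUM

    def check_integrity(self) -> None:
        """Verify the cell-table/lattice invariants; raise IntegrityError."""
        va_scan = np.zeros_like(self.va)
        sa_scan = np.zeros_like(self.sa)
        tm = np.zeros_like(self.touch_m)
        tb = np.zeros_like(self.touch_b)
        mf = np.zeros_like(self.med_faces)
        kernel.scan_geometry(self.labels, va_scan, sa_scan, tm, tb, mf)
        if not np.array_equal(va_scan, np.where(self.alive, self.va, 0)):
            bad = np.flatnonzero(va_scan != np.where(self.alive, self.va, 0))
            raise IntegrityError(f"volume mismatch for labels {bad[:10].tolist()}")
        live = np.flatnonzero(self.alive)
        if not np.array_equal(sa_scan[live], self.sa[live]):
            raise IntegrityError("surface mismatch")
        field_labels = np.unique(self.labels)
        for lab in field_labels:
            if lab >= C.FIRST_CELL_LABEL and not self.alive[lab]:
                raise IntegrityError(f"orphan label {lab} on lattice")
        if (self.labels[: self.bm_rows, :] != C.BM_LABEL).any():
            raise IntegrityError("basal membrane region was modified")
        n_bm = int(np.count_nonzero(self.labels == C.BM_LABEL))
        n_med = int(np.count_nonzero(self.labels == C.MEDIUM_LABEL))
        if n_bm + n_med + int(self.va[live].sum()) != self.labels.size:
            raise IntegrityError("lattice is not partitioned by labels")

    # ---- pixel helpers ----

    def cell_pixels(self, label: int) -> np.ndarray:
        """(n, 2) array of (y, x) coordinates of the cell's pixels."""
        return np.argwhere(self.labels == label)

    def copy(self) -> "SimulationState":
        return _copy.deepcopy(self)
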