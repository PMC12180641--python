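"""Cell-level biology: the 16 lineage models and their processes.

A lineage model is a triple of building-block rules, one per proliferative
cell type:

* progenitor rule — ``SSD`` (strictly asymmetric, stem-cell manner) or
  ``SPA`` (population asymmetry: symmetric renewal / asymmetric / symmetric
  differentiation with probabilities p_sym / p_asym / 1 - p_sym - p_asym);
* basal rule — ``BPA`` (population asymmetry), ``BSD`` (asymmetric),
  ``BPCD`` (symmetric proliferation + differentiation on loss of basal-
  membrane contact), ``BCD`` (no division, contact-loss differentiation);
* intermediate rule — ``ICD`` (no division, differentiates into umbrella on
  medium contact) or ``IPCD`` (symmetric proliferation + the same contact
  differentiation).

Differentiation is strictly one-way along P -> B -> I -> U.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass

import numpy as np

from urocpm import constants as C
from urocpm.engine.state import SimulationState

PROGENITOR_RULES = ("SSD", "SPA")
BASAL_RULES = ("BPA", "BCD", "BPCD", "BSD")
INTERMEDIATE_RULES = ("ICD", "IPCD")


@dataclass(frozen=True)
class LineageModel:
    """Triple of building-block rule IDs, e.g. ``SPA/BPCD/ICD``."""

    progenitor_rule: str
    basal_rule: str
    intermediate_rule: str

    def __post_init__(self):
        if self.progenitor_rule not in PROGENITOR_RULES:
            raise ValueError(f"unknown progenitor rule {self.progenitor_rule!r}")
        if self.basal_rule not in BASAL_RULES:
            raise ValueError(f"unknown basal rule {self.basal_rule!r}")
        if self.intermediate_rule not in INTERMEDIATE_RULES:
            raise ValueError(f"unknown intermediate rule {self.intermediate_rule!r}")

    @classmethod
    def parse(cls, text: str) -> "LineageModel":
        parts = text.strip().upper().split("/")
        if len(parts) != 3:
            raise ValueError(f"lineage model must be 'P/B/I', got {text!r}")
        return cls(*parts)

    def __str__(self) -> str:
        return f"{self.progenitor_rule}/{self.basal_rule}/{self.intermediate_rule}"

    def proliferative_types(self) -> set:
        """Cell types that grow toward a division trigger under this model."""
        out = {C.PROGENITOR}
        if self.basal_rule != "BCD":
            out.add(C.BASAL)
        if self.intermediate_rule == "IPCD":
            out.add(C.INTERMEDIATE)
        return out

    def contact_differentiates_basal(self) -> bool:
        return self.basal_rule in ("BCD", "BPCD")


def all_models() -> list:
    """The 16 lineage models, in deterministic order."""
    return [
        LineageModel(p, b, i)
        for p, b, i in itertools.product(PROGENITOR_RULES, BASAL_RULES, INTERMEDIATE_RULES)
    ]


class DivisionKind(enum.Enum):
    SYMMETRIC_RENEWAL = "symmetric_renewal"
    ASYMMETRIC = "asymmetric"
    SYMMETRIC_DIFFERENTIATION = "symmetric_differentiation"
    DIFFERENTIATE_IN_PLACE = "differentiate_in_place"
    NONE = "none"


@dataclass(frozen=True)
class DivisionOutcome:
    kind: DivisionKind
    daughter_types: tuple  # () for NONE, (t,) for in-place, (t1, t2) otherwise

    def __post_init__(self):
        # daughters may only move forward along P -> B -> I -> U
        for t in self.daughter_types:
            if t not in C.CELL_TYPES:
                raise ValueError(f"invalid daughter type {t}")


_NO_DIVISION = DivisionOutcome(DivisionKind.NONE, ())


def decide_division(cell_type: int, model: LineageModel, lineage_cfg, rng: np.random.Generator) -> DivisionOutcome:
    """Division outcome for a cell that has reached its trigger volume."""
    ps = lineage_cfg.p_sym
    pa = lineage_cfg.p_asym
    if cell_type == C.PROGENITOR:
        if model.progenitor_rule == "SSD":
            return DivisionOutcome(DivisionKind.ASYMMETRIC, (C.PROGENITOR, C.BASAL))
        u = rng.random()
        if u < ps:
            return DivisionOutcome(DivisionKind.SYMMETRIC_RENEWAL, (C.PROGENITOR, C.PROGENITOR))
        if u < ps + pa:
            return DivisionOutcome(DivisionKind.ASYMMETRIC, (C.PROGENITOR, C.BASAL))
        return DivisionOutcome(DivisionKind.SYMMETRIC_DIFFERENTIATION, (C.BASAL, C.BASAL))
    if cell_type == C.BASAL:
        rule = model.basal_rule
        if rule == "BSD":
            return DivisionOutcome(DivisionKind.ASYMMETRIC, (C.BASAL, C.INTERMEDIATE))
        if rule == "BPA":
            u = rng.random()
            if u < ps:
                return DivisionOutcome(DivisionKind.SYMMETRIC_RENEWAL, (C.BASAL, C.BASAL))
            if u < ps + pa:
                return DivisionOutcome(DivisionKind.ASYMMETRIC, (C.BASAL, C.INTERMEDIATE))
            return DivisionOutcome(DivisionKind.SYMMETRIC_DIFFERENTIATION, (C.INTERMEDIATE, C.INTERMEDIATE))
        if rule == "BPCD":
            return DivisionOutcome(DivisionKind.SYMMETRIC_RENEWAL, (C.BASAL, C.BASAL))
        return _NO_DIVISION  # BCD: contact differentiation only
    if cell_type == C.INTERMEDIATE:
        if model.intermediate_rule == "IPCD":
            return DivisionOutcome(DivisionKind.SYMMETRIC_RENEWAL, (C.INTERMEDIATE, C.INTERMEDIATE))
        return _NO_DIVISION  # ICD
    raise ValueError(f"type {C.TYPE_NAMES.get(cell_type, cell_type)} has no division rule in any model")


# ---------------------------------------------------------------------------
# growth


def grow_cells(state: SimulationState, model: LineageModel, lineage_cfg, dt: float) -> None:
    """Advance target volumes by one growth increment.

    Proliferative cells (under the model's rules) gain
    ``growth_rate * Vmax * dt`` of target volume, multiplied by the contact-
    inhibition release factor when they are not completely surrounded (i.e.
    touch the medium).  Targets are capped at the division-trigger volume.
    Ages of all cells advance by ``dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    ids = state.cell_ids()
    if ids.size == 0:
        return
    state.age[ids] += dt
    types = state.ctype[ids]
    prolif = np.isin(types, list(model.proliferative_types()))
    if not prolif.any():
        return
    ids = ids[prolif]
    types = types[prolif]
    factor = np.where(state.touch_m[ids], lineage_cfg.contact_inhibition_factor, 1.0)
    vmax = state.v_max_px[types]
    new_vt = state.vt[ids] + state.growth_rate[types] * vmax * factor * dt
    state.vt[ids] = np.minimum(new_vt, vmax)
    scale = state.config.engine.surface_scale
    state.st[ids] = scale * 2.0 * np.sqrt(np.pi * state.vt[ids])


# ---------------------------------------------------------------------------
# mitosis mechanics


def _unwrapped_coords(pixels: np.ndarray, width: int) -> np.ndarray:
    """Pixel coordinates with x unwrapped across the periodic seam."""
    coords = pixels.astype(np.float64)
    xs = coords[:, 1]
    if xs.max() - xs.min() > width / 2:
        coords = coords.copy()
        coords[:, 1] = (xs + width / 2) % width
    return coords


def divide_cell(state: SimulationState, label: int, outcome: DivisionOutcome,
                rng: np.random.Generator, orientation: str = "principal"):
    """Split a cell through its centroid into two daughters.

    The dividing plane runs along the cell's shorter principal axis (so
    elongated cells are cut across their length); ``orientation="random"``
    draws a random plane instead.  The parent label is reused for one
    daughter.  For asymmetric outcomes the stem-like daughter type is given
    to the half whose centroid lies nearer the basal membrane.

    Returns ``(kept_label, new_label)`` or ``None`` when the cell is too
    small to split (division deferred).
    """
    if len(outcome.daughter_types) != 2:
        raise ValueError("divide_cell needs a two-daughter outcome")
    pixels = state.cell_pixels(label)
    if pixels.shape[0] < 2:
        return None
    coords = _unwrapped_coords(pixels, state.width_px)
    centred = coords - coords.mean(axis=0)
    if orientation == "random":
        theta = rng.random() * np.pi
        axis = np.array([np.sin(theta), np.cos(theta)])
    else:
        cov = np.cov(centred.T) if centred.shape[0] > 1 else np.eye(2)
        evals, evecs = np.linalg.eigh(cov)
        axis = evecs[:, int(np.argmax(evals))]  # long axis; plane is normal to it
    proj = centred @ axis
    order = np.argsort(proj, kind="stable")
    half = pixels.shape[0] // 2
    set_a = pixels[order[:half]]
    set_b = pixels[order[half:]]

    t1, t2 = outcome.daughter_types
    if outcome.kind == DivisionKind.ASYMMETRIC and t1 != t2:
        # stem daughter (t1, the earlier type on the path) sits nearer the BM
        if set_a[:, 0].mean() > set_b[:, 0].mean():
            set_a, set_b = set_b, set_a
    parent_va = pixels.shape[0]
    new_label = state.new_cell(t2, target_volume=parent_va / 2.0)
    state.labels[set_b[:, 0], set_b[:, 1]] = new_label
    state.va[new_label] = set_b.shape[0]
    state.va[label] = set_a.shape[0]
    state.set_type(label, t1)
    state.vt[label] = parent_va / 2.0
    state.st[label] = state.config.target_surface_px(state.vt[label])
    state.age[label] = 0.0
    return label, new_label


# ---------------------------------------------------------------------------
# contact-driven differentiation


def contact_differentiate(state: SimulationState, model: LineageModel,
                          medium_contact_faces: int = 1) -> int:
    """Apply the model's contact rules; returns the number of switched cells.

    Under BCD/BPCD a basal cell that lost basal-membrane contact becomes
    intermediate; under ICD/IPCD an intermediate cell in contact with the
    medium becomes umbrella.  ``medium_contact_faces`` sets how many medium
    faces count as contact (a single pinhole face during lattice churn is
    noise, not exposure to the lumen).  Requires fresh contact flags.
    """
    ids = state.cell_ids()
    changed = 0
    if model.contact_differentiates_basal():
        basal = ids[(state.ctype[ids] == C.BASAL) & ~state.touch_b[ids]]
        for lab in basal:
            state.set_type(lab, C.INTERMEDIATE)
        changed += basal.size
    inter = ids[
        (state.ctype[ids] == C.INTERMEDIATE)
        & (state.med_faces[ids] >= medium_contact_faces)
    ]
    for lab in inter:
        state.set_type(lab, C.UMBRELLA)
    changed += inter.size
    return changed


# ---------------------------------------------------------------------------
# death processes


def apoptosis_step(state: SimulationState, rng: np.random.Generator, dt: float) -> int:
    """Each cell dies with probability apoptosis_chance(type) * dt."""
    ids = state.cell_ids()
    if ids.size == 0:
        return 0
    p = state.apoptosis_chance[state.ctype[ids]] * dt
    doomed = ids[rng.random(ids.size) < p]
    for lab in doomed:
        state.remove_cell(lab)
    return int(doomed.size)


def voiding_event(state: SimulationState, rng: np.random.Generator, washout_p: float = 0.02) -> int:
    """Bladder voiding: every cell touching the medium (any type) is washed
    out independently with probability ``washout_p``."""
    ids = state.cell_ids()
    apical = ids[state.touch_m[ids]]
    if apical.size == 0:
        return 0
    removed = apical[rng.random(apical.size) < washout_p]
    for lab in removed:
        state.remove_cell(lab)
    return int(removed.size)


# ---------------------------------------------------------------------------
# the per-MCS biology hook


class LineageStepper:
    """Schedules the biological processes around the lattice dynamics.

    Per MCS (in this order): growth -> divisions -> contact differentiation;
    every voiding interval (default 6 h): apoptosis, then voiding.
    """

    def __init__(self, model: LineageModel, config, rng: np.random.Generator):
        self.model = model
        self.config = config
        self.rng = rng
        self.lineage_cfg = config.lineage
        mcs_per_day = config.engine.mcs_per_day
        self.voiding_interval_mcs = max(
            1, int(round(mcs_per_day * self.lineage_cfg.voiding_interval_hours / 24.0))
        )
        self.differentiation_interval_mcs = max(
            1,
            int(round(mcs_per_day * self.lineage_cfg.differentiation_interval_hours / 24.0)),
        )
        self.n_divisions = 0
        self.n_apoptoses = 0
        self.n_washed_out = 0

    def step(self, state: SimulationState) -> None:
        dt = 1.0 / state.mcs_per_day
        grow_cells(state, self.model, self.lineage_cfg, dt)
        divided = self._division_sweep(state)
        if divided:
            state.refresh_geometry(prune=True)
        if state.mcs_count % self.differentiation_interval_mcs == 0:
            contact_differentiate(
                state, self.model, self.lineage_cfg.medium_contact_faces
            )
        if state.mcs_count % self.voiding_interval_mcs == 0:
            interval_days = self.voiding_interval_mcs / state.mcs_per_day
            self.n_apoptoses += apoptosis_step(state, self.rng, interval_days)
            self.n_washed_out += voiding_event(
                state, self.rng, self.lineage_cfg.voiding_washout_p
            )

    def _division_sweep(self, state: SimulationState) -> int:
        prolif = self.model.proliferative_types()
        ids = state.cell_ids()
        mask = np.isin(state.ctype[ids], list(prolif))
        ids = ids[mask]
        trigger = self.lineage_cfg.division_trigger_ratio * state.v_max_px[state.ctype[ids]]
        ready = ids[state.va[ids] >= trigger]
        divided = 0
        for lab in ready:
            outcome = decide_division(int(state.ctype[lab]), self.model, self.lineage_cfg, self.rng)
            if outcome.kind == DivisionKind.NONE:
                continue
            result = divide_cell(
                state, int(lab), outcome, self.rng,
                orientation=self.lineage_cfg.division_orientation,
            )
            if result is not None:
                divided += 1
        self.n_divisions += divided
        return divided
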