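"""Arrangement, volume and total fitness of a tissue snapshot.

The arrangement score inspects the stacking of cells in regularly spaced
vertical sampling windows; the volume score compares per-group summed cell
volumes with targets derived from the reference tissue thickness; the total
fitness is their pointwise mean, time-averaged over a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from urocpm import constants as C
from urocpm.engine import kernel


@dataclass
class ColumnLayerProfile:
    """Bottom-to-top stack of cell layers in one sampling window.

    One layer = one maximal run of rows dominated by the same cell; the
    medium terminates the scan at the free surface, the basal membrane is
    excluded.  ``layer_types`` therefore lists one entry per stacked cell
    (e.g. ``[B, I, I, I, U]`` for a five-cell column).
    """

    layer_labels: list = field(default_factory=list)
    layer_types: list = field(default_factory=list)

    @property
    def layer_count(self) -> int:
        return len(self.layer_types)

    @property
    def collapsed_types(self) -> list:
        """Type sequence with consecutive duplicates merged (e.g. [B, I, U])."""
        out = []
        for t in self.layer_types:
            if not out or out[-1] != t:
                out.append(t)
        return out


def _window_geometry(state, fitness_cfg):
    """Sampling-window starts (px), window width (px) and first tissue row."""
    spacing_px = fitness_cfg.column_spacing_um * state.px_per_um
    width_um = state.width_px / state.px_per_um
    n_samples = int(round(width_um / fitness_cfg.column_spacing_um)) - 1
    if n_samples < 1:
        raise ValueError("lattice too narrow for the configured column spacing")
    win = int(round(spacing_px))
    centers = (np.arange(1, n_samples + 1) * spacing_px).round().astype(np.int64)
    starts = (centers - win // 2) % state.width_px
    return starts, win, state.bm_rows


def _profile_from_modes(mode_column: np.ndarray, ctype: np.ndarray,
                        min_rows: int = 2) -> ColumnLayerProfile:
    rows = []
    for lab in mode_column:
        if lab == C.MEDIUM_LABEL:
            break
        if lab == C.BM_LABEL:
            continue
        rows.append(int(lab))
    runs = []  # (label, n_rows)
    for lab in rows:
        if runs and runs[-1][0] == lab:
            runs[-1][1] += 1
        else:
            runs.append([lab, 1])
    # drop sub-threshold blips (wiggly cell boundaries flip the per-row
    # majority back and forth; a single stray row is not a layer), merging
    # equal-label neighbours that become adjacent
    while len(runs) > 1:
        shortest = min(range(len(runs)), key=lambda i: runs[i][1])
        if runs[shortest][1] >= min_rows:
            break
        del runs[shortest]
        i = max(shortest - 1, 0)
        while i + 1 < len(runs):
            if runs[i][0] == runs[i + 1][0]:
                runs[i][1] += runs[i + 1][1]
                del runs[i + 1]
            else:
                i += 1
    prof = ColumnLayerProfile()
    for lab, _ in runs:
        prof.layer_labels.append(lab)
        prof.layer_types.append(int(ctype[lab]))
    return prof


def column_profiles(state, fitness_cfg) -> list:
    """Profiles of all sampling windows across the lattice."""
    starts, win, y0 = _window_geometry(state, fitness_cfg)
    modes = kernel.column_modes(state.labels, starts, win, y0)
    mr = getattr(fitness_cfg, "min_layer_rows", 2)
    return [
        _profile_from_modes(modes[i], state.ctype, mr) for i in range(modes.shape[0])
    ]


def column_profile(state, x_start: int, fitness_cfg) -> ColumnLayerProfile:
    """Profile of a single window starting at pixel column ``x_start``."""
    win = int(round(fitness_cfg.column_spacing_um * state.px_per_um))
    starts = np.array([x_start % state.width_px], dtype=np.int64)
    modes = kernel.column_modes(state.labels, starts, win, state.bm_rows)
    return _profile_from_modes(modes[0], state.ctype, getattr(fitness_cfg, "min_layer_rows", 2))


def arrangement_fitness_column(profile: ColumnLayerProfile, fitness_cfg=None) -> float:
    """Single-column arrangement score fa* in [0, 1].

    fa* = 1 - (EB + EU + Elib + Eopt) / 4 for non-empty columns, else 0:
    EB penalises a first layer that is not basal/progenitor, EU a last layer
    that is not umbrella, Elib the fraction of in-between layers that are
    not intermediate, and Eopt a stack height outside 3..7 cells.
    """
    n = profile.layer_count
    if n == 0:
        return 0.0
    lo = fitness_cfg.eopt_min_layers if fitness_cfg else 3
    hi = fitness_cfg.eopt_max_layers if fitness_cfg else 7
    elib_mode = fitness_cfg.elib_mode if fitness_cfg else "strict"
    types = profile.layer_types
    e_b = 0.0 if types[0] in (C.BASAL, C.PROGENITOR) else 1.0
    e_u = 0.0 if types[-1] == C.UMBRELLA else 1.0
    between = types[1:-1]
    if between:
        if elib_mode == "all":
            e_lib = len(between) / n
        else:
            e_lib = sum(1 for t in between if t != C.INTERMEDIATE) / len(between)
    else:
        e_lib = 0.0
    e_opt = 0.0 if lo <= n <= hi else 1.0
    return 1.0 - (e_b + e_u + e_lib + e_opt) / 4.0


def arrangement_fitness(state, fitness_cfg) -> float:
    """Mean fa* over the sampling windows (31 on the default 800 um lattice)."""
    profiles = column_profiles(state, fitness_cfg)
    return float(np.mean([arrangement_fitness_column(p, fitness_cfg) for p in profiles]))


def n_arrangement_samples(state, fitness_cfg) -> int:
    starts, _, _ = _window_geometry(state, fitness_cfg)
    return int(starts.shape[0])


def _windows_umbrella_topped(state, fitness_cfg) -> np.ndarray:
    """Per sampling window: is the majority of topmost cells umbrella?

    Works pixel-column-wise (topmost non-medium, non-BM pixel per column) so
    a thin but contiguous umbrella sheet counts as cover.
    """
    starts, win, y0 = _window_geometry(state, fitness_cfg)
    region = state.labels[y0:, :]
    mask = region >= C.FIRST_CELL_LABEL
    has_cell = mask.any(axis=0)
    top_idx = region.shape[0] - 1 - np.argmax(mask[::-1, :], axis=0)
    top_type = state.ctype[region[top_idx, np.arange(region.shape[1])]]
    col_is_u = has_cell & (top_type == C.UMBRELLA)
    out = np.empty(starts.shape[0], dtype=bool)
    for i, x0 in enumerate(starts):
        cols = (x0 + np.arange(win)) % state.width_px
        out[i] = col_is_u[cols].sum() * 2 > win
    return out


def surface_coverage(state, fitness_cfg) -> float:
    """Fraction of sampling windows whose topmost cells are umbrella."""
    return float(np.mean(_windows_umbrella_topped(state, fitness_cfg)))


def group_volume_targets(state, fitness_cfg) -> dict:
    """Target pixel volumes per group {(P,B), I, U} from the reference
    thickness and relative fractions."""
    total = state.width_px * fitness_cfg.thickness_um * state.px_per_um
    return {
        "basal": total * fitness_cfg.fraction_basal,
        "intermediate": total * fitness_cfg.fraction_intermediate,
        "umbrella": total * fitness_cfg.fraction_umbrella,
    }


def volume_fitness(state, fitness_cfg) -> float:
    """Mean over groups of 1 / (4 * r^2 + 1), r the relative volume deviation."""
    targets = group_volume_targets(state, fitness_cfg)
    ids = state.cell_ids()
    types = state.ctype[ids]
    vols = state.va[ids]
    actual = {
        "basal": float(vols[(types == C.PROGENITOR) | (types == C.BASAL)].sum()),
        "intermediate": float(vols[types == C.INTERMEDIATE].sum()),
        "umbrella": float(vols[types == C.UMBRELLA].sum()),
    }
    scores = []
    for group, target in targets.items():
        if target <= 0:
            raise ValueError(f"zero target volume for group {group}")
        r = (target - actual[group]) / target
        scores.append(1.0 / (4.0 * r * r + 1.0))
    return float(np.mean(scores))


def total_fitness(fa: float, fv: float) -> float:
    """Pointwise total fitness: the mean of arrangement and volume scores."""
    return 0.5 * (fa + fv)


def score_state(state, fitness_cfg) -> dict:
    """One-pass snapshot scoring: fa, fv, f and umbrella surface coverage."""
    profiles = column_profiles(state, fitness_cfg)
    fa = float(np.mean([arrangement_fitness_column(p, fitness_cfg) for p in profiles]))
    covered = bool(_windows_umbrella_topped(state, fitness_cfg).all())
    fv = volume_fitness(state, fitness_cfg)
    return {"fa": fa, "fv": fv, "f": total_fitness(fa, fv), "covered": covered}


@dataclass
class FitnessSeries:
    """Per-time-point fitness samples plus the run-level time average."""

    times: np.ndarray
    fa: np.ndarray
    fv: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.fa = np.asarray(self.fa, dtype=float)
        self.fv = np.asarray(self.fv, dtype=float)
        if not (len(self.times) == len(self.fa) == len(self.fv)):
            raise ValueError("times, fa and fv must have equal length")

    @property
    def f(self) -> np.ndarray:
        return 0.5 * (self.fa + self.fv)

    @property
    def f_mean(self) -> float:
        return time_average(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.times, "fA": self.fa, "fV": self.fv, "f": self.f})


def time_average(series: FitnessSeries) -> float:
    """Unweighted mean of the total fitness over all sampled time points."""
    if len(series.times) == 0:
        raise ValueError("empty fitness series")
    return float(np.mean(series.f))
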