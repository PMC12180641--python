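"""Synthetic lattices and time series with known ground truth.

These generators let the fitness and classification code be exercised (and
scored end-to-end through the CLI) without running the simulator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from urocpm import classify as CL
from urocpm import constants as C
from urocpm.config import Config, default_config
from urocpm.engine.state import SimulationState


def _resolve_type(t) -> int:
    if isinstance(t, str):
        return C.TYPE_CODES[t.lower()]
    return int(t)


def make_layered_lattice(bands, config: Config | None = None) -> SimulationState:
    """Build a lattice of horizontal bands of cells above the basal membrane.

    ``bands`` is a bottom-to-top list of ``(type, n_cells, total_pixels)``.
    Pixels are assigned in scan order (row by row, bottom to top), so each
    cell occupies full rows plus at most two partial rows; every cell with at
    least one full row shows up as one layer in every sampling column.
    """
    config = config or default_config()
    state = SimulationState(config)
    w = state.width_px
    h = state.height_px
    y0 = state.bm_rows
    flat = state.labels[y0:].reshape(-1)  # scan order above the BM
    pos = 0
    for type_spec, n_cells, total_px in bands:
        code = _resolve_type(type_spec)
        base = total_px // n_cells
        rem = total_px - base * n_cells
        for i in range(n_cells):
            size = base + (1 if i < rem else 0)
            if pos + size > flat.size:
                raise ValueError("bands exceed lattice capacity")
            label = state.new_cell(code, target_volume=float(size))
            flat[pos : pos + size] = label
            pos += size
    state.refresh_geometry(prune=False)
    return state


def ideal_tissue_state(config: Config | None = None, n_intermediate_layers: int = 4) -> SimulationState:
    """A tissue whose group volumes exactly match the configured targets and
    whose columns stack basal -> intermediate layers -> umbrella."""
    config = config or default_config()
    state_probe = SimulationState(config)
    total = state_probe.width_px * config.fitness.thickness_um * config.lattice.px_per_um
    fr = config.fitness
    pix_b = int(round(total * fr.fraction_basal))
    pix_i = int(round(total * fr.fraction_intermediate))
    pix_u = int(round(total * fr.fraction_umbrella))
    bands = [
        (C.BASAL, 1, pix_b),
        (C.INTERMEDIATE, n_intermediate_layers, pix_i),
        (C.UMBRELLA, 1, pix_u),
    ]
    return make_layered_lattice(bands, config)


def striped_state(ideal_windows, config: Config | None = None,
                  n_intermediate_layers: int = 4) -> SimulationState:
    """Ideal cell stacks in the given sampling windows, medium elsewhere.

    Window ``k`` (1-based) covers the pixel columns of the k-th arrangement
    sampling window; listed windows receive a full stack (one basal, several
    intermediate, one umbrella cell), all other windows stay empty.
    """
    config = config or default_config()
    state = SimulationState(config)
    spacing_px = int(round(config.fitness.column_spacing_um * config.lattice.px_per_um))
    y0 = state.bm_rows
    heights = [6] + [8] * n_intermediate_layers + [6]
    types = [C.BASAL] + [C.INTERMEDIATE] * n_intermediate_layers + [C.UMBRELLA]
    for k in ideal_windows:
        x_lo = k * spacing_px - spacing_px // 2
        cols = (x_lo + np.arange(spacing_px)) % state.width_px
        y = y0
        for t, hh in zip(types, heights):
            label = state.new_cell(t, target_volume=float(hh * spacing_px))
            state.labels[np.ix_(np.arange(y, y + hh), cols)] = label
            y += hh
    state.refresh_geometry(prune=False)
    return state


def make_count_series(kind: str, params: dict | None = None, noise: float = 0.0,
                      rng: np.random.Generator | None = None,
                      days: float = 720.0, interval: float = 0.5):
    """Cell-count time series with a named trend and its expected label.

    Kinds: ``constant``, ``linear``, ``exponential``, ``collapse``.  Returns
    ``(DataFrame, expected_label)``; the frame has columns day, n_P, n_B,
    n_I, n_U, total_cells.
    """
    params = dict(params or {})
    rng = rng or np.random.default_rng(0)
    t = np.arange(0.0, days + 1e-9, interval)
    base = float(params.get("base", 600.0))
    if kind == "constant":
        n = np.full_like(t, base)
        expected = CL.STABLE
    elif kind == "linear":
        slope = float(params.get("slope", 2.0))  # cells per day
        n = base + slope * t
        expected = CL.LINEAR_GROWTH
    elif kind == "exponential":
        rate = float(params.get("rate", 0.005))  # per day
        n = base * np.exp(rate * t)
        expected = CL.EXPONENTIAL_GROWTH
    elif kind == "collapse":
        t_collapse = float(params.get("collapse_day", 400.0))
        tail = np.maximum(0.0, 1.0 - (t - t_collapse) / float(params.get("decay_days", 150.0)))
        n = np.where(t < t_collapse, base, base * tail)
        expected = CL.ATROPHY
    else:
        raise ValueError(f"unknown series kind {kind!r}")
    if noise > 0:
        n = n * (1.0 + noise * rng.standard_normal(t.size))
        n = np.maximum(n, 0.0)
    n = np.round(n)
    n_p = np.where(n > 0, np.maximum(1, np.round(0.02 * n)), 0)
    if kind == "collapse":
        n_p = np.where(t < float(params.get("collapse_day", 400.0)), n_p, 0)
    n_u = np.round(0.08 * n)
    n_b = np.round(0.15 * n)
    n_i = np.maximum(n - n_p - n_u - n_b, 0)
    df = pd.DataFrame(
        {
            "day": t,
            "n_P": n_p.astype(int),
            "n_B": n_b.astype(int),
            "n_I": n_i.astype(int),
            "n_U": n_u.astype(int),
            "total_cells": n.astype(int),
        }
    )
    return df, expected
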