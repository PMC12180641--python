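"""Initial condition: a damaged urothelium — bare basal membrane with a
sparse scattering of progenitor cells (the wound-healing scenario)."""

from __future__ import annotations

import numpy as np

from urocpm import constants as C
from urocpm.engine.state import SimulationState


class PlacementError(RuntimeError):
    """Progenitor placement could not satisfy the requested coverage."""


def build_initial_state(config, seed: int = 0) -> SimulationState:
    """Build the wound-healing initial state.

    The basal membrane spans the full width at the bottom of the lattice;
    progenitor cells of minimal viable size are placed at uniformly random,
    non-overlapping positions directly on the membrane so that roughly
    ``init.progenitor_fraction`` of the columns are covered.  Everything
    else is medium.  Same seed => bit-identical state.
    """
    state = SimulationState(config, seed=seed)
    rng = np.random.default_rng(seed)
    icfg = config.init
    w = state.width_px
    cw = icfg.cell_width_px
    ch = icfg.cell_height_px
    n_cells = int(round(icfg.progenitor_fraction * w / cw))
    if n_cells == 0:
        return state
    if n_cells * cw > w:
        raise PlacementError(
            f"progenitor fraction {icfg.progenitor_fraction} cannot be placed "
            f"with cell width {cw} on a {w}-px lattice"
        )

    occupied = np.zeros(w, dtype=bool)
    starts = []
    for _ in range(n_cells):
        placed = False
        for _ in range(icfg.max_retries):
            x0 = int(rng.integers(0, w))
            cols = (x0 + np.arange(cw)) % w
            if not occupied[cols].any():
                occupied[cols] = True
                starts.append(x0)
                placed = True
                break
        if not placed:
            raise PlacementError("could not place all progenitor cells (bounded retries exceeded)")

    y0 = state.bm_rows
    for x0 in starts:
        cols = (x0 + np.arange(cw)) % w
        label = state.new_cell(C.PROGENITOR, target_volume=float(cw * ch))
        state.labels[y0 : y0 + ch, cols] = label
    state.refresh_geometry(prune=False)
    return state
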