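import numpy as np
import pytest

from urocpm import constants as C
from urocpm.config import default_config
from urocpm.engine.state import SimulationState


@pytest.fixture(scope="session")
def default_cfg():
    return default_config()


def small_config(width_um=40.0, height_um=20.0, **engine_overrides):
    """A small-lattice config (default 32x16 px) with packaged defaults."""
    cfg = default_config()
    cfg.lattice.width_um = width_um
    cfg.lattice.height_um = height_um
    for key, val in engine_overrides.items():
        setattr(cfg.engine, key, val)
    return cfg


@pytest.fixture
def small_cfg():
    return small_config()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def paint_cell(state: SimulationState, cell_type, y0, y1, x0, x1, target_volume=None):
    """Create a rectangular cell on the lattice (helper for hand-built states)."""
    size = (y1 - y0) * (x1 - x0)
    label = state.new_cell(cell_type, target_volume=float(target_volume if target_volume is not None else size))
    state.labels[y0:y1, x0:x1] = label
    return label


def zero_contact_energies(cfg):
    cfg.contact_energies = {k: 0.0 for k in cfg.contact_energies}
    return cfg


@pytest.fixture
def blob_state(small_cfg, rng):
    """A 32x16 state with four irregular cells for energy-oracle tests."""
    state = SimulationState(small_cfg, seed=7)
    h, w = state.labels.shape
    seeds = [(5, 4, C.PROGENITOR), (6, 12, C.BASAL), (10, 20, C.INTERMEDIATE), (8, 28, C.UMBRELLA)]
    labels = []
    for sy, sx, t in seeds:
        labels.append(state.new_cell(t, target_volume=30.0))
    yy, xx = np.mgrid[0:h, 0:w]
    best = np.full((h, w), -1)
    bestd = np.full((h, w), np.inf)
    for (sy, sx, _), lab in zip(seeds, labels):
        dx = np.minimum(np.abs(xx - sx), w - np.abs(xx - sx))
        d = (yy - sy) ** 2 + dx**2 + rng.normal(0, 2, size=(h, w))
        closer = d < bestd
        best[closer] = lab
        bestd[closer] = d[closer]
    mask = (bestd < 30) & (yy >= state.bm_rows)
    state.labels[mask] = best[mask]
    state.refresh_geometry(prune=False)
    return state
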