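"""Calibration aid for the Metropolis temperature.

Places one isolated cell of each type at its target volume on a small
lattice and measures, over a range of temperatures, the relative volume
fluctuation and whether the cell stays in one connected piece.  The default
temperature is chosen so volumes fluctuate a few percent around the target
without fragmentation.

Usage: python scripts/calibrate_temperature.py [--mcs 2000]
"""

import argparse

import numpy as np

from urocpm import constants as C
from urocpm.config import default_config
from urocpm.engine import run_mcs, scheduler
from urocpm.engine.state import SimulationState


def largest_component_fraction(labels, label):
    from scipy import ndimage

    mask = labels == label
    comp, n = ndimage.label(mask)
    if n == 0:
        return 0.0
    sizes = ndimage.sum_labels(mask, comp, index=range(1, n + 1))
    return float(np.max(sizes) / np.sum(sizes))


def measure(temperature, mcs, type_name, type_code):
    cfg = default_config()
    cfg.lattice.width_um = 50.0
    cfg.lattice.height_um = 50.0
    cfg.engine.temperature = temperature
    state = SimulationState(cfg, seed=0)
    vt = state.v_max_px[type_code]
    side = max(2, int(round(np.sqrt(vt))))
    label = state.new_cell(type_code, target_volume=vt)
    state.labels[10 : 10 + side, 10 : 10 + side] = label
    state.refresh_geometry(prune=False)
    scheduler.seed_attempt_stream(hash((type_name, temperature)) % 2**31)
    volumes = []
    for i in range(mcs):
        run_mcs(state)
        if i >= mcs // 2:
            volumes.append(state.va[label])
    volumes = np.array(volumes, dtype=float)
    rel_fluct = volumes.std() / vt
    rel_offset = (volumes.mean() - vt) / vt
    coherence = largest_component_fraction(state.labels, label)
    return rel_fluct, rel_offset, coherence


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--mcs", type=int, default=2000)
    ap.add_argument("--temperatures", type=float, nargs="*",
                    default=[5.0, 10.0, 15.0, 22.0, 30.0, 40.0, 60.0])
    args = ap.parse_args()
    print(f"{'type':>14} {'T':>6} {'fluct%':>8} {'offset%':>8} {'coherence':>10}")
    for type_name, code in [("progenitor", C.PROGENITOR), ("intermediate", C.INTERMEDIATE)]:
        for temp in args.temperatures:
            fl, off, coh = measure(temp, args.mcs, type_name, code)
            print(f"{type_name:>14} {temp:>6.1f} {100*fl:>8.2f} {100*off:>8.2f} {coh:>10.3f}")


if __name__ == "__main__":
    main()
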