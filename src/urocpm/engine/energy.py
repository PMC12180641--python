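"""Effective-energy evaluation and single copy attempts (reference path).

``total_energy`` is the brute-force evaluation used as the oracle for the
incremental ``delta_energy`` that the compiled kernel applies millions of
times per simulated day.
"""

from __future__ import annotations

import math

import numpy as np

from urocpm import constants as C
from urocpm.engine import kernel
from urocpm.engine.state import SimulationState


def volume_energy(state: SimulationState) -> float:
    ids = state.cell_ids()
    dv = state.va[ids] - state.vt[ids]
    return float(np.sum(state.lambda_volume[state.ctype[ids]] * dv * dv))


def surface_energy(state: SimulationState) -> float:
    ids = state.cell_ids()
    ds = state.sa[ids] - state.st[ids]
    return float(np.sum(state.lambda_surface[state.ctype[ids]] * ds * ds))


def adhesion_energy(state: SimulationState) -> float:
    """Contact energy summed over unordered heterolabel neighbour pairs
    (without the lambda_A weight)."""
    return float(kernel.adhesion_total(state.labels, state.ctype, state.jmat))


def total_energy(state: SimulationState, check: bool = False) -> float:
    """E = EV + ES + lambda_A * EA.

    With ``check``, first verify that recorded volumes match pixel counts.
    """
    if check:
        state.check_integrity()
    lam_a = state.config.engine.lambda_adhesion
    return volume_energy(state) + surface_energy(state) + lam_a * adhesion_energy(state)


def _assert_adjacent(state: SimulationState, pixel, invading_label: int) -> None:
    y, x = pixel
    h, w = state.labels.shape
    for dy, dx in C.MOORE_OFFSETS:
        ny = y + dy
        if ny < 0 or ny >= h:
            continue
        nx = (x + dx) % w
        if state.labels[ny, nx] == invading_label:
            return
    raise ValueError(f"label {invading_label} is not a Moore neighbour of pixel {tuple(pixel)}")


def delta_energy(state: SimulationState, pixel, invading_label: int) -> float:
    """Incremental energy change of overwriting ``pixel`` with ``invading_label``."""
    _assert_adjacent(state, pixel, invading_label)
    y, x = pixel
    t = int(state.labels[y, x])
    d_e, _, _ = kernel.copy_delta(
        state.labels, state.ctype, state.va, state.vt, state.sa, state.st,
        state.lambda_volume, state.lambda_surface, state.jmat_eff,
        y, x, int(invading_label), t,
    )
    return float(d_e)


def apply_copy(state: SimulationState, pixel, invading_label: int) -> None:
    """Overwrite ``pixel`` with ``invading_label`` and update the cell table."""
    y, x = pixel
    t = int(state.labels[y, x])
    s = int(invading_label)
    if s == t:
        return
    _, d_s_s, d_s_t = kernel.copy_delta(
        state.labels, state.ctype, state.va, state.vt, state.sa, state.st,
        state.lambda_volume, state.lambda_surface, state.jmat_eff,
        y, x, s, t,
    )
    state.labels[y, x] = s
    if s >= C.FIRST_CELL_LABEL:
        state.va[s] += 1
        state.sa[s] += d_s_s
    if t >= C.FIRST_CELL_LABEL:
        state.va[t] -= 1
        state.sa[t] += d_s_t


def metropolis_probability(d_e: float, temperature: float) -> float:
    """min(1, exp(-dE/T)); ties (dE = 0) are accepted with probability 1."""
    if d_e <= 0.0:
        return 1.0
    return math.exp(-d_e / temperature)


def attempt_copy(state: SimulationState, rng: np.random.Generator) -> bool:
    """One Metropolis copy attempt (pure-python reference of the kernel step).

    Picks a uniform source pixel and a uniform Moore neighbour target, and
    proposes overwriting the target with the source label.  Degenerate
    proposals (same label, frozen BM, target off the fixed y boundary) are
    consumed as rejections.
    """
    h, w = state.labels.shape
    x = int(rng.random() * w)
    y = int(rng.random() * h)
    k = int(rng.random() * 8)
    dy, dx = C.MOORE_OFFSETS[k]
    ty = y + dy
    if ty < 0 or ty >= h:
        return False
    tx = (x + dx) % w
    s = int(state.labels[y, x])
    t = int(state.labels[ty, tx])
    if s == t or s == C.BM_LABEL or t == C.BM_LABEL:
        return False
    d_e = delta_energy(state, (ty, tx), s)
    if d_e <= 0.0 or rng.random() < math.exp(-d_e / state.temperature):
        apply_copy(state, (ty, tx), s)
        return True
    return False
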