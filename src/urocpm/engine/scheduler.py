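"""Monte-Carlo-step scheduler.

One MCS = as many copy attempts as there are lattice sites, followed by a
geometry refresh and (optionally) the biology hook supplied by the caller —
growth, division, differentiation, apoptosis and voiding live in
``urocpm.lineage`` and are wired in through :class:`urocpm.simulation.Simulation`.
"""

from __future__ import annotations

from urocpm.engine import kernel
from urocpm.engine.state import SimulationState

_kernel_seeded_for = None


def seed_attempt_stream(seed: int) -> None:
    """Seed the compiled kernel's private PRNG (one stream per run)."""
    global _kernel_seeded_for
    kernel.seed_kernel(seed)
    _kernel_seeded_for = seed


def run_mcs(state: SimulationState, biology=None) -> SimulationState:
    """Advance the state by one Monte-Carlo step (in place).

    Performs width*height copy attempts, refreshes the cell table and
    advances the clock by 1/mcs_per_day days.  If ``biology`` is given, its
    ``step(state)`` is invoked after the attempts (it sees fresh contact
    flags and the advanced clock).
    """
    n_attempts = state.width_px * state.height_px
    kernel.run_attempts(
        state.labels, state.ctype, state.va, state.vt, state.sa, state.st,
        state.lambda_volume, state.lambda_surface, state.jmat_eff,
        state.temperature, n_attempts,
    )
    state.refresh_geometry(prune=True)
    state.mcs_count += 1
    if biology is not None:
        biology.step(state)
    return state


def run_days(state: SimulationState, days: float, biology=None) -> SimulationState:
    n_steps = int(round(days * state.mcs_per_day))
    for _ in range(n_steps):
        run_mcs(state, biology=biology)
    return state
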