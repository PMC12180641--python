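"""Single-run driver: couples the lattice engine, the lineage biology and
the fitness sampler, and records the run's time series."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from urocpm import constants as C
from urocpm import fitness as F
from urocpm.config import Config
from urocpm.engine import scheduler
from urocpm.init import build_initial_state
from urocpm.lineage import LineageModel, LineageStepper


def _sub_seed(seed: int, key: int) -> int:
    return int(np.random.SeedSequence([int(seed), key]).generate_state(1)[0])


class Simulation:
    """One seeded simulation run of one lineage model.

    Uses three independent random streams derived from the run seed: initial
    placement, the compiled copy-attempt kernel, and the biology (divisions,
    apoptosis, voiding).  Same (config, model, seed) => identical run.
    """

    def __init__(self, config: Config, model, seed: int = 0):
        if isinstance(model, str):
            model = LineageModel.parse(model)
        config = config.for_model(str(model))
        self.config = config
        self.model = model
        self.seed = int(seed)
        self.state = build_initial_state(config, seed=self.seed)
        scheduler.seed_attempt_stream(_sub_seed(seed, 1))
        bio_rng = np.random.default_rng(_sub_seed(seed, 2))
        self.stepper = LineageStepper(model, config, bio_rng)
        self._records: list = []
        self._record_sample()

    # ---- recording ----

    def _record_sample(self) -> None:
        st = self.state
        counts = st.counts_by_type()
        score = F.score_state(st, self.config.fitness)
        self._records.append(
            {
                "day": st.time_days,
                "n_P": counts[C.PROGENITOR],
                "n_B": counts[C.BASAL],
                "n_I": counts[C.INTERMEDIATE],
                "n_U": counts[C.UMBRELLA],
                "total_cells": sum(counts.values()),
                "fA": score["fa"],
                "fV": score["fv"],
                "f": score["f"],
                "covered": score["covered"],
            }
        )

    @property
    def series(self) -> pd.DataFrame:
        return pd.DataFrame(self._records)

    @property
    def fitness_series(self) -> F.FitnessSeries:
        df = self.series
        return F.FitnessSeries(df["day"].to_numpy(), df["fA"].to_numpy(), df["fV"].to_numpy())

    # ---- running ----

    def run(self, days: float, snapshot_dir=None, validate_daily: bool = True) -> pd.DataFrame:
        """Advance the simulation by ``days`` simulated days.

        Fitness/counts are sampled every ``fitness.sample_interval_days``;
        the cell-table/lattice consistency check runs after every simulated
        day.  Optional label-map snapshots follow the configured cadence.
        """
        mcs_per_day = self.state.mcs_per_day
        total_mcs = int(round(days * mcs_per_day))
        sample_mcs = max(1, int(round(self.config.fitness.sample_interval_days * mcs_per_day)))
        if snapshot_dir is not None:
            snapshot_dir = Path(snapshot_dir)
            snapshot_dir.mkdir(parents=True, exist_ok=True)
            self._maybe_snapshot(snapshot_dir)
        for _ in range(total_mcs):
            scheduler.run_mcs(self.state, biology=self.stepper)
            mcs = self.state.mcs_count
            if mcs % sample_mcs == 0:
                self._record_sample()
            if validate_daily and mcs % mcs_per_day == 0:
                self.state.check_integrity()
            if snapshot_dir is not None and mcs % mcs_per_day == 0:
                self._maybe_snapshot(snapshot_dir)
        return self.series

    def _maybe_snapshot(self, snapshot_dir: Path) -> None:
        from urocpm import io

        sched = self.config.schedule
        day = self.state.time_days
        if day <= sched.snapshot_switch_day:
            cadence = sched.snapshot_every_days_early
        else:
            cadence = sched.snapshot_every_days_late
        # snapshot on multiples of the cadence (day is an exact multiple of
        # 1/mcs_per_day, so compare within half a step)
        if abs(day / cadence - round(day / cadence)) > 1e-9:
            return
        tag = f"{str(self.model).replace('/', '-')}_seed{self.seed}_day{day:07.2f}"
        io.write_snapshot(self.state, snapshot_dir, tag)

    # ---- derived run measures ----

    def healing_time(self):
        """First sampled day at which every sampling window is topped by an
        umbrella cell, or None if never reached."""
        for rec in self._records:
            if rec["covered"]:
                return rec["day"]
        return None
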