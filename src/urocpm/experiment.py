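"""Batch orchestration: replicate runs per lineage model, run summaries,
fitness distributions and the box-plot/table reports."""

from __future__ import annotations

import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from urocpm import classify as CL
from urocpm import io
from urocpm.config import Config, default_config
from urocpm.fitness import FitnessSeries, time_average
from urocpm.lineage import LineageModel, all_models
from urocpm.simulation import Simulation

log = logging.getLogger("urocpm.experiment")


@dataclass
class RunSummary:
    model: str
    seed: int
    f_mean: float = float("nan")
    labels: list = field(default_factory=list)
    healing_time_days: float | None = None
    steady_state_day: float | None = None
    duration_days: float = 0.0
    failed: bool = False
    error: str = ""


def healing_time(series: pd.DataFrame):
    """First sampled day with full umbrella coverage, or None."""
    covered = series[series["covered"].astype(bool)]
    if len(covered) == 0:
        return None
    return float(covered["day"].iloc[0])


def steady_state_day(series: pd.DataFrame, band: float = 0.10, ref_days: float = 100.0):
    """First day after which total cell counts stay within ``band`` of the
    final-``ref_days`` mean; None if never settled."""
    day = series["day"].to_numpy(dtype=float)
    n = series["total_cells"].to_numpy(dtype=float)
    if day.size == 0:
        return None
    ref = n[day >= day[-1] - ref_days]
    mean = ref.mean()
    if mean <= 0:
        return None
    outside = np.abs(n - mean) > band * mean
    if not outside.any():
        return float(day[0])
    last_bad = np.flatnonzero(outside)[-1]
    if last_bad + 1 >= day.size:
        return None
    return float(day[last_bad + 1])


def run_single(model, seed: int, duration_days: float, config: Config | None = None,
               out_dir=None, validate_daily: bool = True) -> tuple:
    """Execute one seeded run; returns (RunSummary, series DataFrame)."""
    config = config or default_config()
    if isinstance(model, str):
        model = LineageModel.parse(model)
    snapshot_dir = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        snapshot_dir = out_dir / "snapshots"
    sim = Simulation(config, model, seed=seed)
    sim.run(duration_days, snapshot_dir=snapshot_dir, validate_daily=validate_daily)
    series = sim.series
    fs = FitnessSeries(series["day"].to_numpy(), series["fA"].to_numpy(), series["fV"].to_numpy())
    labels: list = []
    span = series["day"].max() - series["day"].min()
    if span >= config.classify.min_days:
        dev = CL.classify_run(series, series, config.classify)
        labels = sorted(dev.labels)
    summary = RunSummary(
        model=str(model),
        seed=seed,
        f_mean=time_average(fs),
        labels=labels,
        healing_time_days=healing_time(series),
        steady_state_day=steady_state_day(series),
        duration_days=float(duration_days),
    )
    if out_dir is not None:
        io.write_series_csv(series, out_dir / f"series_seed{seed}.csv")
    return summary, series


def run_batch(model, n: int, base_seed: int, duration_days: float,
              config: Config | None = None, out_dir=None,
              validate_daily: bool = False) -> list:
    """n independent replicate runs with seeds base_seed..base_seed+n-1.

    A crashed run is recorded as a failed summary, never silently dropped.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or default_config()
    if isinstance(model, str):
        model = LineageModel.parse(model)
    summaries = []
    for seed in range(base_seed, base_seed + n):
        run_dir = None
        if out_dir is not None:
            run_dir = Path(out_dir) / f"{str(model).replace('/', '-')}_seed{seed}"
        try:
            summary, _ = run_single(
                model, seed, duration_days, config, out_dir=run_dir,
                validate_daily=validate_daily,
            )
        except Exception as exc:  # noqa: BLE001 - failed runs are recorded
            log.error("run %s seed %d failed: %s", model, seed, exc)
            summary = RunSummary(
                model=str(model), seed=seed, failed=True,
                error="".join(traceback.format_exception_only(exc)).strip(),
                duration_days=float(duration_days),
            )
        summaries.append(summary)
    return summaries


def summaries_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model": s.model,
                "seed": s.seed,
                "f_mean": s.f_mean,
                "labels": ";".join(s.labels),
                "healing_time_days": s.healing_time_days,
                "steady_state_day": s.steady_state_day,
                "failed": s.failed,
            }
            for s in summaries
        ]
    )


def summarize(summaries) -> pd.DataFrame:
    """Per-model distribution of the run-level time-averaged total fitness:
    median, min, max, span (max - min) and quartiles."""
    df = summaries_frame(summaries)
    df = df[~df["failed"]]
    rows = []
    for model, grp in df.groupby("model", sort=False):
        f = grp["f_mean"].to_numpy(dtype=float)
        rows.append(
            {
                "model": model,
                "n": f.size,
                "median": float(np.median(f)),
                "min": float(f.min()),
                "max": float(f.max()),
                "span": float(f.max() - f.min()),
                "q1": float(np.percentile(f, 25)),
                "q3": float(np.percentile(f, 75)),
            }
        )
    return pd.DataFrame(rows).set_index("model")


def fitness_boxplot(summaries, path) -> None:
    """Box-and-whisker plot of per-model run fitness distributions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = summaries_frame(summaries)
    df = df[~df["failed"]]
    models = list(dict.fromkeys(df["model"]))
    data = [df.loc[df["model"] == m, "f_mean"].to_numpy() for m in models]
    fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(models) + 2), 4))
    ax.boxplot(data, tick_labels=models, whis=(0, 100))
    ax.set_ylabel("time-averaged total fitness")
    ax.set_ylim(0, 1)
    plt.setp(ax.get_xticklabels(), rotation=60, ha="right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
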