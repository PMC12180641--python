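"""Whole-run tissue-development classification.

Assigns a non-empty set of labels from {stable, chaotic, linear_growth,
exponential_growth, atrophy} to a completed run from its cell-count time
series (and, for the chaotic label, the arrangement-fitness series).  The
trend labels are mutually exclusive; chaotic may co-occur with any.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STABLE = "stable"
CHAOTIC = "chaotic"
LINEAR_GROWTH = "linear_growth"
EXPONENTIAL_GROWTH = "exponential_growth"
ATROPHY = "atrophy"


@dataclass
class DevelopmentLabels:
    labels: set
    stats: dict = field(default_factory=dict)

    def __contains__(self, item) -> bool:
        return item in self.labels

    def __iter__(self):
        return iter(sorted(self.labels))


def _aicc(sse: float, n: int, k: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    sse = max(sse, 1e-300)
    aic = n * np.log(sse / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def classify_run(counts: pd.DataFrame, fitness: pd.DataFrame | None = None,
                 classify_cfg=None) -> DevelopmentLabels:
    """Classify a completed run.

    ``counts`` needs columns ``day`` and ``total_cells`` (``n_P`` is used for
    the progenitor-extinction criterion when present); ``fitness`` needs
    ``day`` and ``fA``.  Requires at least ``min_days`` of data.
    """
    if classify_cfg is None:
        from urocpm.config import ClassifyConfig

        classify_cfg = ClassifyConfig()
    cfg = classify_cfg
    span = counts["day"].max() - counts["day"].min()
    if span < cfg.min_days:
        raise ValueError(
            f"need >= {cfg.min_days} simulated days of data, got {span:.1f}"
        )
    win = counts[counts["day"] >= cfg.window_start_day]
    t = win["day"].to_numpy(dtype=float)
    n = win["total_cells"].to_numpy(dtype=float)
    mean_n = float(n.mean())
    stats: dict = {"window_mean_count": mean_n}

    labels: set = set()

    # linear trend over the post-healing window; slope as % of the mean
    # count per 100 days
    b, a = np.polyfit(t, n, 1)
    rel_slope_per_100d = (100.0 * b / mean_n) * 100.0 if mean_n > 0 else 0.0
    stats["slope_per_day"] = float(b)
    stats["rel_slope_pct_per_100d"] = float(rel_slope_per_100d)

    # atrophy: collapse of the tissue or sustained negative trend
    final_count = float(n[-1]) if n.size else 0.0
    peak = float(n.max()) if n.size else 0.0
    collapsed = peak > 0 and final_count <= cfg.atrophy_final_frac * peak
    progenitor_extinct = False
    if "n_P" in counts.columns:
        np_series = win["n_P"].to_numpy(dtype=float)
        if np_series.size and np_series[-1] == 0 and np_series.max() > 0:
            # extinct: declining trend after the last progenitor vanished
            t_ext = t[np.nonzero(np_series == 0)[0][0]]
            after = n[t >= t_ext]
            if after.size >= 3:
                b_after, _ = np.polyfit(t[t >= t_ext], after, 1)
                progenitor_extinct = b_after < 0
    stats["collapsed"] = bool(collapsed)
    stats["progenitor_extinct_decline"] = bool(progenitor_extinct)

    threshold = cfg.stable_slope_pct_per_100d
    if collapsed or progenitor_extinct or rel_slope_per_100d <= -threshold:
        labels.add(ATROPHY)
    elif rel_slope_per_100d >= threshold:
        # growing: linear vs exponential by goodness of fit (AICc in count space)
        lin_pred = a + b * t
        sse_lin = float(np.sum((n - lin_pred) ** 2))
        pos = n > 0
        if pos.sum() >= 3:
            c1, c0 = np.polyfit(t[pos], np.log(n[pos]), 1)
            exp_pred = np.exp(c0 + c1 * t)
            sse_exp = float(np.sum((n - exp_pred) ** 2))
        else:
            sse_exp = np.inf
        stats["aicc_linear"] = _aicc(sse_lin, n.size, 2)
        stats["aicc_exponential"] = _aicc(sse_exp, n.size, 2)
        if stats["aicc_exponential"] < stats["aicc_linear"]:
            labels.add(EXPONENTIAL_GROWTH)
        else:
            labels.add(LINEAR_GROWTH)
    else:
        labels.add(STABLE)

    # chaotic: persistent disorder of the layer arrangement
    if fitness is not None and "fA" in fitness.columns:
        fwin = fitness[fitness["day"] >= cfg.window_start_day]
        mean_fa = float(fwin["fA"].mean()) if len(fwin) else float("nan")
        stats["window_mean_fA"] = mean_fa
        if np.isfinite(mean_fa) and mean_fa < cfg.chaotic_fa_threshold:
            labels.add(CHAOTIC)

    stats["final_count"] = final_count
    return DevelopmentLabels(labels=labels, stats=stats)
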