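"""Trial-by-trial power-correlation connectivity.

Functional connectivity between a frontal seed and a sensory electrode is
the Spearman rank correlation, across trials of one speech condition, of the
per-trial mean broadband power (200–1500 ms window).  Trials discarded by
the outlier rule in *either* electrode are dropped pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .broadband import BroadbandSet, BroadbandTimecourse
from .selection import RESPONSE_WINDOW


@dataclass
class ConnectivityResult:
    """Spearman ρ for one (frontal, sensory) pair in one condition."""

    pair: tuple[str, str]
    condition: str
    rho: float
    n_trials: int
    p_value: float
    defined: bool = True

    def __post_init__(self) -> None:
        if self.defined and not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError("rho must lie in [-1, 1]")


def trial_power(tc: BroadbandTimecourse,
                window: tuple[float, float] = RESPONSE_WINDOW) -> float:
    """Mean percent-change over the valid time points inside ``window``."""
    sel = (tc.times >= window[0]) & (tc.times <= window[1])
    vals = tc.pct[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no valid time points inside the window")
    return float(vals.mean())


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, bool]:
    """Spearman rank correlation with mid-rank ties and t-approximation p.

    Returns ``(rho, p, defined)``; ``defined`` is False when either series
    has zero rank variance (constant input), in which case rho is NaN.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length series with at least 3 trials")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan"), False
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue), True


def spearman_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided critical |rho| at level ``alpha`` from the t approximation."""
    if n < 4:
        raise ValueError("need at least 4 trials")
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t_crit / np.sqrt(n - 2 + t_crit**2))


def connectivity_table(bb: BroadbandSet, frontal: str,
                       sensory: Sequence[str],
                       conditions: Sequence[str] = ("AV", "Vis", "Aud"),
                       window: tuple[float, float] = RESPONSE_WINDOW,
                       min_trials: int = 3) -> list[ConnectivityResult]:
    """One Spearman ρ per (pair, condition), pairwise-complete over trials."""
    results = []
    for cond in conditions:
        if not (bb.trials["condition"] == cond).any():
            continue
        f_power = bb.window_means(frontal, window, condition=cond)
        for name in sensory:
            s_power = bb.window_means(name, window, condition=cond)
            common = f_power.index.intersection(s_power.index)
            if len(common) < min_trials:
                continue  # pair skipped: too few common retained trials
            rho, p, defined = spearman(f_power.loc[common].to_numpy(),
                                       s_power.loc[common].to_numpy())
            results.append(ConnectivityResult(
                pair=(frontal, name), condition=cond, rho=rho,
                n_trials=len(common), p_value=p, defined=defined))
    return results


def connectivity_frame(results: Sequence[ConnectivityResult],
                       labels: dict[str, str] | None = None) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "frontal": r.pair[0], "target": r.pair[1],
            "condition": r.condition, "rho": r.rho, "n": r.n_trials,
            "p": r.p_value,
            "target_label": (labels or {}).get(r.pair[1], ""),
        })
    return pd.DataFrame(rows)
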