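"""Responsive-electrode selection and frontal-seed choice.

An electrode is *responsive* when its per-trial mean broadband percent
change over the 200–1500 ms analysis window differs from zero (one-sample t
test on AV trials), with Benjamini–Hochberg FDR control at q = 0.01 across
the electrodes of one region.  Among the FDR-selected frontal candidates,
the per-subject seed is the electrode with the largest signal-to-noise
ratio μ/σ of those per-trial window means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .broadband import BroadbandSet

RESPONSE_WINDOW = (200.0, 1500.0)


@dataclass
class ResponsivenessResult:
    """Per-electrode response summary used for selection."""

    electrode: str
    mean_response: float     # mean pct, 200-1500 ms, across AV trials
    snr: float               # mu/sigma of per-trial window means
    p_value: float
    n_trials: int
    selected: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")


def responsiveness_test(window_means: np.ndarray) -> float:
    """Two-sided one-sample t test of per-trial window means against zero.

    Zero variance across trials is degenerate: p is 0 when the common value
    is nonzero (an infinitely consistent response) and 1 when it is zero.
    """
    x = np.asarray(window_means, float)
    if len(x) < 5:
        raise ValueError("need at least 5 retained trials")
    if np.std(x, ddof=1) == 0:
        return 0.0 if x.mean() != 0 else 1.0
    return float(stats.ttest_1samp(x, 0.0).pvalue)


def fdr_bh(p_values: np.ndarray, q: float = 0.01) -> np.ndarray:
    """Benjamini–Hochberg step-up selection mask.

    Rejects all hypotheses with p <= p(k*) where k* is the largest k such
    that the k-th smallest p satisfies p(k) <= k*q/m.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    below = sorted_p <= (np.arange(1, m + 1) * q / m)
    if not below.any():
        return np.zeros(m, bool)
    k_star = int(np.max(np.nonzero(below)[0]))
    return p <= sorted_p[k_star]


def evaluate_responsiveness(bb: BroadbandSet,
                            electrodes: list[str] | None = None,
                            condition: str = "AV",
                            window: tuple[float, float] = RESPONSE_WINDOW
                            ) -> list[ResponsivenessResult]:
    """Test every electrode's AV-trial response; no FDR applied yet."""
    electrodes = electrodes if electrodes is not None else bb.electrodes
    results = []
    for name in electrodes:
        means = bb.window_means(name, window, condition=condition).to_numpy()
        mu = float(means.mean())
        sd = float(means.std(ddof=1)) if len(means) > 1 else 0.0
        results.append(ResponsivenessResult(
            electrode=name, mean_response=mu,
            snr=mu / sd if sd > 0 else np.inf * np.sign(mu) if mu else 0.0,
            p_value=responsiveness_test(means), n_trials=len(means)))
    return results


def apply_selection(results: list[ResponsivenessResult],
                    q: float = 0.01) -> list[ResponsivenessResult]:
    """Set the ``selected`` flags by BH-FDR over the supplied family."""
    mask = fdr_bh(np.array([r.p_value for r in results]), q=q)
    for r, sel in zip(results, mask):
        r.selected = bool(sel)
    return results


def select_frontal(results: list[ResponsivenessResult]) -> str:
    """Seed electrode: highest SNR among FDR-selected candidates.

    Ties resolve to the electrode earliest in the candidate ordering (lowest
    index), so the choice is reproducible.
    """
    candidates = [r for r in results if r.selected]
    if not candidates:
        raise ValueError("no FDR-selected frontal candidates")
    best = candidates[0]
    for r in candidates[1:]:
        if r.snr > best.snr:
            best = r
    return best.electrode


def selection_table(results: list[ResponsivenessResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "electrode": r.electrode, "mean_response": r.mean_response,
        "snr": r.snr, "p_value": r.p_value, "n_trials": r.n_trials,
        "selected": r.selected,
    } for r in results])
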