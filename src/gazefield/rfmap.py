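"""Receptive-field estimation from flash-evoked potentials.

The analysis chain per electrode: discard trials with raw-voltage excursions
beyond ``k`` pooled standard deviations, smooth each retained trace with an
order-5 / 11-sample Savitzky-Golay filter, average the 100–300 ms
post-stimulus window (first across trials, then across time) per grid
position, fit an axis-aligned 2-D Gaussian plus offset to the resulting map,
and classify the electrode as *mouth* (receptive-field center within 5° of
the mouth-center reference) or *non-mouth*.  Fits whose model-data Pearson
correlation is <= 0.7 are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

from .synth import RFMappingSession, gaussian_field

MOUTH_LABEL = "mouth"
NON_MOUTH_LABEL = "non-mouth"
REJECTED_LABEL = "rejected"


class DegenerateDataError(ValueError):
    """Raised when an operation's input is degenerate (e.g. all trials bad)."""


# ---------------------------------------------------------------------------
# trial-level preprocessing
# ---------------------------------------------------------------------------

def smooth_evoked(trace: np.ndarray, window: int = 11, polyorder: int = 5) -> np.ndarray:
    """Savitzky-Golay smoothing (order 5, 11-sample frame) of a voltage trace.

    Works on the last axis, so a (n_trials, n_samples) stack is smoothed
    trial-wise in one call.
    """
    trace = np.asarray(trace, float)
    if trace.shape[-1] < window:
        raise ValueError(f"trace shorter than the filter frame ({window} samples)")
    return signal.savgol_filter(trace, window_length=window, polyorder=polyorder,
                                axis=-1)


def reject_voltage_outliers(trials: np.ndarray | Sequence[np.ndarray],
                            k: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Discard trials with any raw sample beyond ``k`` SD of the pooled voltage.

    Mean and SD are pooled over all samples of all trials.  Returns
    ``(retained_trials, keep_mask)``; raises :class:`DegenerateDataError` if
    nothing survives.
    """
    arr = np.asarray(trials, float)
    if arr.ndim != 2 or len(arr) < 2:
        raise ValueError("need at least 2 trials of equal length")
    mu = arr.mean()
    sd = arr.std()
    if sd == 0:
        keep = np.ones(len(arr), bool)
        return arr, keep
    keep = np.max(np.abs(arr - mu), axis=1) <= k * sd
    if not keep.any():
        raise DegenerateDataError("voltage outlier rule discarded every trial")
    return arr[keep], keep


# ---------------------------------------------------------------------------
# grid response map
# ---------------------------------------------------------------------------

@dataclass
class GridResponseMap:
    """Mean evoked amplitude per flashed grid position (missing ones dropped)."""

    positions: np.ndarray          # (n_pos, 2) degrees
    amplitude: np.ndarray          # (n_pos,)
    n_trials_used: np.ndarray      # (n_pos,)

    def __post_init__(self) -> None:
        if not (len(self.positions) == len(self.amplitude) == len(self.n_trials_used)):
            raise ValueError("one amplitude and trial count per position required")
        if np.any(self.n_trials_used < 1):
            raise ValueError("retained positions need at least one trial")


def build_grid_map(session: RFMappingSession, electrode: str,
                   window_ms: tuple[float, float] = (100.0, 300.0),
                   outlier_k: float = 3.0) -> GridResponseMap:
    """Average filtered evoked voltage (100–300 ms) per grid position.

    Outlier trials are removed with the pooled-SD rule before smoothing.
    Positions left with zero retained trials are excluded from the map.
    """
    traces = session.electrode_traces(electrode)
    _, keep = reject_voltage_outliers(traces, k=outlier_k)
    smoothed = smooth_evoked(traces[keep])
    win = (session.time_ms >= window_ms[0]) & (session.time_ms <= window_ms[1])
    trial_amp = smoothed[:, win].mean(axis=1)
    pos_index = session.trials["pos_index"].to_numpy()[keep]

    positions, amplitudes, counts = [], [], []
    for p in range(len(session.grid)):
        sel = pos_index == p
        n = int(sel.sum())
        if n == 0:
            continue  # flagged missing: excluded from the fit
        positions.append(session.grid[p])
        amplitudes.append(trial_amp[sel].mean())
        counts.append(n)
    return GridResponseMap(positions=np.asarray(positions, float),
                           amplitude=np.asarray(amplitudes, float),
                           n_trials_used=np.asarray(counts, int))


# ---------------------------------------------------------------------------
# Gaussian receptive-field fit
# ---------------------------------------------------------------------------

@dataclass
class ReceptiveField:
    """Fitted axis-aligned 2-D Gaussian receptive field."""

    center: tuple[float, float]
    sigma: tuple[float, float]
    amplitude: float
    offset: float
    fit_r: float
    eccentricity: float | None = None
    label: str = REJECTED_LABEL
    diagnostic: str = ""


def _gauss_model(params: np.ndarray, positions: np.ndarray) -> np.ndarray:
    x0, y0, sx, sy, a, c = params
    return a * gaussian_field(positions, (x0, y0), (sx, sy)) + c


def fit_gaussian_rf(gmap: GridResponseMap, r_threshold: float = 0.7,
                    n_restarts: int = 5, seed: int = 0) -> ReceptiveField:
    """Nonlinear least-squares fit of Gaussian + offset to a grid map.

    Initialization at the map argmax with sigma at one grid spacing and
    offset at the map minimum, plus ``n_restarts`` jittered restarts; the
    best solution by residual sum of squares wins.  ``fit_r`` is the Pearson
    correlation between the fitted surface and the map; fits with
    ``fit_r <= r_threshold`` (or non-convergence) are labelled rejected.
    """
    pos = gmap.positions
    amp = gmap.amplitude
    if len(pos) < 6:
        raise ValueError("need at least 6 grid positions to fit 6 parameters")

    spacing = max(np.median(np.diff(np.unique(pos[:, 0]))), 1.0)
    i_max = int(np.argmax(amp))
    p0 = np.array([pos[i_max, 0], pos[i_max, 1], spacing, spacing,
                   amp.max() - amp.min(), amp.min()])
    lo_x, hi_x = pos[:, 0].min() - spacing, pos[:, 0].max() + spacing
    lo_y, hi_y = pos[:, 1].min() - spacing, pos[:, 1].max() + spacing
    bounds = (np.array([lo_x, lo_y, 0.2, 0.2, -np.inf, -np.inf]),
              np.array([hi_x, hi_y, 50.0, 50.0, np.inf, np.inf]))

    rng = np.random.default_rng(seed)
    best = None
    starts = [p0]
    for _ in range(n_restarts):
        q = p0.copy()
        q[0] += rng.uniform(-2, 2) * spacing
        q[1] += rng.uniform(-2, 2) * spacing
        q[2:4] *= rng.uniform(0.5, 2.0, size=2)
        starts.append(np.clip(q, bounds[0], np.minimum(bounds[1], 1e12)))
    for start in starts:
        try:
            res = optimize.least_squares(
                lambda p: _gauss_model(p, pos) - amp, start, bounds=bounds)
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res

    if best is None:
        return ReceptiveField(center=(np.nan, np.nan), sigma=(np.nan, np.nan),
                              amplitude=np.nan, offset=np.nan, fit_r=np.nan,
                              label=REJECTED_LABEL,
                              diagnostic="fit did not converge from any start")

    x0, y0, sx, sy, a, c = best.x
    model = _gauss_model(best.x, pos)
    if np.std(model) == 0 or np.std(amp) == 0:
        fit_r = 0.0
    else:
        fit_r = float(stats.pearsonr(model, amp)[0])
    label = REJECTED_LABEL if fit_r <= r_threshold else "unclassified"
    return ReceptiveField(center=(float(x0), float(y0)),
                          sigma=(float(abs(sx)), float(abs(sy))),
                          amplitude=float(a), offset=float(c), fit_r=fit_r,
                          label=label,
                          diagnostic="" if label != REJECTED_LABEL
                          else f"fit_r={fit_r:.3f} <= {r_threshold}")


def classify_electrode(rf: ReceptiveField, reference: tuple[float, float] = (0.0, 0.0),
                       threshold_deg: float = 5.0) -> ReceptiveField:
    """Label a fitted RF as mouth / non-mouth by distance to the reference.

    ``reference`` is the mouth-center position in visual-field degrees
    (fixation when the subject fixates the mouth; a displaced point when the
    mouth is in the periphery).  The boundary is strict: eccentricity exactly
    at ``threshold_deg`` is non-mouth.
    """
    if rf.label == REJECTED_LABEL:
        raise ValueError("cannot classify a rejected receptive field")
    ecc = float(np.hypot(rf.center[0] - reference[0], rf.center[1] - reference[1]))
    label = MOUTH_LABEL if ecc < threshold_deg else NON_MOUTH_LABEL
    return replace(rf, eccentricity=ecc, label=label)


def map_session(session: RFMappingSession,
                reference: tuple[float, float] = (0.0, 0.0),
                threshold_deg: float = 5.0,
                r_threshold: float = 0.7,
                outlier_k: float = 3.0,
                seed: int = 0) -> pd.DataFrame:
    """Fit and classify every electrode of a mapping session.

    Returns a table with one row per electrode: center, sigma, fit quality,
    eccentricity and label (rejected electrodes keep NaN eccentricity).
    """
    rows = []
    for name in session.electrodes:
        gmap = build_grid_map(session, name, outlier_k=outlier_k)
        rf = fit_gaussian_rf(gmap, r_threshold=r_threshold, seed=seed)
        if rf.label != REJECTED_LABEL:
            rf = classify_electrode(rf, reference, threshold_deg)
        rows.append({
            "electrode": name,
            "x0": rf.center[0], "y0": rf.center[1],
            "sx": rf.sigma[0], "sy": rf.sigma[1],
            "amplitude": rf.amplitude, "offset": rf.offset,
            "fit_r": rf.fit_r,
            "eccentricity": rf.eccentricity if rf.eccentricity is not None else np.nan,
            "label": rf.label,
        })
    return pd.DataFrame(rows)
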