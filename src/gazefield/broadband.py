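"""Broadband (70–150 Hz) percent-change timecourses from raw speech trials.

Preprocessing order: common-average reference across electrodes, zero-phase
band-stop notches at the mains harmonics, sliding-window multitaper
time-frequency transform (3 Slepian tapers, 200 ms window, 10 ms steps,
2 Hz frequency bins from 10–200 Hz), per-frequency percent change against a
baseline pooled over all trials and conditions (−500 to −100 ms), average of
the percent-change bins inside the high-gamma band, and a leave-one-out
10-SD trial-rejection rule on the resulting broadband traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import signal

from .synth import SpeechSession

#: default high-gamma band (Hz)
BAND = (70.0, 150.0)
#: default baseline window (ms relative to stimulus onset)
BASELINE_WINDOW = (-500.0, -100.0)

#: multitaper defaults: 200 ms window with ±10 Hz smoothing gives
#: K = 2*T*W - 1 = 2*0.2*10 - 1 = 3 Slepian tapers
MT_WINDOW_MS = 200.0
MT_STEP_MS = 10.0
MT_FREQ_SMOOTHING_HZ = 10.0
MT_N_TAPERS = 3
MT_FREQ_RANGE = (10.0, 200.0)
MT_FREQ_STEP = 2.0


def slepian_taper_count(window_ms: float = MT_WINDOW_MS,
                        half_bandwidth_hz: float = MT_FREQ_SMOOTHING_HZ) -> int:
    """Taper count K = 2*T*W - 1 for window length T and half-bandwidth W."""
    return int(round(2.0 * (window_ms / 1000.0) * half_bandwidth_hz - 1.0))


class DegenerateSignalError(ValueError):
    """Raised when a signal is too degenerate to normalize (zero baseline)."""


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def common_average_reference(signals: np.ndarray, axis: int = 0) -> np.ndarray:
    """Subtract the across-electrode mean sample-by-sample.

    ``axis`` indexes electrodes.  After referencing, the electrode mean is
    exactly zero at every sample.
    """
    arr = np.asarray(signals, float)
    if arr.shape[axis] < 2:
        raise ValueError("common average reference needs at least 2 electrodes")
    return arr - arr.mean(axis=axis, keepdims=True)


def notch_line_noise(trace: np.ndarray, fs: float,
                     freqs: Sequence[float] = (60.0, 120.0, 180.0),
                     half_width_hz: float = 2.0, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-stop at each mains harmonic.

    Each notch removes ``f0 ± half_width_hz``; a 100 Hz passband tone loses
    well under 1 dB.  Filters along the last axis.
    """
    out = np.asarray(trace, float)
    for f0 in freqs:
        if f0 + half_width_hz >= fs / 2:
            raise ValueError(f"notch frequency {f0} Hz is at or above Nyquist")
        sos = signal.butter(order, [f0 - half_width_hz, f0 + half_width_hz],
                            btype="bandstop", fs=fs, output="sos")
        out = signal.sosfiltfilt(sos, out, axis=-1)
    return out


# ---------------------------------------------------------------------------
# multitaper time-frequency transform
# ---------------------------------------------------------------------------

@dataclass
class TimeFrequencyResponse:
    """Taper-averaged sliding-window power, (n_times, n_freqs)."""

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        if np.any(np.diff(self.times) <= 0) or np.any(np.diff(self.freqs) <= 0):
            raise ValueError("time and frequency grids must be strictly increasing")


def multitaper_tfr(traces: np.ndarray, fs: float, time_ms: np.ndarray,
                   window_ms: float = MT_WINDOW_MS, step_ms: float = MT_STEP_MS,
                   n_tapers: int = MT_N_TAPERS,
                   half_bandwidth_hz: float = MT_FREQ_SMOOTHING_HZ,
                   freq_range: tuple[float, float] = MT_FREQ_RANGE,
                   freq_step: float = MT_FREQ_STEP) -> TimeFrequencyResponse | list:
    """Sliding-window multitaper power of one trial (or a stack of trials).

    Time points are window centers on the ``step_ms`` grid; windows that
    would extend beyond the trial are simply not produced (no zero padding).
    The FFT is zero-padded to ``fs / freq_step`` samples so the frequency
    grid lands exactly on multiples of ``freq_step``.
    """
    if fs < 2 * freq_range[1]:
        raise ValueError(f"sampling rate {fs} Hz cannot resolve {freq_range[1]} Hz")
    arr = np.atleast_2d(np.asarray(traces, float))
    win_n = int(round(window_ms * fs / 1000.0))
    step_n = int(round(step_ms * fs / 1000.0))
    if arr.shape[-1] < win_n:
        raise ValueError("trial shorter than one multitaper window")

    nw = (window_ms / 1000.0) * half_bandwidth_hz  # time-bandwidth product
    tapers = signal.windows.dpss(win_n, NW=nw, Kmax=n_tapers)  # (K, win_n)
    nfft = int(round(fs / freq_step))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    fsel = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
    freqs = freqs[fsel]

    frames = np.lib.stride_tricks.sliding_window_view(arr, win_n, axis=-1)
    frames = frames[..., ::step_n, :]                       # (..., n_frames, win_n)
    centers = time_ms[win_n // 2::step_n][: frames.shape[-2]]

    out = []
    for trial in frames:
        tapered = trial[None, :, :] * tapers[:, None, :]    # (K, n_frames, win_n)
        spec = np.fft.rfft(tapered, n=nfft, axis=-1)
        power = (np.abs(spec) ** 2).mean(axis=0)[:, fsel]   # (n_frames, n_freqs)
        out.append(TimeFrequencyResponse(times=centers, freqs=freqs, power=power))
    if np.asarray(traces).ndim == 1:
        return out[0]
    return out


# ---------------------------------------------------------------------------
# percent change and outlier rejection
# ---------------------------------------------------------------------------

@dataclass
class BroadbandTimecourse:
    """One trial's broadband percent-change trace."""

    times: np.ndarray
    pct: np.ndarray
    trial_id: int
    condition: str
    retained: bool = True

    def __post_init__(self) -> None:
        if np.any(self.pct < -100.0 - 1e-9):
            raise ValueError("percent change cannot fall below -100")


def percent_change_matrix(power: np.ndarray, times: np.ndarray, freqs: np.ndarray,
                          baseline_window: tuple[float, float] = BASELINE_WINDOW,
                          band: tuple[float, float] = BAND) -> np.ndarray:
    """Per-frequency baseline normalization, then high-gamma band average.

    ``power`` has shape (n_trials, n_times, n_freqs); the baseline B(f) is
    the mean over baseline time points of *all* trials (all conditions
    pooled).  Returns the (n_trials, n_times) broadband percent change.
    """
    tsel = (times >= baseline_window[0]) & (times <= baseline_window[1])
    if not tsel.any():
        raise ValueError("baseline window not covered by the time grid")
    bsel = (freqs >= band[0]) & (freqs <= band[1])
    baseline = power[:, tsel, :].mean(axis=(0, 1))          # B(f)
    if np.any(baseline[bsel] == 0):
        raise DegenerateSignalError("zero baseline power in a band frequency bin")
    pct = 100.0 * (power[:, :, bsel] - baseline[bsel]) / baseline[bsel]
    return pct.mean(axis=2)


def broadband_percent_change(tfrs: Sequence[TimeFrequencyResponse],
                             trial_ids: Sequence[int],
                             conditions: Sequence[str],
                             baseline_window: tuple[float, float] = BASELINE_WINDOW,
                             band: tuple[float, float] = BAND
                             ) -> list[BroadbandTimecourse]:
    """Percent-change timecourses for all trials of one electrode."""
    power = np.stack([tfr.power for tfr in tfrs])
    pct = percent_change_matrix(power, tfrs[0].times, tfrs[0].freqs,
                                baseline_window, band)
    return [BroadbandTimecourse(times=tfrs[0].times, pct=row,
                                trial_id=int(tid), condition=str(cond))
            for row, tid, cond in zip(pct, trial_ids, conditions)]


def loo_outlier_mask(pct: np.ndarray, k: float = 10.0,
                     post_mask: np.ndarray | None = None) -> np.ndarray:
    """Leave-one-out outlier rule on a (n_trials, n_times) percent matrix.

    A trial is discarded when, at any post-stimulus time point, it deviates
    more than ``k`` standard deviations from the mean computed across the
    *other* trials at that time point.  Returns the keep mask.
    """
    if len(pct) < 3:
        raise ValueError("leave-one-out outlier rule needs at least 3 trials")
    x = pct if post_mask is None else pct[:, post_mask]
    t = len(x)
    s = x.sum(axis=0)
    ss = (x ** 2).sum(axis=0)
    loo_mean = (s - x) / (t - 1)
    # unbiased variance over the t-1 other trials
    loo_var = (ss - x**2 - (t - 1) * loo_mean**2) / (t - 2)
    loo_sd = np.sqrt(np.clip(loo_var, 0.0, None))
    exceed = np.abs(x - loo_mean) > k * loo_sd
    return ~exceed.any(axis=1)


def reject_power_outliers(timecourses: Sequence[BroadbandTimecourse],
                          k: float = 10.0,
                          stim_onset_ms: float = 0.0) -> list[BroadbandTimecourse]:
    """Apply the leave-one-out rule; returns all trials with flags updated."""
    times = timecourses[0].times
    pct = np.stack([tc.pct for tc in timecourses])
    keep = loo_outlier_mask(pct, k=k, post_mask=times >= stim_onset_ms)
    return [BroadbandTimecourse(times=tc.times, pct=tc.pct, trial_id=tc.trial_id,
                                condition=tc.condition, retained=bool(kp))
            for tc, kp in zip(timecourses, keep)]


# ---------------------------------------------------------------------------
# session-level container
# ---------------------------------------------------------------------------

@dataclass
class BroadbandSet:
    """Per-electrode broadband percent-change matrices for one speech session."""

    times: np.ndarray
    trials: pd.DataFrame                       # trial_id, condition, word
    electrodes: list[str]
    regions: list[str]
    pct: dict[str, np.ndarray] = field(default_factory=dict)
    retained: dict[str, np.ndarray] = field(default_factory=dict)
    band: tuple[float, float] = BAND
    baseline_window: tuple[float, float] = BASELINE_WINDOW

    def timecourses(self, electrode: str) -> list[BroadbandTimecourse]:
        pct = self.pct[electrode]
        keep = self.retained[electrode]
        return [BroadbandTimecourse(times=self.times, pct=pct[i],
                                    trial_id=int(row.trial_id),
                                    condition=str(row.condition),
                                    retained=bool(keep[i]))
                for i, row in enumerate(self.trials.itertuples())]

    def window_means(self, electrode: str, window: tuple[float, float],
                     condition: str | None = None,
                     retained_only: bool = True) -> pd.Series:
        """Mean percent change inside ``window`` per trial (indexed by trial_id)."""
        tsel = (self.times >= window[0]) & (self.times <= window[1])
        if not tsel.any():
            raise ValueError("window contains no valid time points")
        vals = self.pct[electrode][:, tsel].mean(axis=1)
        mask = np.ones(len(vals), bool)
        if retained_only:
            mask &= self.retained[electrode]
        if condition is not None:
            mask &= (self.trials["condition"] == condition).to_numpy()
        return pd.Series(vals[mask], index=self.trials["trial_id"].to_numpy()[mask])

    def condition_matrix(self, electrode: str, condition: str,
                         retained_only: bool = True) -> np.ndarray:
        mask = (self.trials["condition"] == condition).to_numpy()
        if retained_only:
            mask &= self.retained[electrode]
        return self.pct[electrode][mask]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with h5py.File(path, "w") as h5:
            h5.create_dataset("times", data=self.times)
            h5.attrs["band"] = self.band
            h5.attrs["baseline_window"] = self.baseline_window
            h5.attrs["electrodes"] = list(self.electrodes)
            h5.attrs["regions"] = list(self.regions)
            tg = h5.create_group("trials")
            tg.create_dataset("trial_id", data=self.trials["trial_id"].to_numpy(int))
            for col in ("condition", "word"):
                if col in self.trials:
                    tg.create_dataset(col, data=self.trials[col].astype("S").to_numpy())
            for name in self.electrodes:
                grp = h5.create_group(f"electrodes/{name}")
                grp.create_dataset("pct", data=self.pct[name])
                grp.create_dataset("retained", data=self.retained[name])
        return path

    @classmethod
    def load(cls, path: str | Path) -> "BroadbandSet":
        with h5py.File(path, "r") as h5:
            times = h5["times"][()]
            def _as_str(values):
                return [v.decode() if isinstance(v, bytes) else str(v)
                        for v in values]
            electrodes = _as_str(h5.attrs["electrodes"])
            regions = _as_str(h5.attrs["regions"])
            tdata = {"trial_id": h5["trials/trial_id"][()]}
            for col in ("condition", "word"):
                if f"trials/{col}" in h5:
                    tdata[col] = [v.decode() for v in h5[f"trials/{col}"][()]]
            trials = pd.DataFrame(tdata)
            pct = {n: h5[f"electrodes/{n}/pct"][()] for n in electrodes}
            retained = {n: h5[f"electrodes/{n}/retained"][()].astype(bool)
                        for n in electrodes}
            band = tuple(h5.attrs["band"])
            baseline = tuple(h5.attrs["baseline_window"])
        return cls(times=times, trials=trials, electrodes=electrodes,
                   regions=regions, pct=pct, retained=retained,
                   band=band, baseline_window=baseline)


def process_session(session: SpeechSession,
                    band: tuple[float, float] = BAND,
                    baseline_window: tuple[float, float] = BASELINE_WINDOW,
                    outlier_k: float = 10.0,
                    car: bool = True) -> BroadbandSet:
    """Raw speech session -> per-electrode broadband percent-change set.

    ``car`` applies common-average referencing across electrodes before the
    notch filters; disable it for sessions with only a couple of electrodes,
    where the reference would mix the electrodes' own signals rather than
    remove shared artifacts.
    """
    if session.traces.size == 0 or len(session.electrodes) == 0:
        raise ValueError("session contains no electrodes or no trials")
    fs = session.acq.sampling_rate
    traces = session.traces
    if car:
        traces = common_average_reference(traces, axis=1)
    traces = notch_line_noise(traces, fs, freqs=session.acq.line_freqs)

    out = BroadbandSet(times=None, trials=session.trials.copy(),
                       electrodes=list(session.electrodes),
                       regions=list(session.regions), band=band,
                       baseline_window=baseline_window)
    for e, name in enumerate(session.electrodes):
        tfrs = multitaper_tfr(traces[:, e, :], fs, session.time_ms)
        power = np.stack([tfr.power for tfr in tfrs])
        pct = percent_change_matrix(power, tfrs[0].times, tfrs[0].freqs,
                                    baseline_window, band)
        keep = loo_outlier_mask(pct, k=outlier_k,
                                post_mask=tfrs[0].times >= 0.0)
        out.pct[name] = pct
        out.retained[name] = keep
        if out.times is None:
            out.times = tfrs[0].times
    return out
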