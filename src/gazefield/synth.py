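"""Synthetic ECoG session generation with known ground truth.

Two kinds of sessions are generated, mirroring a typical intracranial
audiovisual-speech protocol:

* **Receptive-field mapping sessions** — a small checkerboard is flashed at
  positions of a rectangular grid spanning the display; each flash evokes a
  biphasic potential whose amplitude follows a 2-D Gaussian over stimulus
  position (the electrode's ground-truth receptive field), superimposed on
  power-law background noise.

* **Speech sessions** — on every trial a band-limited (70–150 Hz) carrier is
  amplitude-modulated by a condition-dependent envelope (AV / Vis / Aud) and
  by a lognormal per-trial gain.  The gain loads on a latent standard-normal
  trial factor shared across electrodes, which induces the trial-by-trial
  power correlations measured by the connectivity stage.  Power-law
  background and mains-line sinusoids (60/120/180 Hz) are added on top.

Every generator is a pure function of (configuration, seed): identical seeds
give bit-identical sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

CONDITIONS = ("AV", "Vis", "Aud")
WORDS = ("drive", "known", "last", "meant")

#: physical display extent in degrees of visual angle (width, height),
#: fixation at the center
DISPLAY_DEG = (30.5, 22.9)


# ---------------------------------------------------------------------------
# acquisition & stimulus configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionSpec:
    """Recording-chain description.

    ``sampling_rate`` is the digitization rate; ``lowpass_cutoff`` /
    ``highpass_cutoff`` describe the amplifier's anti-aliasing band (they
    bound the synthetic background spectrum).  ``noise_floor`` is the SD of
    the background process in the session's (arbitrary) voltage units.  The
    background PSD follows the knee form common to neural field potentials,
    S(f) ∝ 1 / (1 + (f / knee)**exponent): flat below ``background_knee_hz``
    and falling as 1/f**exponent above it.
    """

    sampling_rate: float = 2000.0
    lowpass_cutoff: float = 500.0
    highpass_cutoff: float = 0.3
    line_freqs: tuple[float, ...] = (60.0, 120.0, 180.0)
    line_amplitudes: tuple[float, ...] = (0.3, 0.15, 0.1)
    noise_floor: float = 0.5
    background_exponent: float = 2.0
    background_knee_hz: float = 10.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2.0 * self.lowpass_cutoff:
            raise ValueError(
                "sampling_rate must exceed twice the lowpass cutoff "
                f"({self.sampling_rate} <= 2*{self.lowpass_cutoff})"
            )
        if list(self.line_freqs) != sorted(set(self.line_freqs)):
            raise ValueError("line_freqs must be strictly increasing")
        if len(self.line_amplitudes) != len(self.line_freqs):
            raise ValueError("one line amplitude per line frequency required")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be non-negative")

    @classmethod
    def rf_default(cls) -> "AcquisitionSpec":
        """Defaults for mapping sessions (evoked potentials, µV scale)."""
        return cls(noise_floor=40.0)

    @classmethod
    def speech_default(cls) -> "AcquisitionSpec":
        """Defaults for speech sessions (broadband carrier has unit SD)."""
        return cls(noise_floor=0.5)


@dataclass(frozen=True)
class StimulusSchedule:
    """Per-word timing of the audiovisual word stimuli (ms from video onset)."""

    words: tuple[str, ...] = WORDS
    video_onset_ms: float = 0.0
    mouth_move_onset_ms: tuple[float, ...] = (200.0, 233.0, 200.0, 200.0)
    auditory_onset_ms: tuple[float, ...] = (267.0, 233.0, 300.0, 333.0)
    vocal_duration_ms: tuple[float, ...] = (500.0, 400.0, 530.0, 500.0)
    trial_duration_ms: tuple[float, ...] = (1670.0, 1300.0, 1500.0, 1400.0)
    isi_ms: float = 2500.0

    def __post_init__(self) -> None:
        n = len(self.words)
        for name in ("mouth_move_onset_ms", "auditory_onset_ms",
                     "vocal_duration_ms", "trial_duration_ms"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one entry per word")
        for w, m, a, d in zip(self.words, self.mouth_move_onset_ms,
                              self.auditory_onset_ms, self.trial_duration_ms):
            # mouth movement may start with vocalization ('known': 233/233 ms)
            if not (0 <= m <= a < d):
                raise ValueError(
                    f"word {w!r}: need 0 <= mouth onset <= auditory onset "
                    f"< trial duration, got ({m}, {a}, {d})"
                )

    @property
    def mean_mouth_onset_ms(self) -> float:
        return float(np.mean(self.mouth_move_onset_ms))

    @property
    def mean_auditory_onset_ms(self) -> float:
        return float(np.mean(self.auditory_onset_ms))

    def auditory_onset_for(self, word: str) -> float:
        return float(self.auditory_onset_ms[self.words.index(word)])


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthElectrode:
    """Generative parameters for one simulated electrode.

    ``rf_center``/``rf_sigma``/``evoked_gain`` drive the mapping session;
    ``condition_envelopes`` (condition -> amplitude envelope over the speech
    epoch), ``divergence_onset_ms`` and ``factor_loading`` drive the speech
    session.  ``factor_loading`` (λ in [0, 1]) is the electrode's loading on
    the shared latent trial gain.
    """

    name: str
    region: str = "visual"
    rf_center: tuple[float, float] | None = None
    rf_sigma: tuple[float, float] | None = None
    evoked_gain: float = 0.0
    condition_envelopes: Mapping[str, np.ndarray] | None = None
    divergence_onset_ms: float | None = None
    factor_loading: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.factor_loading <= 1.0:
            raise ValueError("factor_loading must be in [0, 1]")
        if self.rf_sigma is not None and min(self.rf_sigma) <= 0:
            raise ValueError("rf_sigma components must be positive")
        if self.condition_envelopes is not None:
            for cond, env in self.condition_envelopes.items():
                if np.any(np.asarray(env) < 0):
                    raise ValueError(f"envelope for {cond!r} must be non-negative")


def default_grid(n_x: int = 9, n_y: int = 7, spacing_deg: float = 3.0) -> np.ndarray:
    """Checkerboard-flash grid: ``n_x * n_y`` positions centred on fixation.

    The default 9 x 7 grid with 3° spacing spans 27° x 21°, i.e. (almost all
    of) the 30.5° x 22.9° display.
    """
    xs = (np.arange(n_x) - (n_x - 1) / 2) * spacing_deg
    ys = (np.arange(n_y) - (n_y - 1) / 2) * spacing_deg
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def gaussian_field(positions: np.ndarray, center: Sequence[float],
                   sigma: Sequence[float]) -> np.ndarray:
    """Unit-height axis-aligned 2-D Gaussian evaluated at ``positions``."""
    pos = np.asarray(positions, float)
    dx = (pos[:, 0] - center[0]) / sigma[0]
    dy = (pos[:, 1] - center[1]) / sigma[1]
    return np.exp(-0.5 * (dx**2 + dy**2))


def evoked_template(time_ms: np.ndarray) -> np.ndarray:
    """Biphasic flash-evoked deflection (difference of temporal Gaussians).

    Positive complex peaking at 160 ms (σ = 55 ms, spanning most of the
    100–300 ms averaging window) followed by a weaker negative rebound at
    380 ms (σ = 50 ms); essentially zero outside ~50–500 ms.
    """
    t = np.asarray(time_ms, float)
    return (np.exp(-0.5 * ((t - 160.0) / 55.0) ** 2)
            - 0.5 * np.exp(-0.5 * ((t - 380.0) / 50.0) ** 2))


# ---------------------------------------------------------------------------
# noise building blocks (all deterministic given the rng)
# ---------------------------------------------------------------------------

def _shaped_noise(rng: np.random.Generator, shape: tuple[int, ...], n: int,
                  amplitude: np.ndarray) -> np.ndarray:
    """White noise spectrally shaped by ``amplitude`` (rfft bins), unit var.

    The output variance is fixed analytically (Parseval), not by empirical
    rescaling, so scaling is deterministic and independent of the draw.
    """
    w = rng.standard_normal(shape + (n,))
    spec = np.fft.rfft(w, axis=-1) * amplitude
    x = np.fft.irfft(spec, n=n, axis=-1)
    weights = np.full(amplitude.shape, 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    var = float(np.sum(weights * amplitude**2) / n)
    if var <= 0:
        return np.zeros(shape + (n,))
    return x / math.sqrt(var)


def powerlaw_background(rng: np.random.Generator, shape: tuple[int, ...],
                        n: int, acq: AcquisitionSpec) -> np.ndarray:
    """Knee-spectrum background noise with SD = noise_floor.

    PSD ∝ 1/(1 + (f/knee)**exponent), restricted to the amplifier band.
    """
    if acq.noise_floor == 0:
        return np.zeros(shape + (n,))
    f = np.fft.rfftfreq(n, 1.0 / acq.sampling_rate)
    amp = np.zeros_like(f)
    band = (f >= acq.highpass_cutoff) & (f <= acq.lowpass_cutoff)
    amp[band] = (1.0 + (f[band] / acq.background_knee_hz)
                 ** acq.background_exponent) ** -0.5
    return acq.noise_floor * _shaped_noise(rng, shape, n, amp)


@lru_cache(maxsize=8)
def _carrier_amplitude(n: int, fs: float, lo: float, hi: float,
                       order: int) -> np.ndarray:
    f = np.fft.rfftfreq(n, 1.0 / fs)
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    _, h = signal.sosfreqz(sos, worN=2 * np.pi * f / fs)
    # squared magnitude = zero-phase (forward-backward) response
    return np.abs(h) ** 2


def bandlimited_carrier(rng: np.random.Generator, shape: tuple[int, ...],
                        n: int, fs: float, band: tuple[float, float] = (70.0, 150.0),
                        sd: float = 1.0, order: int = 4) -> np.ndarray:
    """Gaussian carrier noise confined to ``band`` (high-gamma by default)."""
    amp = _carrier_amplitude(n, fs, band[0], band[1], order)
    return sd * _shaped_noise(rng, shape, n, amp)


# ---------------------------------------------------------------------------
# condition envelopes
# ---------------------------------------------------------------------------

def _smoothstep(t: np.ndarray, start: float, width: float) -> np.ndarray:
    """Raised-cosine step from 0 to 1 over [start, start + width] (ms)."""
    x = np.clip((t - start) / max(width, 1e-9), 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * x)


def condition_envelopes(time_ms: np.ndarray,
                        schedule: StimulusSchedule | None = None,
                        av_pct: float = 98.0,
                        vis_pct: float | None = None,
                        aud_pct: float = 0.0,
                        enhancement_pct: float = 26.0,
                        divergence_onset_ms: float | None = 400.0,
                        rise_ms: float = 150.0,
                        divergence_rise_ms: float = 100.0,
                        fall_ms: float = 300.0,
                        sustain_end_ms: float = 1500.0) -> dict[str, np.ndarray]:
    """Build the three condition envelopes for one electrode.

    Plateaus are given as the broadband percent-change they should produce:
    an envelope gain g multiplies carrier amplitude, hence band power by g²,
    so g = sqrt(1 + pct/100).  The Vis envelope tracks AV until
    ``divergence_onset_ms`` and then transitions to the AV plateau plus
    ``enhancement_pct`` (or to an explicit ``vis_pct``).  The Aud envelope
    rises at the (mean) auditory onset instead of the mouth-movement onset.
    """
    schedule = schedule or StimulusSchedule()
    t = np.asarray(time_ms, float)
    if vis_pct is None:
        vis_pct = av_pct + enhancement_pct

    def gain(pct: float) -> float:
        if pct < -100.0:
            raise ValueError("plateau percent change cannot be below -100")
        return math.sqrt(1.0 + pct / 100.0)

    fall = 1.0 - _smoothstep(t, sustain_end_ms, fall_ms)

    def profile(pct: float, onset: float) -> np.ndarray:
        g = gain(pct)
        rise = _smoothstep(t, onset, rise_ms)
        return 1.0 + (g - 1.0) * rise * fall

    av = profile(av_pct, schedule.mean_mouth_onset_ms)
    if divergence_onset_ms is None:
        vis = profile(vis_pct, schedule.mean_mouth_onset_ms)
    else:
        extra = gain(vis_pct) - gain(av_pct)
        vis = av + extra * _smoothstep(t, divergence_onset_ms,
                                       divergence_rise_ms) * fall
    aud = profile(aud_pct, schedule.mean_auditory_onset_ms)
    return {"AV": av, "Vis": vis, "Aud": aud}


def speech_time_ms(acq: AcquisitionSpec | None = None,
                   epoch_ms: tuple[float, float] = (-700.0, 1600.0)) -> np.ndarray:
    """Sample grid of the speech-trial epoch (ms relative to video onset)."""
    acq = acq or AcquisitionSpec.speech_default()
    dt = 1000.0 / acq.sampling_rate
    n = int(round((epoch_ms[1] - epoch_ms[0]) / dt))
    return epoch_ms[0] + dt * np.arange(n)


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

@dataclass
class RFMappingSession:
    """One receptive-field mapping run.

    ``traces`` has shape (n_trials, n_electrodes, n_samples); ``trials`` has
    one row per trial (trial_id, pos_index, x_deg, y_deg).
    """

    acq: AcquisitionSpec
    grid: np.ndarray
    trials: pd.DataFrame
    traces: np.ndarray
    time_ms: np.ndarray
    electrodes: list[str]
    seed: int
    truth: list[GroundTruthElectrode] | None = None

    kind = "rf"

    def electrode_traces(self, electrode: str) -> np.ndarray:
        return self.traces[:, self.electrodes.index(electrode), :]


@dataclass
class SpeechSession:
    """One speech run: trials tagged with condition and word."""

    acq: AcquisitionSpec
    schedule: StimulusSchedule
    trials: pd.DataFrame
    traces: np.ndarray
    time_ms: np.ndarray
    electrodes: list[str]
    regions: list[str]
    seed: int
    truth: list[GroundTruthElectrode] | None = None

    kind = "speech"

    def electrode_traces(self, electrode: str) -> np.ndarray:
        return self.traces[:, self.electrodes.index(electrode), :]


def make_rf_session(truth: Sequence[GroundTruthElectrode],
                    grid: np.ndarray | None = None,
                    trials_per_pos: int = 24,
                    acq: AcquisitionSpec | None = None,
                    seed: int = 0,
                    epoch_ms: tuple[float, float] = (0.0, 500.0)) -> RFMappingSession:
    """Simulate a checkerboard mapping session.

    Each trial's trace is power-law background noise plus the biphasic evoked
    template scaled by ``evoked_gain`` times the electrode's ground-truth
    Gaussian evaluated at the flashed position.
    """
    truth = list(truth)
    if not truth:
        raise ValueError("empty electrode list")
    if trials_per_pos < 1:
        raise ValueError("trials_per_pos must be >= 1")
    acq = acq or AcquisitionSpec.rf_default()
    grid = default_grid() if grid is None else np.asarray(grid, float)
    half_w, half_h = DISPLAY_DEG[0] / 2, DISPLAY_DEG[1] / 2
    if np.any(np.abs(grid[:, 0]) > half_w) or np.any(np.abs(grid[:, 1]) > half_h):
        raise ValueError("grid positions fall outside the display bounds")

    rng = np.random.default_rng(seed)
    n_pos = len(grid)
    pos_index = np.repeat(np.arange(n_pos), trials_per_pos)
    rng.shuffle(pos_index)
    n_trials = len(pos_index)

    dt = 1000.0 / acq.sampling_rate
    n_samples = int(round((epoch_ms[1] - epoch_ms[0]) / dt))
    time_ms = epoch_ms[0] + dt * np.arange(n_samples)
    template = evoked_template(time_ms)

    traces = np.zeros((n_trials, len(truth), n_samples))
    for e, el in enumerate(truth):
        noise = powerlaw_background(rng, (n_trials,), n_samples, acq)
        if el.evoked_gain != 0 and el.rf_center is not None:
            amp = el.evoked_gain * gaussian_field(grid, el.rf_center, el.rf_sigma)
            noise += amp[pos_index, None] * template[None, :]
        traces[:, e, :] = noise

    trials = pd.DataFrame({
        "trial_id": np.arange(n_trials),
        "pos_index": pos_index,
        "x_deg": grid[pos_index, 0],
        "y_deg": grid[pos_index, 1],
    })
    return RFMappingSession(acq=acq, grid=grid, trials=trials, traces=traces,
                            time_ms=time_ms, electrodes=[el.name for el in truth],
                            seed=seed, truth=truth)


def make_speech_session(truth: Sequence[GroundTruthElectrode],
                        schedule: StimulusSchedule | None = None,
                        n_trials_per_cond: int = 32,
                        acq: AcquisitionSpec | None = None,
                        seed: int = 0,
                        conditions: Sequence[str] = CONDITIONS,
                        epoch_ms: tuple[float, float] = (-700.0, 1600.0),
                        carrier_sd: float = 1.0,
                        gain_scale: float = 0.2,
                        gain_independent_sd: float = 0.5) -> SpeechSession:
    """Simulate a speech session with latent-factor trial gains.

    Per electrode the trace is::

        background + carrier(t) * envelope(condition, t) * g_trial + line noise

    with ``g = exp(s*(λ·z + σ_η·η) - s²(λ² + σ_η²))`` so that E[g²] = 1
    (``s`` = ``gain_scale``); ``z`` is a standard-normal latent shared by all
    electrodes on a trial and ``η`` is electrode-specific.  Line noise is a
    common signal across electrodes (as mains pickup is), so common-average
    referencing removes it.
    """
    truth = list(truth)
    if not truth:
        raise ValueError("empty electrode list")
    if n_trials_per_cond < 1:
        raise ValueError("n_trials_per_cond must be >= 1")
    for c in conditions:
        if c not in CONDITIONS:
            raise ValueError(f"unknown condition label {c!r}")
    acq = acq or AcquisitionSpec.speech_default()
    schedule = schedule or StimulusSchedule()

    time_ms = speech_time_ms(acq, epoch_ms)
    n_samples = len(time_ms)
    for el in truth:
        if el.condition_envelopes is not None:
            for cond, env in el.condition_envelopes.items():
                if len(np.asarray(env)) != n_samples:
                    raise ValueError(
                        f"electrode {el.name!r}: envelope for {cond!r} has "
                        f"length {len(env)}, expected {n_samples}"
                    )

    rng = np.random.default_rng(seed)
    cond_labels = np.repeat(list(conditions), n_trials_per_cond)
    rng.shuffle(cond_labels)
    n_trials = len(cond_labels)
    words = rng.choice(schedule.words, size=n_trials)
    z = rng.standard_normal(n_trials)  # shared latent trial factor

    # common mains pickup: one phase per (trial, line), shared by electrodes
    phases = rng.uniform(0, 2 * np.pi, size=(n_trials, len(acq.line_freqs)))
    t_s = time_ms / 1000.0
    line = np.zeros((n_trials, n_samples))
    for k, (f0, a0) in enumerate(zip(acq.line_freqs, acq.line_amplitudes)):
        line += a0 * np.sin(2 * np.pi * f0 * t_s[None, :] + phases[:, k, None])

    flat = np.ones(n_samples)
    traces = np.empty((n_trials, len(truth), n_samples))
    for e, el in enumerate(truth):
        envs = el.condition_envelopes or {}
        env_mat = np.stack([np.asarray(envs.get(c, flat), float)
                            for c in cond_labels])
        lam = el.factor_loading
        eta = rng.standard_normal(n_trials)
        s = gain_scale
        g = np.exp(s * (lam * z + gain_independent_sd * eta)
                   - s**2 * (lam**2 + gain_independent_sd**2))
        bg = powerlaw_background(rng, (n_trials,), n_samples, acq)
        carrier = bandlimited_carrier(rng, (n_trials,), n_samples,
                                      acq.sampling_rate, sd=carrier_sd)
        traces[:, e, :] = bg + carrier * env_mat * g[:, None] + line

    trials = pd.DataFrame({
        "trial_id": np.arange(n_trials),
        "condition": cond_labels,
        "word": words,
    })
    return SpeechSession(acq=acq, schedule=schedule, trials=trials,
                         traces=traces, time_ms=time_ms,
                         electrodes=[el.name for el in truth],
                         regions=[el.region for el in truth],
                         seed=seed, truth=truth)


# ---------------------------------------------------------------------------
# truth factories for typical electrode profiles
# ---------------------------------------------------------------------------

def visual_electrode(name: str, rf_center: tuple[float, float],
                     time_ms: np.ndarray,
                     rf_sigma: tuple[float, float] = (2.0, 2.0),
                     evoked_gain: float = 90.0,
                     av_pct: float = 98.0,
                     enhancement_pct: float = 26.0,
                     divergence_onset_ms: float | None = 400.0,
                     factor_loading: float = 0.8,
                     schedule: StimulusSchedule | None = None) -> GroundTruthElectrode:
    """Visual-cortex profile: retinotopic RF, no Aud response, Vis>AV divergence."""
    envs = condition_envelopes(time_ms, schedule, av_pct=av_pct, aud_pct=0.0,
                               enhancement_pct=enhancement_pct,
                               divergence_onset_ms=divergence_onset_ms)
    return GroundTruthElectrode(name=name, region="visual", rf_center=rf_center,
                                rf_sigma=rf_sigma, evoked_gain=evoked_gain,
                                condition_envelopes=envs,
                                divergence_onset_ms=divergence_onset_ms,
                                factor_loading=factor_loading)


def frontal_electrode(name: str, time_ms: np.ndarray,
                      av_pct: float = 33.0, vis_pct: float = 53.0,
                      aud_pct: float = 26.0,
                      divergence_onset_ms: float | None = 540.0,
                      factor_loading: float = 1.0,
                      schedule: StimulusSchedule | None = None) -> GroundTruthElectrode:
    """Frontal profile: responds to all conditions, early Vis>AV divergence."""
    envs = condition_envelopes(time_ms, schedule, av_pct=av_pct, vis_pct=vis_pct,
                               aud_pct=aud_pct,
                               divergence_onset_ms=divergence_onset_ms)
    return GroundTruthElectrode(name=name, region="frontal",
                                condition_envelopes=envs,
                                divergence_onset_ms=divergence_onset_ms,
                                factor_loading=factor_loading)


def auditory_electrode(name: str, time_ms: np.ndarray,
                       av_pct: float = 41.0, vis_pct: float = 9.0,
                       aud_pct: float = 42.0,
                       factor_loading: float = 0.2,
                       schedule: StimulusSchedule | None = None) -> GroundTruthElectrode:
    """Auditory (STG) profile: strong AV/Aud response, weak Vis, no divergence."""
    envs = condition_envelopes(time_ms, schedule, av_pct=av_pct, vis_pct=vis_pct,
                               aud_pct=aud_pct, divergence_onset_ms=None)
    return GroundTruthElectrode(name=name, region="auditory",
                                condition_envelopes=envs,
                                divergence_onset_ms=None,
                                factor_loading=factor_loading)
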