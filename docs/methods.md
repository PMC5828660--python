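# Methods

This note documents the generative models behind `gazefield`'s synthetic
sessions, the analysis procedures, the defaults and why they were chosen,
and what the validation experiments do and do not establish.

## Synthetic sessions

### Acquisition model

Signals are generated at 2 kHz within a 0.3–500 Hz amplifier band, in
arbitrary voltage units. The background process has the knee-form spectrum
typical of neural field potentials,

    S(f) ∝ 1 / (1 + (f / f_knee)^α),       f_knee = 10 Hz, α = 2,

flat below the knee and falling as 1/f² above it, scaled to a total SD of
`noise_floor` (40 units for mapping sessions, 0.5 for speech sessions,
where the high-gamma carrier has unit SD). A pure power-law background was
rejected because its variance is almost entirely sub-5 Hz drift, which
drowns the 100–300 ms evoked window means at any amplitude compatible with
the 3-SD voltage artifact rule. Mains pickup is added as 60/120/180 Hz
sinusoids (amplitudes 0.3/0.15/0.1, random phase per trial) *common to all
electrodes*, so common-average referencing removes it exactly, as it does
for shared artifacts in real montages. Spectral shaping is done in the
frequency domain with an analytic (Parseval) normalization, so a given
seed yields bit-identical sessions.

### Receptive-field mapping sessions

A 9 × 7 grid with 3° spacing (spanning 27° × 21° of the 30.5° × 22.9°
display, fixation at center) is flashed in random order, 24 trials per
position by default (within the protocol's 12–30 range). Each 0–500 ms
trial epoch contains background noise plus a biphasic evoked template — a
positive complex at 160 ms (σ = 55 ms) spanning most of the 100–300 ms
averaging window, followed by a 0.5-amplitude negative rebound at 380 ms —
scaled by `evoked_gain` times an axis-aligned 2-D Gaussian (the ground-
truth receptive field) evaluated at the flashed position. The default gain
(90–120 units against the 40-unit floor) keeps single-trial evoked peaks
below the 3-SD artifact threshold, the regime the protocol's low discard
counts imply.

One consequence is worth stating plainly: a hard "any raw sample beyond
3 pooled SD" rule applied to a *Gaussian* background sampled at 2 kHz
fires often (the background's ~56 Hz RMS bandwidth implies ≈0.6 threshold
crossings per 0.5 s trial), and the generator's measured discard fraction
is ≈30% per electrode. Real recordings discard far fewer trials because
their voltage distributions are not Gaussian-tail-dominated at 3 SD. The
discards here are signal-independent, so they reduce the effective trial
count uniformly without biasing the maps; receptive-field recovery is
unaffected (see Validation).

### Speech sessions

Trials (epoch −700..+1600 ms around video onset) mix the three conditions
in equal, seed-shuffled numbers (default 32 per condition; protocol range
32–64), each tagged with one of the four words whose printed timings give
mouth-movement onsets of 200/233/200/200 ms and auditory onsets of
267/233/300/333 ms (mean 283.25 ms). One printed pair ('known', 233/233)
has the mouth movement starting *with* the vocalization, so the schedule
invariant is mouth ≤ auditory, not strictly less.

Each electrode's trace is

    background + carrier(t) · env_c(t) · g_t + line noise,

where `carrier` is unit-SD Gaussian noise band-limited to 70–150 Hz (4th-
order Butterworth magnitude, squared as a zero-phase response), `env_c` is
the condition's amplitude envelope, and `g_t` is a lognormal per-trial
gain,

    g_t = exp(s·(λ·z_t + σ_η·η_t) − s²·(λ² + σ_η²)),

with `z_t` a standard-normal latent factor shared by all electrodes on a
trial, `η_t` electrode-specific, `s = 0.2`, `σ_η = 0.5`, and λ the
electrode's loading (0–1). The correction term fixes E[g²] = 1, so gains
modulate trial-to-trial power without biasing condition means. This
latent-factor copula is the generative counterpart of trial-by-trial power
correlation: the population rank correlation between two electrodes'
powers is an increasing function of λ₁λ₂ (exactly, Pearson correlation of
log-powers λ₁λ₂/√((λ₁²+σ_η²)(λ₂²+σ_η²))). At λ₁ = λ₂ = 1 this predicts
Spearman ρ ≈ 0.78 before estimation noise; the measured calibration value
at 48–64 trials is ≈0.73. Note the population ρ is *not* a function of the
product alone for unequal loadings, so the monotonicity calibration uses
the equal-loading diagonal λ ∈ {0, 0.25, 0.5, 1}.

Envelopes are condition-level gain profiles: g = √(1 + pct/100) converts a
target plateau percent-change into an amplitude gain. AV rises at the mean
mouth-movement onset (150 ms raised-cosine ramp), Vis tracks AV until its
`divergence_onset_ms` and then transitions (100 ms) to the AV plateau plus
the enhancement, Aud rises at the mean auditory onset; all decay back to
baseline after 1500 ms. Default plateaus follow the magnitudes typical of
this preparation: mouth-region visual electrodes 98% AV with +26%
Vis enhancement, non-mouth 33% with +2%, frontal 33/53/26%, auditory
41/9/42%. Per-word envelope variation is not modelled — words affect only
trial metadata and relative-latency bookkeeping.

What the generator does *not* emulate: epileptiform artifacts, non-
stationary background power, evoked (phase-locked) components in speech
trials, oscillatory (narrowband) rhythms beyond the background spectrum,
per-word envelope differences, and volume-conduction correlations between
neighbouring electrodes. Passing recovery tests therefore show that the
analysis chain is correct and well-calibrated under a plausible signal
model, not that it is robust to every pathology of clinical data.

## Analysis stages

**Receptive-field mapping.** The voltage-outlier rule pools mean and SD
over all samples of all of an electrode's trials (the per-timepoint
alternative would make the threshold depend on stimulus position). The
Savitzky–Golay filter is `scipy.signal.savgol_filter` (order 5, frame 11).
Grid positions left without retained trials are excluded from the fit
rather than imputed. The Gaussian fit is axis-aligned with independent
σx, σy plus offset (6 parameters) — rotation is omitted for
identifiability on a 7 × 9 grid — initialized at the map argmax with σ at
one grid spacing and offset at the map minimum, with 5 jittered restarts;
non-convergence from every start yields a rejected label with a
diagnostic. Fit quality is the Pearson correlation between fitted surface
and map (Spearman would ignore the amplitude structure the criterion is
meant to capture); r ≤ 0.7 rejects. Eccentricity is the Euclidean distance
from the fitted center to the mouth-center reference — the fixation point
in the main design, a displaced coordinate when the mouth is parafoveal —
and the 5° mouth boundary is strict (exactly 5° is non-mouth).

**Broadband estimation.** Common-average referencing is applied across
electrodes before notch filtering and epoch analysis; it is a config
switch (`car`) because with only two or three (synthetic) electrodes the
"reference" is mostly the other electrode's signal rather than a shared
artifact. Notches are zero-phase 2nd-order Butterworth band-stops with
2 Hz half-width. The multitaper transform uses K = 3 Slepian tapers
(2·0.2 s·10 Hz − 1), 200 ms windows hopped 10 ms, FFTs zero-padded to put
bins exactly on the 2 Hz grid from 10–200 Hz; windows that would extend
past the epoch are simply not produced (no zero padding), so the time grid
runs from −600 to +1500 ms. Percent change is computed per frequency bin
against the bin's baseline (mean over −500..−100 ms of *all* trials of
*all* conditions) and then averaged over the 70–150 Hz bins;
normalizing before averaging prevents the 1/f-dominated low bins from
swamping the band mean. A zero baseline in any band bin raises a
degenerate-signal error rather than producing infinities. The trial-
rejection rule compares each trial at each post-stimulus time point
against the mean and SD of the *other* trials (leave-one-out) and
discards the whole trial on any exceedance beyond 10 SD; it operates on
the broadband trace, not per-frequency power.

**Selection.** The responsiveness test is a two-sided one-sample t test of
per-trial 200–1500 ms window means against zero — the simplest test
consistent with using mean window amplitude as the response measure; only
AV trials are tested so Vis/Aud contrasts remain unbiased. The
Benjamini–Hochberg step-up is applied per region within a session (the
natural FDR family here). Zero-variance inputs resolve by sign (p = 0 for
a nonzero mean, else 1) and are logged. The frontal seed maximizes μ/σ of
the window means among FDR-passing candidates — an electrode must first
be significantly responsive before it can be a seed — with ties broken to
the lowest index.

**Connectivity.** Spearman ρ with mid-rank ties (continuous powers make
ties rare; the rule is fixed for reproducibility) and the t-approximation
p-value; constant series are flagged undefined rather than given a value.
Trials discarded in either electrode are dropped pairwise, and pairs with
fewer than 3 common retained trials are skipped. Trials pool all words
within a condition.

**Latency.** The running test is a one-sided Welch t test (the hypothesis
is directional — a *greater* Vis response — and variance equality is not
assumable); zero-variance time points resolve by comparing means. Onset is
the first grid time with p < α for every 10 ms step in [t, t + 200 ms),
reported at multitaper window centers. Relative latency subtracts the mean
auditory onset (283.25 ms) since trials pool words.

**Mixed model.** One row per (electrode, condition); treatment coding
against the (AV, mouth) cell; interaction columns dropped (and flagged)
when only one electrode type is present; a missing expected level is an
error naming the level. Fitting is REML via statsmodels `MixedLM`. The
Satterthwaite denominator df — the source of the fractional df such
analyses report — is computed in-package from the closed-form
random-intercept REML log-likelihood: for coefficient j,
df = 2·f², ÷ (∇f' A ∇f), where f(θ) is the j-th diagonal of
(X'V(θ)⁻¹X)⁻¹, θ = (σ²_b, σ²_ε), and A is the inverse observed REML
information (central finite differences, one-sided at the σ²_b ≥ 0
boundary); df is capped at the fixed-effects residual df. This matches
lme4/lmerTest to ~7 significant digits on shared data (tested).
Degenerate inputs — zero residual variance, or a singular random-effects
fit — fall back to OLS with residual df and are flagged; for balanced
designs the fixed-effect estimates coincide with GLS regardless, which is
why zero-noise balanced data reproduce cell-mean differences exactly.

## Validation experiments and problem sizes

The calibration module regenerates data from known truth and re-analyzes
it; `scripts/acceptance.py` runs the full set in a few minutes on one CPU.
Sizes were chosen as the smallest that make the Monte-Carlo error
comfortably smaller than the decision margins: 100 electrodes for RF
recovery (median center error ≈0.29°, label agreement ≈96%); 100 seeds per
level for the connectivity loading grid and 1000 pairs at n = 48 trials
for the null false-positive rate (≈0.05); 100 seeds for onset recovery
(median |error| ≈20–30 ms for a 500 ms divergence) and onset ordering
(≈96% correct for 450 vs 700 ms); 500 replicates of 50 electrodes for CI
coverage (≈95%). Connectivity calibrations measure per-trial power with a
direct band-pass + mean-square estimator rather than the multitaper chain:
Spearman ρ is invariant to the monotone relation between the two
estimators, and the multitaper route is exercised on single sessions in
the test suite. Onset-recovery electrodes use a divergence of ≈3 trial-SD
("high SNR"), since the question is timing calibration, not detection
power; the ±100 ms recovery margin absorbs the two opposing systematic
effects of the 200 ms spectral window (early leakage) and the 100 ms
envelope ramp (late crossing).

## Known limitations

* The generator's Gaussian tails make the 3-SD voltage rule discard ≈30%
  of mapping trials (see above); treat the rule's discard *fraction* as
  model-dependent even though the rule itself is implemented exactly.
* Onset estimates are biased early by up to one window half-width when
  divergences are strong, and late for weak divergences (persistence
  gating); only the net calibration within ±100 ms is claimed.
* The latent-factor copula produces exchangeable trial gains; real
  session-level nonstationarities (drowsiness, medication) induce
  autocorrelated gains that would inflate correlations between electrodes
  sharing slow trends.
* Satterthwaite df are computed for the random-intercept model only;
  random slopes and crossed random effects are out of scope.
* Real-data ingestion (clinical amplifier formats, BIDS-iEEG) is not
  implemented; sessions enter through the package's own HDF5+JSON format.
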