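"""Generator contracts: determinism, degenerate configs, spectral content."""

import numpy as np
import pytest
from scipy import signal as sps

from gazefield import synth


class TestAcquisitionAndSchedule:
    def test_sampling_rate_must_clear_lowpass(self):
        with pytest.raises(ValueError, match="lowpass"):
            synth.AcquisitionSpec(sampling_rate=900.0, lowpass_cutoff=500.0)

    def test_line_freqs_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            synth.AcquisitionSpec(line_freqs=(120.0, 60.0, 180.0),
                                  line_amplitudes=(0.1, 0.1, 0.1))

    def test_word_timing_order_enforced(self):
        with pytest.raises(ValueError, match="auditory"):
            synth.StimulusSchedule(auditory_onset_ms=(100.0, 233.0, 300.0, 333.0))

    def test_mean_auditory_onset(self):
        sched = synth.StimulusSchedule()
        assert sched.mean_auditory_onset_ms == pytest.approx(283.25)
        assert sched.auditory_onset_for("meant") == 333.0


class TestRFSession:
    def test_zero_gain_zero_noise_gives_silent_traces(self):
        truth = synth.GroundTruthElectrode(name="e0", evoked_gain=0.0)
        acq = synth.AcquisitionSpec(noise_floor=0.0)
        ses = synth.make_rf_session([truth], trials_per_pos=2, acq=acq, seed=0)
        assert np.all(ses.traces == 0.0)

    def test_same_seed_bit_identical(self, rf_truth):
        a = synth.make_rf_session([rf_truth], trials_per_pos=3, seed=5)
        b = synth.make_rf_session([rf_truth], trials_per_pos=3, seed=5)
        assert np.array_equal(a.traces, b.traces)
        assert a.trials.equals(b.trials)

    def test_different_seed_differs(self, rf_truth):
        a = synth.make_rf_session([rf_truth], trials_per_pos=3, seed=5)
        b = synth.make_rf_session([rf_truth], trials_per_pos=3, seed=6)
        assert not np.array_equal(a.traces, b.traces)

    def test_grid_argmax_matches_truth_center(self, rf_truth):
        """High gain, low noise: the mean-response argmax falls on the grid
        cell containing the generating center (3°, 1°) -> cell (3, 0)."""
        acq = synth.AcquisitionSpec(noise_floor=1.0)
        ses = synth.make_rf_session([rf_truth], trials_per_pos=4, acq=acq, seed=1)
        win = (ses.time_ms >= 100) & (ses.time_ms <= 300)
        means = np.zeros(len(ses.grid))
        tr = ses.electrode_traces("e0")
        for p in range(len(ses.grid)):
            sel = ses.trials["pos_index"].to_numpy() == p
            means[p] = tr[sel][:, win].mean()
        # oracle: the generating Gaussian evaluated on the grid
        oracle = synth.gaussian_field(ses.grid, (3.0, 1.0), (2.0, 2.0))
        assert np.argmax(means) == np.argmax(oracle)

    def test_rejects_bad_inputs(self, rf_truth):
        with pytest.raises(ValueError, match="empty"):
            synth.make_rf_session([], seed=0)
        with pytest.raises(ValueError, match="trials_per_pos"):
            synth.make_rf_session([rf_truth], trials_per_pos=0)
        with pytest.raises(ValueError, match="display"):
            synth.make_rf_session([rf_truth], grid=np.array([[40.0, 0.0]]))


class TestSpeechSession:
    def test_unknown_condition_label(self):
        tm = synth.speech_time_ms()
        truth = [synth.visual_electrode("v0", (0, 0), tm)]
        with pytest.raises(ValueError, match="unknown condition"):
            synth.make_speech_session(truth, conditions=("AV", "Tactile"))

    def test_envelope_length_mismatch(self):
        tm = synth.speech_time_ms()
        bad = synth.GroundTruthElectrode(
            name="v0", condition_envelopes={"AV": np.ones(10)})
        with pytest.raises(ValueError, match="length"):
            synth.make_speech_session([bad])

    def test_same_seed_bit_identical(self):
        tm = synth.speech_time_ms()
        truth = [synth.visual_electrode("v0", (0, 0), tm)]
        a = synth.make_speech_session(truth, n_trials_per_cond=3, seed=9)
        b = synth.make_speech_session(truth, n_trials_per_cond=3, seed=9)
        assert np.array_equal(a.traces, b.traces)
        assert a.trials.equals(b.trials)

    def test_balanced_shuffled_conditions(self):
        tm = synth.speech_time_ms()
        truth = [synth.visual_electrode("v0", (0, 0), tm)]
        ses = synth.make_speech_session(truth, n_trials_per_cond=5, seed=3)
        counts = ses.trials["condition"].value_counts()
        assert set(counts.index) == {"AV", "Vis", "Aud"}
        assert (counts == 5).all()

    def test_spectral_content_dominated_by_band(self):
        """No background, constant envelope: >=90% of power in 70-150 Hz."""
        acq = synth.AcquisitionSpec(noise_floor=0.0)
        truth = [synth.GroundTruthElectrode(name="c0"),
                 synth.GroundTruthElectrode(name="c1")]
        ses = synth.make_speech_session(truth, n_trials_per_cond=4, acq=acq,
                                        seed=3, gain_scale=0.0)
        trace = ses.electrode_traces("c0").ravel()
        f, pxx = sps.periodogram(trace, fs=acq.sampling_rate)
        in_band = (f >= 70) & (f <= 150)
        assert pxx[in_band].sum() / pxx.sum() >= 0.90

    def test_envelope_plateau_sets_band_power(self):
        """Envelope gain g scales band power by ~g² (checked at g=2)."""
        tm = synth.speech_time_ms()
        acq = synth.AcquisitionSpec(noise_floor=0.0)
        env = np.ones_like(tm)
        env[tm >= 0] = 2.0
        truth = [synth.GroundTruthElectrode(
            name="c0", condition_envelopes={"AV": env})]
        ses = synth.make_speech_session(truth, n_trials_per_cond=6, acq=acq,
                                        conditions=("AV",), seed=4,
                                        gain_scale=0.0)
        tr = ses.electrode_traces("c0")
        pre = (tm >= -600) & (tm <= -100)
        post = (tm >= 300) & (tm <= 1200)
        ratio = (tr[:, post] ** 2).mean() / (tr[:, pre] ** 2).mean()
        assert ratio == pytest.approx(4.0, rel=0.15)


class TestCouplingLink:
    def test_shared_factor_induces_rank_correlation(self):
        """λ=1 on both electrodes couples their per-trial band powers;
        λ=0 leaves them uncorrelated (empirical |ρ| < 0.25 at n=64)."""
        from gazefield.calibration import _pair_trial_powers
        from gazefield.connectivity import spearman

        x, y = _pair_trial_powers(1.0, 1.0, 64, seed=21)
        rho, _, _ = spearman(x, y)
        assert rho >= 0.6
        x, y = _pair_trial_powers(0.0, 0.0, 64, seed=22)
        rho, _, _ = spearman(x, y)
        assert abs(rho) < 0.25
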