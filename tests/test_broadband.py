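"""Broadband pipeline: CAR, notch, multitaper, percent change, outliers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazefield import broadband, synth

FS = 2000.0


class TestCommonAverageReference:
    def test_identical_signals_cancel(self):
        x = np.tile(np.sin(np.linspace(0, 10, 100)), (4, 1))
        assert np.allclose(broadband.common_average_reference(x), 0.0)

    def test_two_electrode_closed_form(self):
        a, b = np.arange(10.0), np.arange(10.0)[::-1].copy()
        out = broadband.common_average_reference(np.stack([a, b]))
        assert np.allclose(out[0], (a - b) / 2)
        assert np.allclose(out[1], (b - a) / 2)

    def test_per_sample_mean_exactly_zero(self):
        x = np.random.default_rng(0).standard_normal((6, 500))
        out = broadband.common_average_reference(x)
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-12)

    def test_single_electrode_error(self):
        with pytest.raises(ValueError, match="2 electrodes"):
            broadband.common_average_reference(np.zeros((1, 10)))


class TestNotch:
    def test_60hz_attenuated_100hz_passed(self):
        t = np.arange(int(FS)) / FS
        tone60 = np.sin(2 * np.pi * 60 * t)
        tone100 = np.sin(2 * np.pi * 100 * t)
        out60 = broadband.notch_line_noise(tone60, FS)
        out100 = broadband.notch_line_noise(tone100, FS)
        rms = lambda x: np.sqrt((x[200:-200] ** 2).mean())
        assert rms(out60) <= 0.1 * rms(tone60)       # >= 20 dB at the notch
        assert rms(out100) >= 0.89 * rms(tone100)    # < 1 dB in the passband

    def test_zero_in_zero_out(self):
        assert np.allclose(broadband.notch_line_noise(np.zeros(1000), FS), 0.0)

    def test_notch_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            broadband.notch_line_noise(np.zeros(1000), 300.0, freqs=(150.0,))


class TestMultitaper:
    def test_taper_count_from_smoothing_parameters(self):
        assert broadband.slepian_taper_count(200.0, 10.0) == 3

    def test_zero_signal_zero_power(self):
        time_ms = -500 + 0.5 * np.arange(3000)
        tfr = broadband.multitaper_tfr(np.zeros(3000), FS, time_ms)
        assert np.allclose(tfr.power, 0.0)
        assert tfr.freqs[0] == 10.0 and tfr.freqs[-1] == 200.0
        assert np.allclose(np.diff(tfr.freqs), 2.0)
        assert np.allclose(np.diff(tfr.times), 10.0)

    def test_sinusoid_concentrates_at_its_frequency(self):
        time_ms = 0.5 * np.arange(4000)
        tone = np.sin(2 * np.pi * 100 * time_ms / 1000.0)
        tfr = broadband.multitaper_tfr(tone, FS, time_ms)
        peak_freqs = tfr.freqs[np.argmax(tfr.power, axis=1)]
        assert np.all(peak_freqs == 100.0)

    def test_variance_step_doubles_band_power(self):
        """Doubling the carrier variance at t0 doubles band power within
        one window of t0 (analytic envelope oracle, ±20%)."""
        rng = np.random.default_rng(5)
        time_ms = -500 + 0.5 * np.arange(6000)
        carrier = synth.bandlimited_carrier(rng, (), 6000, FS)
        env = np.where(time_ms >= 1000.0, np.sqrt(2.0), 1.0)
        tfr = broadband.multitaper_tfr(carrier * env, FS, time_ms)
        band = (tfr.freqs >= 70) & (tfr.freqs <= 150)
        bp = tfr.power[:, band].mean(axis=1)
        before = bp[(tfr.times > 0) & (tfr.times < 900)].mean()
        after = bp[(tfr.times > 1100) & (tfr.times < 2000)].mean()
        assert after / before == pytest.approx(2.0, rel=0.2)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="resolve"):
            broadband.multitaper_tfr(np.zeros(500), 300.0, np.arange(500))


class TestPercentChange:
    def _tfr_stack(self, n_trials=4, n_times=50, n_freqs=96, fill=1.0):
        times = -500 + 10.0 * np.arange(n_times)
        freqs = 10 + 2.0 * np.arange(n_freqs)
        power = np.full((n_trials, n_times, n_freqs), fill)
        return power, times, freqs

    def test_power_equal_to_baseline_gives_zero(self):
        power, times, freqs = self._tfr_stack()
        pct = broadband.percent_change_matrix(power, times, freqs)
        assert np.allclose(pct, 0.0)

    def test_zero_baseline_is_degenerate(self):
        power, times, freqs = self._tfr_stack(fill=0.0)
        with pytest.raises(broadband.DegenerateSignalError):
            broadband.percent_change_matrix(power, times, freqs)

    def test_known_step_recovered(self):
        power, times, freqs = self._tfr_stack()
        power[:, times >= 0, :] *= 3.0
        pct = broadband.percent_change_matrix(power, times, freqs)
        assert np.allclose(pct[:, times >= 0], 200.0)
        assert np.allclose(pct[:, times < 0], 0.0)

    def test_amplifier_gain_invariance(self, speech_session):
        """Percent change is unchanged when raw voltages are rescaled."""
        import copy
        bb1 = broadband.process_session(speech_session, car=False)
        scaled = copy.copy(speech_session)
        scaled.traces = speech_session.traces * 7.3
        bb2 = broadband.process_session(scaled, car=False)
        assert np.allclose(bb1.pct["v0"], bb2.pct["v0"], atol=1e-8)

    def test_stationary_signal_hovers_near_zero(self, speech_bb):
        """With a flat envelope (Aud trials of visual electrodes) the mean
        post-stimulus pct stays near zero."""
        aud = speech_bb.condition_matrix("v0", "Aud")
        post = speech_bb.times >= 0
        assert abs(aud[:, post].mean()) < 15.0


class TestPowerOutliers:
    def _tc(self, pct, trial_id, cond="AV"):
        times = -500 + 10.0 * np.arange(len(pct))
        return broadband.BroadbandTimecourse(times=times, pct=np.asarray(pct, float),
                                             trial_id=trial_id, condition=cond)

    def test_identical_trials_kept(self):
        tcs = [self._tc(np.full(100, 5.0), i) for i in range(5)]
        out = broadband.reject_power_outliers(tcs)
        assert all(tc.retained for tc in out)

    def test_spike_trial_discarded(self):
        """A 15-SD spike: verify against hand-computed leave-one-out stats."""
        rng = np.random.default_rng(6)
        pct = rng.standard_normal((8, 100))
        times = -500 + 10.0 * np.arange(100)
        post = times >= 0
        j = np.nonzero(post)[0][10]
        others = pct[[i for i in range(8) if i != 2], j]
        pct[2, j] = others.mean() + 15.0 * others.std(ddof=1)
        tcs = [self._tc(row, i) for i, row in enumerate(pct)]
        out = broadband.reject_power_outliers(tcs, k=10.0)
        assert [tc.retained for tc in out] == [i != 2 for i in range(8)]

    def test_matches_brute_force_loo(self):
        """Vectorized rule equals per-trial recomputation on random input."""
        rng = np.random.default_rng(7)
        for k in (1.5, 2.0, 3.0):
            pct = rng.standard_normal((9, 40))
            mask = broadband.loo_outlier_mask(pct, k=k)
            brute = np.ones(9, bool)
            for i in range(9):
                rest = np.delete(pct, i, axis=0)
                m = rest.mean(axis=0)
                s = rest.std(axis=0, ddof=1)
                brute[i] = not np.any(np.abs(pct[i] - m) > k * s)
            assert np.array_equal(mask, brute)

    def test_too_few_trials(self):
        with pytest.raises(ValueError, match="3 trials"):
            broadband.loo_outlier_mask(np.zeros((2, 10)))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        pct = rng.standard_normal((7, 30)) * 3
        pct[rng.integers(7)] += rng.uniform(0, 30)
        perm = rng.permutation(7)
        mask = broadband.loo_outlier_mask(pct, k=2.0)
        mask_perm = broadband.loo_outlier_mask(pct[perm], k=2.0)
        assert np.array_equal(mask_perm, mask[perm])


class TestProcessSession:
    def test_empty_session_rejected(self):
        import pandas as pd
        empty = synth.SpeechSession(
            acq=synth.AcquisitionSpec(), schedule=synth.StimulusSchedule(),
            trials=pd.DataFrame({"trial_id": [], "condition": [], "word": []}),
            traces=np.zeros((0, 0, 100)), time_ms=np.arange(100.0),
            electrodes=[], regions=[], seed=0)
        with pytest.raises(ValueError, match="no electrodes"):
            broadband.process_session(empty)

    def test_store_round_trip(self, speech_bb, tmp_path):
        path = speech_bb.save(tmp_path / "bb.h5")
        loaded = broadband.BroadbandSet.load(path)
        assert loaded.electrodes == speech_bb.electrodes
        assert np.array_equal(loaded.times, speech_bb.times)
        for name in speech_bb.electrodes:
            assert np.array_equal(loaded.pct[name], speech_bb.pct[name])
            assert np.array_equal(loaded.retained[name], speech_bb.retained[name])
        assert loaded.trials["condition"].tolist() == \
            speech_bb.trials["condition"].tolist()
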