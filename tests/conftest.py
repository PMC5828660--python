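import numpy as np
import pytest

from gazefield import broadband, synth


@pytest.fixture(scope="session")
def rf_truth():
    return synth.GroundTruthElectrode(
        name="e0", rf_center=(3.0, 1.0), rf_sigma=(2.0, 2.0), evoked_gain=90.0)


@pytest.fixture(scope="session")
def rf_session(rf_truth):
    return synth.make_rf_session([rf_truth], seed=7)


@pytest.fixture(scope="session")
def speech_session():
    """Two strongly coupled visual electrodes, all three conditions."""
    tm = synth.speech_time_ms()
    truth = [synth.visual_electrode(f"v{i}", rf_center=(0.0, 0.0),
                                    time_ms=tm, factor_loading=1.0)
             for i in range(2)]
    return synth.make_speech_session(truth, n_trials_per_cond=8, seed=11)


@pytest.fixture(scope="session")
def speech_bb(speech_session):
    return broadband.process_session(speech_session, car=False)


@pytest.fixture(scope="session")
def selection_bb():
    """Moderate-coupling electrodes with enough AV trials for stable
    responsiveness statistics."""
    tm = synth.speech_time_ms()
    truth = [synth.visual_electrode(f"v{i}", rf_center=(0.0, 0.0),
                                    time_ms=tm, factor_loading=0.3)
             for i in range(2)]
    session = synth.make_speech_session(truth, n_trials_per_cond=16, seed=17,
                                        conditions=("AV",))
    return broadband.process_session(session, car=False)
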