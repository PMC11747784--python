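import numpy as np
import pytest

from ssvep_cvd import Recording, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_sim_config():
    """Reduced trial count for fast end-to-end tests; signal model unchanged."""
    return SimConfig(n_trials_per_session=3, artifact_rate=0.0)


@pytest.fixture
def toy_recording(rng):
    """20 s, 4-channel recording: 10 s stimulation then 10 s rest."""
    fs = 250.0
    n = 5000
    data = rng.standard_normal((4, n))
    trigger = np.concatenate([np.zeros(2500, dtype=int), np.ones(2500, dtype=int)])
    return Recording(
        data=data, trigger=trigger, fs=fs, meta={"subject_id": "S1"}
    )
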