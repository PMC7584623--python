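import numpy as np
import pytest

from floatbloom import pipeline, synthetic


@pytest.fixture(scope="session")
def small_config():
    """Noise-free 6-float, 2-year array used by several integration tests."""
    return synthetic.TruthConfig(n_floats=6, n_years=2, seed=7).noise_free()


@pytest.fixture(scope="session")
def small_dataset(small_config):
    truth = synthetic.simulate_truth(small_config)
    profiles = synthetic.emit_float_profiles(truth, small_config)
    return truth, profiles


@pytest.fixture(scope="session")
def small_pipeline(small_dataset):
    truth, profiles = small_dataset
    derived, rate_series, climatology = pipeline.run_pipeline(profiles)
    return truth, derived, rate_series, climatology


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
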