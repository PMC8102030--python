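import numpy as np
import pytest

from herbdiff.compounds import PEAK_COMPOUNDS, zero_intercept_registry
from herbdiff.fingerprint import match_common_peaks
from herbdiff.simulate import GeneratorConfig, default_profiles, generate_sample_set


@pytest.fixture(scope="session")
def gen_cfg():
    return GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def sample_set(gen_cfg):
    """Default two-class synthetic sample set with its generating truth."""
    return generate_sample_set(default_profiles(), gen_cfg, return_truth=True)


@pytest.fixture(scope="session")
def fp_matrix(sample_set):
    tables, _ = sample_set
    return match_common_peaks(tables)


@pytest.fixture(scope="session")
def noiseless_world():
    """Zero-noise, zero-intercept conditions under which quantification is
    exact: (registry, config, tables, truth)."""
    registry = zero_intercept_registry(PEAK_COMPOUNDS)
    cfg = GeneratorConfig(seed=11, n_cm=5, n_ci=5, area_cv=0.0, rt_jitter_sd=0.0)
    tables, truth = generate_sample_set(default_profiles(), cfg, compounds=registry, return_truth=True)
    return registry, cfg, tables, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
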