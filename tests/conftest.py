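import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from jointeffects.effects import FilterConfig, growth_by_community
from jointeffects.synthetic import SyntheticConfig, generate_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def noise_free_bundle():
    """Small scenario with all noise off: estimates must equal truth."""
    cfg = SyntheticConfig(
        n_affecting=6,
        n_focal=1,
        measurement_cv=0.0,
        joint_noise_sd=0.0,
        autofluorescence_scale=0.0,
        truth_rule="strongest",
        seed=11,
    )
    return generate_scenario(cfg)


@pytest.fixture(scope="session")
def noise_free_growth(noise_free_bundle):
    return growth_by_community(noise_free_bundle["wells"], FilterConfig(min_replicates=1))
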