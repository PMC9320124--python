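import numpy as np
import pytest

from bandcoda.cohort import center_age_by_group, exclusion_cascade
from bandcoda.simulate import GeneratorConfig, generate_cohort, inject_missingness

#: printed all-sample geometric means (min/day); sum 960.1, closed in fixtures
ALL_SAMPLE_GM = np.array([722.9, 105.7, 51.1, 27.8, 15.4, 9.1, 5.8, 14.3, 8.0])


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def analytical_sample(default_config):
    """Full-size synthetic cohort run through the cascade and age centring."""
    roster = inject_missingness(
        generate_cohort(default_config, seed=11), default_config, seed=12
    )
    retained, _ = exclusion_cascade(roster)
    return center_age_by_group(retained)


@pytest.fixture(scope="session")
def small_sample():
    """Quick 400-record complete cohort for unit-level regression tests."""
    cfg = GeneratorConfig(
        n=400, n_missing_outcome=0, n_missing_wear=0, n_missing_ses=0
    )
    return center_age_by_group(generate_cohort(cfg, seed=7))
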