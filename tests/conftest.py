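import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import latentdiff as ld

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def recovery_config():
    """Homogeneous 6-item scale, true latent d = -0.5 (group 2 higher)."""
    return ld.OrdinalFactorConfig.simple(
        n_items=6, loading=0.7, group_sizes=(2000, 2000), latent_d=-0.5, seed=42
    )


@pytest.fixture(scope="session")
def recovery_data(recovery_config):
    return ld.generate_ordinal_factor_data(recovery_config)


@pytest.fixture(scope="session")
def recovery_fit(recovery_data):
    return ld.fit_invariant_mgcfa(recovery_data, estimator="ULS")
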