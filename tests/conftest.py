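import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import patientrep as pr

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort() -> pr.SyntheticCohort:
    """A compact cohort reused by the integration-flavoured tests."""
    return pr.generate_cohort(
        pr.GeneratorConfig(
            n_patients=400, n_descriptors=80, n_diseases=8, n_topics=5, seed=11
        )
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def random_layer(rng) -> pr.AutoencoderLayer:
    return pr.AutoencoderLayer(
        W=rng.normal(scale=0.4, size=(5, 4)),
        b=rng.normal(scale=0.2, size=5),
        b_prime=rng.normal(scale=0.2, size=4),
    )
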