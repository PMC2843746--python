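import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oligosurvey.markov_stats import base_composition
from oligosurvey.synthetic_data import generate_random_genome

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def iid_1mb():
    """1 Mb i.i.d. chromosome at 50% G+C, shared across tests."""
    return generate_random_genome(1_000_000, 0.5, seed=12345, chromosome_id="iid1mb")


@pytest.fixture(scope="session")
def iid_1mb_comp(iid_1mb):
    return base_composition(iid_1mb.sequence)


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)


def random_sequence(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))
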