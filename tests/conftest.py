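import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def catalog():
    from hoxminer import default_catalog

    return default_catalog()


@pytest.fixture(scope="session")
def profile():
    from hoxminer import default_profile

    return default_profile()


@pytest.fixture(scope="session")
def threshold(profile):
    from hoxminer import calibrate_threshold

    return calibrate_threshold(profile)


@pytest.fixture()
def rng():
    return np.random.default_rng(20161110)


def random_transcript(rng, length=2000, with_n=False):
    alphabet = "ACGTN" if with_n else "ACGT"
    probs = [0.24, 0.24, 0.24, 0.24, 0.04] if with_n else None
    return "".join(rng.choice(list(alphabet), size=length, p=probs))
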