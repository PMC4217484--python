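import numpy as np
import pytest
from hypothesis import settings

from chanstoch import build_scheme, generate_ap_fixture

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from chanstoch.kinetics import Edge, KineticScheme, RateForm


@pytest.fixture(scope="session")
def hh_na():
    return build_scheme("hh_na")


@pytest.fixture(scope="session")
def hh_k():
    return build_scheme("hh_k")


@pytest.fixture(scope="session")
def all_schemes():
    return [build_scheme(n) for n in ("hh_na", "hh_k", "sb_na_somatic", "sb_na_axonal", "sb_k")]


def make_two_state(alpha=0.4, beta=0.6):
    """Voltage-independent open/closed telegraph channel."""
    return KineticScheme(
        "two_state",
        ("closed", "open"),
        (Edge(0, 1, "alpha", "beta"),),
        (1,),
        {"alpha": RateForm("constant", a=alpha), "beta": RateForm("constant", a=beta)},
    )


@pytest.fixture
def two_state():
    return make_two_state()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ap_trace():
    """Noisy 100-ms HH voltage trace with one action potential (UA run)."""
    return generate_ap_fixture(seed=11)


class ZeroNoiseRng:
    """RNG stub that suppresses Gaussian noise (deterministic limit)."""

    def standard_normal(self):
        return 0.0

    def random(self):
        return 0.5


class CountingRng:
    """Wraps a Generator, counting standard-normal draws."""

    def __init__(self, rng):
        self._rng = rng
        self.normal_draws = 0

    def standard_normal(self):
        self.normal_draws += 1
        return float(self._rng.standard_normal())

    def random(self):
        return float(self._rng.random())
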