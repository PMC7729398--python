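import numpy as np
import pytest

from p2xkin.model import RateConstantSet
from p2xkin.synthetic import default_rates


@pytest.fixture(scope="session")
def fixture_rates() -> RateConstantSet:
    """The documented detailed-balance ground-truth rate set."""
    return default_rates()


def random_rate_set(rng: np.random.Generator,
                    lo: float = 0.05, hi: float = 5000.0) -> RateConstantSet:
    """Log-uniform random rate set spanning realistic kinetic scales."""
    return RateConstantSet(np.exp(rng.uniform(np.log(lo), np.log(hi), 26)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
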