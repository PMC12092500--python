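import numpy as np
import pytest

from metacrit import SDTParams, Type2Criteria


@pytest.fixture
def unbiased_d2() -> SDTParams:
    """The package's canonical example observer: d' = 2, c1 = 0, equal priors."""
    return SDTParams(d_prime=2.0, c1=0.0, p_S2=0.5)


@pytest.fixture
def unit_criteria() -> Type2Criteria:
    """Type 2 criteria one unit on either side of an unbiased c1."""
    return Type2Criteria(c2_S1=-1.0, c2_S2=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240211)


def binomial_se(p: float, n: float) -> float:
    """Standard error of an empirical proportion."""
    return float(np.sqrt(max(p * (1.0 - p), 1e-12) / n))
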