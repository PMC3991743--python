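import numpy as np
import pytest

from mirtarkit.duplex import STANDARD_MIR164, ScoringParams


@pytest.fixture
def mirna():
    return STANDARD_MIR164


@pytest.fixture
def params():
    return ScoringParams()


@pytest.fixture
def literal_params():
    return ScoringParams.literal_paper()


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def random_rna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))
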