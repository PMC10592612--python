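import numpy as np
import pytest

from trnatherm import (
    AnticodonPool,
    GeneticCode,
    WobbleRuleTable,
    sense_decoding_anticodons,
)


@pytest.fixture(scope="session")
def code():
    return GeneticCode.bacterial()


@pytest.fixture(scope="session")
def rules():
    return WobbleRuleTable.bacterial_default()


@pytest.fixture(scope="session")
def full_pool(code):
    """All 61 sense-decoding anticodons at copy number 1."""
    return AnticodonPool("complete", {a: 1 for a in sense_decoding_anticodons(code)})


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
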