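import numpy as np
import pytest

from tebench import ReferenceGenome, SimConfig, TELibrary
from tebench.fixtures import build_fixture_objects


@pytest.fixture(scope="session")
def toy():
    """Session-wide toy dataset (deterministic)."""
    return build_fixture_objects(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_genome():
    return ReferenceGenome({"chrI": "ACGTACGTAC" * 1000, "chrII": "TTGGCCAATT" * 500})


@pytest.fixture
def tiny_library():
    return TELibrary(
        {"TY1": "TTTTGGGGCCCC", "TY3": "AAAACCCCGGGGTTTT"},
        {"TY1": (2, 10)},
    )


@pytest.fixture
def yeast_config():
    """The standard single-insertion configuration: 5-bp TSD, paired 100-bp reads."""
    return SimConfig(
        replicates=1,
        tsd_len=5,
        read_len=100,
        paired=True,
        insert_mean=300,
        insert_sd=30,
        error_rate=0.0,
        coverages=(50.0,),
        seed=42,
    )
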