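import numpy as np
import pytest

from chargeblocks import AnnotatedSequence, GeneratorConfig, gen_diblock_unit
from chargeblocks.synthetic_constructs import (
    ki67_r12_like_sites,
    ki67_r12_like_unit,
    npm1_like_idr,
    npm1_like_sites,
)

CHARGED_ALPHABET = list("KREDGSTAPNQ")


@pytest.fixture(scope="session")
def r12_like():
    return ki67_r12_like_unit()


@pytest.fixture(scope="session")
def r12_sites():
    return ki67_r12_like_sites()


@pytest.fixture(scope="session")
def npm1_like():
    return npm1_like_idr()


@pytest.fixture(scope="session")
def npm1_sites():
    return npm1_like_sites()


@pytest.fixture
def random_sequences():
    """Deterministic batch of random sequences over a charge-rich alphabet."""

    def make(n, min_len=10, max_len=60, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            L = int(rng.integers(min_len, max_len + 1))
            residues = "".join(rng.choice(CHARGED_ALPHABET, size=L))
            out.append(AnnotatedSequence(id=f"rand-{i}", residues=residues))
        return out

    return make


@pytest.fixture(scope="session")
def diblock_unit():
    return gen_diblock_unit(GeneratorConfig(seed=0))
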