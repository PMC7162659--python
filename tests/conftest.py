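import numpy as np
import pytest

from gbody.simulate import make_annotation


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def annot():
    """A 30-gene toy annotation shared across tests."""
    return make_annotation(30, chrom_length=60_000, seed=7)


@pytest.fixture(scope="session")
def big_annot():
    """A 500-gene annotation for RIP-seq calibration tests."""
    return make_annotation(500, chrom_length=700_000, seed=1)
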