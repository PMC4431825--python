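import pytest

from mitoleak import (
    bootstrap_ratio,
    load_motifs,
    load_trio_counts,
    reference_gamete_counts,
)
from mitoleak.synthetic_data import random_reference


@pytest.fixture(scope="session")
def motifs():
    return load_motifs()

@pytest.fixture(scope="session")
def motif_by_id(motifs):
    return {m.motif_id: m for m in motifs}


@pytest.fixture(scope="session")
def table():
    return load_trio_counts()


@pytest.fixture(scope="session")
def gametes():
    return reference_gamete_counts()


@pytest.fixture(scope="session")
def ratio_dist(gametes):
    """One shared full-size ratio bootstrap (B=1e5) for the test suite."""
    return bootstrap_ratio(gametes, B=100_000, seed=1)


@pytest.fixture(scope="session")
def reference(motifs):
    """Synthetic 16,569 bp reference carrying every motif's maternal alleles."""
    return random_reference(seed=99, length=16_569, motifs=motifs)
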