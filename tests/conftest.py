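import numpy as np
import pytest

from totikit import published
from totikit.io import GenomeRecord
from totikit.simulate import GenomeParams, make_genome


@pytest.fixture(scope="session")
def gctv2_genome():
    """Synthetic genome with the GcTV2-Gc6 published layout."""
    genome, truth = make_genome(seed=11)
    return genome, truth


@pytest.fixture(scope="session")
def gctv4_genome():
    params = GenomeParams.from_layout(published.GCTV4_LAYOUT)
    genome, truth = make_genome(params, seed=12)
    return genome, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(424242)


def random_rna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))


@pytest.fixture()
def small_genome(rng):
    return GenomeRecord(id="g_small", sequence=random_rna(rng, 1000))
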