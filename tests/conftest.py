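import numpy as np
import pytest

import mutsig as ms


@pytest.fixture(scope="session")
def tri_dict():
    return ms.build_dictionary(ms.TRI)


@pytest.fixture(scope="session")
def tetra_dict():
    return ms.build_dictionary(ms.TETRA)


@pytest.fixture(scope="session")
def toy_store():
    """Small two-chromosome genome covering all tri-nucleotide contexts."""
    return ms.make_toy_genome(n_chrom=2, chrom_length=6000, rng=1234)


@pytest.fixture(scope="session")
def planted_tri():
    """Planted (W, H, V) for a well-separated 3-signature recovery problem."""
    rng = np.random.default_rng(42)
    W = ms.planted_signatures(96, 3, rng)
    H = ms.planted_exposures(3, 40, rng)
    V = ms.simulate_counts(W, H, rng)
    return W, H, V
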