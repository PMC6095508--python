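import numpy as np
import pytest

from sparsimg import (
    DictionaryConfig,
    DomainSpec,
    PartitionSpec,
    PhantomSpec,
    build_mixed_dictionary,
    generate_phantom,
)


@pytest.fixture(scope="session")
def dict16():
    """Mixed pixel-domain dictionary for 16x16 blocks."""
    return build_mixed_dictionary("pixel", 16)


@pytest.fixture(scope="session")
def dict8():
    """Mixed pixel-domain dictionary for 8x8 blocks."""
    return build_mixed_dictionary("pixel", 8)


@pytest.fixture(scope="session")
def smooth128():
    """Seeded 128x128 smooth phantom in the 8-bit range."""
    img, _ = generate_phantom(PhantomSpec("smooth", (128, 128), seed=5))
    return img


@pytest.fixture
def pspec128():
    return PartitionSpec((128, 128), 16)


def random_sparse_block(D, seed, s=5, signed=True):
    """A block that is exactly an s-atom combination, with its ground truth."""
    from sparsimg import BlockDecomposition, reconstruct_block

    rng = np.random.default_rng(seed)
    M = D.size
    flat = rng.choice(M * M, size=s, replace=False)
    pairs = [(int(f) // M + 1, int(f) % M + 1) for f in flat]
    c = rng.uniform(1.0, 2.0, s)
    if signed:
        c = c * rng.choice([-1.0, 1.0], s)
    truth = BlockDecomposition(pairs, c, 0.0, "synthetic")
    return reconstruct_block(truth, D, D), truth
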