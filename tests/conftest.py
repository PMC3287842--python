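import numpy as np
import pytest

import rarepool as rp


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Seeded 10-gene null dataset shared by read-only tests."""
    cfg = rp.null_config(n_genes=10, n_samples=200, n_replicates=3, seed=5)
    return rp.simulate_dataset(cfg)


@pytest.fixture
def toy_gene():
    """6-sample, 3-variant gene with planted MAFs spanning the thresholds.

    MAFs are supplied directly (as if estimated from a larger cohort) so the
    fixed-threshold tests have qualifying variants despite n = 6.
    """
    counts = np.array(
        [
            [0, 0, 1],
            [1, 0, 2],
            [0, 1, 0],
            [0, 0, 1],
            [0, 0, 0],
            [1, 1, 2],
        ],
        dtype=np.int8,
    )
    mafs = np.array([0.005, 0.03, 0.2])
    y = np.array([0.3, 1.9, -0.7, 0.1, -1.2, 2.4])
    return counts, mafs, y
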