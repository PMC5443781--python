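import numpy as np
import pytest

from csdpop import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_pool():
    """A small synthetic allele pool with ground truth (session-cached)."""
    cfg = synthetic.SimConfig(n_alleles=20, hvr_len_range=(5, 15), seed=42)
    pool, truth = synthetic.make_allele_pool(cfg, np.random.default_rng(42))
    return cfg, pool, truth
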