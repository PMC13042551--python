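import numpy as np
import pytest

from s3rl.synthetic import SynthConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_ds():
    """A quick 10×10 fixture with clear structure, for unit tests."""
    return generate(SynthConfig(grid_rows=10, grid_cols=10, n_domains=3,
                                n_genes=50, markers_per_domain=5, seed=7))


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(grid_rows=10, grid_cols=10, n_domains=3, n_genes=50,
                       markers_per_domain=5, seed=7)
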