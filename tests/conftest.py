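import numpy as np
import pytest

from combosyn.features import build_features
from combosyn.synth import SynthConfig, make_world


@pytest.fixture(scope="session")
def default_world():
    """The canonical synthetic world (240 genes, 30 drugs, 40 samples)."""
    return make_world(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def default_features(default_world):
    return build_features(default_world)


@pytest.fixture(scope="session")
def small_world():
    """A reduced world for fast model-training tests."""
    cfg = SynthConfig(n_genes=60, n_pathways=6, genes_per_pathway=10,
                      n_samples=16, n_drugs=12, seed=3)
    return make_world(cfg)


@pytest.fixture(scope="session")
def small_features(small_world):
    return build_features(small_world, n_bits=512)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
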