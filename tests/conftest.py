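import numpy as np
import pytest

from immunoloop.chemlib import TokenVocabulary
from immunoloop.synthetic_hts import SyntheticScreenConfig, generate_library


@pytest.fixture(scope="session")
def toy_library():
    """200 small synthetic molecules; shared by representation tests."""
    cfg = SyntheticScreenConfig(library_size=200, seed=7, min_units=2, max_units=4)
    return generate_library(cfg)


@pytest.fixture(scope="session")
def toy_vocab(toy_library):
    return TokenVocabulary.from_molecules(toy_library.molecules)


@pytest.fixture(scope="session")
def trained_vae(toy_library, toy_vocab):
    """Toy VAE trained to convergence on the 200-molecule library (slow: ~45 s,
    shared across the embedding tests)."""
    from immunoloop.embedding import VaeConfig, train_vae
    cfg = VaeConfig(epochs=300, seed=1, latent_dim=16, kl_weight=0.05)
    return train_vae(toy_library, cfg, toy_vocab)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
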