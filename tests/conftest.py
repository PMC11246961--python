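import numpy as np
import pytest

from ggnes import SynthConfig, generate_dataset, train_baseline
from ggnes.backbone import BackboneParams


@pytest.fixture(scope="session")
def small_dataset():
    """40 samples, N=12, clique-vs-cycle motifs, light noise."""
    return generate_dataset(SynthConfig(N=12, Z=40, noise_sd=0.05, seed=7))


@pytest.fixture(scope="session")
def clean_dataset():
    """Noiseless, separable 40-sample cohort."""
    return generate_dataset(SynthConfig(N=12, Z=40, noise_sd=0.0, seed=3))


@pytest.fixture(scope="session")
def trained_backbone(small_dataset):
    dataset, _ = small_dataset
    params, _ = train_baseline(dataset, epochs=120, seed=0)
    return params


@pytest.fixture()
def tiny_params():
    """A small random backbone for gradient checks (d_in=2, 2 classes)."""
    return BackboneParams.init(2, 2, hidden_dims=(5, 4), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
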