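import numpy as np
import pytest

from mivae import (
    CnnConfig,
    RepresentationConfig,
    SynthParams,
    VaeConfig,
    build_inputs,
    generate_dataset,
)


@pytest.fixture(scope="session")
def default_params() -> SynthParams:
    return SynthParams()


@pytest.fixture(scope="session")
def tiny_trials(default_params):
    """Six trials (3 per class), enough to exercise shapes and ordering."""
    return generate_dataset(default_params, 3, seed=7)


@pytest.fixture(scope="session")
def tiny_images(tiny_trials):
    return build_inputs(tiny_trials, RepresentationConfig())


@pytest.fixture(scope="session")
def small_images(default_params):
    """60 trials with the default (strong) ERD/ERS contrast."""
    ts = generate_dataset(default_params, 30, seed=11)
    return build_inputs(ts, RepresentationConfig())


@pytest.fixture(scope="session")
def separable_features():
    """Two well-separated Gaussian clusters in 40 dimensions."""
    rng = np.random.default_rng(5)
    n = 60
    centers = np.zeros((2, 40))
    centers[0, :10] = 2.5
    centers[1, 10:20] = 2.5
    y = np.arange(n) % 2
    x = centers[y] + rng.standard_normal((n, 40))
    return x.astype(np.float32), y


def fast_cnn_config(**kw) -> CnnConfig:
    defaults = dict(n_filters=8, epochs=10, batch_size=20, seed=3)
    defaults.update(kw)
    return CnnConfig(**defaults)


def fast_vae_config(**kw) -> VaeConfig:
    defaults = dict(
        input_dim=240,
        hidden_dims=(60, 30, 10, 30, 60),
        pretrain_epochs=5,
        finetune_epochs=20,
        pretrain_batch=10,
        finetune_batch=20,
        seed=3,
    )
    defaults.update(kw)
    return VaeConfig(**defaults)
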