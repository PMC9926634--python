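import numpy as np
import pytest

from omicstack.architectures import HyperparameterSet
from omicstack.synthetic import SyntheticSpec, generate


@pytest.fixture(scope="session")
def small_hp():
    """Desk-scale hyperparameters for fast training in tests."""
    return HyperparameterSet(epochs=5, layer_dim=32, latent_dim=16, batch_size=16,
                             n_modules=8)


@pytest.fixture(scope="session")
def oracle_spec():
    """The planted-signal reference cohort: 600 samples, 10% responders,
    views of 300/500/500 features with 30 informative each, expression shift
    1.5 SD, binary rates 0.05 base / +0.20 for responders."""
    return SyntheticSpec(seed=7)


@pytest.fixture(scope="session")
def oracle_data(oracle_spec):
    return generate(oracle_spec)


@pytest.fixture(scope="session")
def oracle_split(oracle_data):
    """Stratified 75/25 train/test split of the reference cohort."""
    from omicstack.comparison import stratified_kfold

    folds = stratified_kfold(oracle_data.labels, 4, seed=0)
    test_idx = folds[0]
    train_idx = np.setdiff1d(np.arange(oracle_data.n_samples), test_idx)
    return oracle_data.subset(train_idx), oracle_data.subset(test_idx)


@pytest.fixture(scope="session")
def tiny_data():
    """A small cohort for contract/shape tests (fast to train on)."""
    return generate(SyntheticSpec(n_samples=160, view_dims=(40, 50, 50),
                                  n_informative=(10, 10, 10), seed=3))
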