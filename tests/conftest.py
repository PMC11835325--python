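import numpy as np
import pytest

from endostitch import experiments as ex
from endostitch import synthetic as syn
from endostitch.warping import double_h_transform

#: seed for the scaled-down training experiments shared across the suite
TRAIN_SEED = 1


@pytest.fixture(scope="session")
def noiseless_samples():
    """Eight noiseless pairs with perturbations ≤ 16 px (no photometrics)."""
    samples, _ = syn.make_dataset(ex.recovery_conditions(5, 8))
    return samples


@pytest.fixture(scope="session")
def jittered_samples():
    """Six pairs across all grades with brightness jitter and blur."""
    samples, _ = syn.make_dataset(ex.study_conditions(7, 6))
    return samples


@pytest.fixture(scope="session")
def sample_canvas(noiseless_samples):
    s = noiseless_samples[0]
    return double_h_transform((s.reference, s.target), s.h_true)


@pytest.fixture(scope="session")
def trained_aligner():
    """The scaled-down pre-training run (shared: training dominates runtime)."""
    return ex.train_scaled_aligner(TRAIN_SEED)


@pytest.fixture(scope="session")
def trained_fusion(trained_aligner):
    return ex.train_scaled_fusion(trained_aligner, TRAIN_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
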