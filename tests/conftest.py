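import numpy as np
import pytest

from maknet.network import ModelConfig
from maknet.preprocess import SplitSpec, split_dataset
from maknet.synth import NoiseSpec, SynthDatasetSpec, make_dataset


@pytest.fixture
def tiny_model_cfg():
    """Smallest config that exercises every block."""
    return ModelConfig(input_len=300, stem_channels=(2, 3), ms_out_channels=4,
                       gru_hidden=3, gru_layers=1, kan_hidden=6, seed=0)


@pytest.fixture(scope="session")
def small_balanced_dataset():
    """60 beats, 12 per class, split 60/20/20; session-scoped (read-only)."""
    spec = SynthDatasetSpec(counts_per_class=dict.fromkeys("NSVFQ", 12),
                            separability=2.0, seed=7)
    return split_dataset(make_dataset(spec), SplitSpec(seed=7))


@pytest.fixture(scope="session")
def small_imbalanced_dataset():
    """Majority/minority ratio 20, split and tagged; session-scoped."""
    spec = SynthDatasetSpec(
        counts_per_class={"N": 200, "S": 10, "V": 30, "F": 10, "Q": 30},
        separability=2.0, seed=11)
    return split_dataset(make_dataset(spec), SplitSpec(seed=11))


@pytest.fixture
def quiet_noise():
    return NoiseSpec.silent()
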