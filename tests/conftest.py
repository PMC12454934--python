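import numpy as np
import pytest

from targetpep.alphabet import SIGNAL_CLASSES
from targetpep.seqio import ProteinRecord, SignalAnnotation
from targetpep.simulate import SyntheticConfig, generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small deterministic synthetic dataset shared across tests."""
    config = SyntheticConfig(
        n_per_class={c: 4 for c in SIGNAL_CLASSES},
        long_fraction=0.0,
        seed=7,
    )
    return generate_dataset(config)


@pytest.fixture()
def toy_record():
    return ProteinRecord("P1", "MKLVAAAGHHWWYYCCDDEE")


@pytest.fixture()
def toy_annotations():
    return [SignalAnnotation("P1", "SP", 1, 5)]
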