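import numpy as np
import pytest

from predpair.model import PredPair
from predpair.nn import ModelConfig
from predpair.structures import SecondaryStructure
from predpair.synthetic import gen_stretch_sequences


@pytest.fixture(scope="session")
def hairpin():
    # 5'-GGGAC....GUCCC-3': a 5-pair stem with a 4-nt loop
    return SecondaryStructure(
        "hairpin",
        "GGGACAUUUGUCCC",
        {(0, 13), (1, 12), (2, 11), (3, 10), (4, 9)},
    )


@pytest.fixture(scope="session")
def tiny_trained():
    """A small model trained briefly on an easy planted-stretch task.

    Shared across interpretation tests; quality only needs to be 'clearly
    better than random', not publication-grade.
    """
    train = gen_stretch_sequences(150, 30, 5, seed=100)
    val = gen_stretch_sequences(30, 30, 5, seed=101)
    model = PredPair(train, val, ModelConfig(learning_rate=3e-3))
    res = model.fit(epochs=10, seed=0, batch_size=64, patience=10)
    return res


@pytest.fixture(scope="session")
def tiny_test_set():
    return gen_stretch_sequences(40, 30, 5, seed=102)
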