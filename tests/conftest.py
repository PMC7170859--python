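import numpy as np
import pytest

from cfopt import CompoundSpec, CompositionSpace, EnsembleConfig, default_space, make_benchmark


@pytest.fixture(scope="session")
def space11():
    return default_space()


@pytest.fixture(scope="session")
def space2():
    """Two compounds, four levels: 16 points, fully enumerable."""
    return CompositionSpace(
        compounds=[CompoundSpec("a", 10.0), CompoundSpec("b", 5.0)],
        fixed_components={"hepes": (50.0, "mM")},
    )


@pytest.fixture(scope="session")
def benchmark(space11):
    return make_benchmark(space=space11)


@pytest.fixture(scope="session")
def tiny_model_config():
    """Small deterministic ensemble for structure-level tests."""
    return EnsembleConfig(
        n_members=2,
        restarts_per_member=1,
        hidden_layers=(8,),
        max_iterations=200,
        base_seed=0,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
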