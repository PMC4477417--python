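import numpy as np
import pytest

import propalign as pa


@pytest.fixture(scope="session")
def example_props() -> pa.WeightedPropertySet:
    """The bundled two-property (hydrophobicity 0.6 / size 0.4) set."""
    return pa.load_example_properties()


@pytest.fixture(scope="session")
def default_props() -> pa.WeightedPropertySet:
    return pa.load_default_properties()


@pytest.fixture(scope="session")
def blosum62() -> pa.SubstitutionMatrix:
    return pa.load_builtin_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def small_benchmark():
    """A deterministic 6-pair benchmark at moderate identity."""
    config = pa.SimulationConfig(
        n_families=3, pairs_per_family=2, ancestor_length=60, seed=11
    )
    pairs, _ = pa.generate_benchmark(config)
    return pairs


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
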