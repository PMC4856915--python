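import numpy as np
import pytest

from polysorb.core import DescriptorTable, ModelingDataset
from polysorb.synthetic import GeneratorConfig, generate_library


@pytest.fixture(scope="session")
def small_library():
    """One deterministic 18-polymer, 60-descriptor library with ground truth."""
    cfg = GeneratorConfig(n_polymers=18, n_descriptors=60, seed=42)
    return generate_library(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_library):
    table, _series, eqs, _truth = small_library
    return ModelingDataset.from_equilibrium(table, eqs)


@pytest.fixture()
def toy_table():
    rng = np.random.default_rng(0)
    values = rng.standard_normal((8, 4))
    return DescriptorTable(
        tuple(f"p{i}" for i in range(8)),
        ("alpha", "beta", "gamma", "delta"),
        values,
    )


@pytest.fixture(scope="session")
def reference_eqs():
    from polysorb.io import load_reference_equilibrium

    return load_reference_equilibrium()
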