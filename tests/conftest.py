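import numpy as np
import pytest

from eluorder import AnalyteTable, GeneratorSpec, generate_linear_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_table(rng):
    """20 analytes, 3 descriptors, mild noise."""
    spec = GeneratorSpec(
        n=20, K=3, true_coefficients=(15.0, 3.0, -1.0, 2.0), noise_sd=0.5, seed=42
    )
    table, _ = generate_linear_dataset(spec)
    return table


@pytest.fixture
def noiseless():
    """Exact linear data plus its generating model."""
    spec = GeneratorSpec(
        n=40, K=3, true_coefficients=(20.0, 5.0, 2.0, 3.0), noise_sd=0.0, seed=7
    )
    return generate_linear_dataset(spec)


def make_table_1d(xs):
    """Helper: one-descriptor table at given positions, retention = 1 + index."""
    xs = np.asarray(xs, dtype=float)
    return AnalyteTable(
        ids=tuple(f"a{i}" for i in range(len(xs))),
        descriptor_names=("x",),
        X=xs.reshape(-1, 1),
        t_obs=np.arange(1.0, len(xs) + 1.0),
    )
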