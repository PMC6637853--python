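import numpy as np
import pandas as pd
import pytest

from mirnetfa import ExpressionMatrix, GroupDesign, SyntheticConfig, simulate
from mirnetfa.pipeline import combined_group_matrices


@pytest.fixture(scope="session")
def default_sim():
    """One default-config synthetic dataset shared across tests."""
    return simulate(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def default_group_mats(default_sim):
    mrna, mirna, design, _ = default_sim
    return combined_group_matrices(mrna, mirna, design)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_design():
    return GroupDesign(
        pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(8)],
                "group": ["High"] * 4 + ["Low"] * 4,
                "phenotype": "toy",
                "gebv": [1.0, 2.0, 3.0, 4.0, -1.0, -2.0, -3.0, -4.0],
            }
        )
    )


def make_expression(values, layer="log2", kind="mRNA", prefix="f", samples=None):
    values = np.asarray(values, float)
    index = [f"{prefix}{i}" for i in range(values.shape[0])]
    if samples is None:
        samples = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=index, columns=samples), layer, kind
    )


def vectors_with_correlation(rho: float, n: int, rng: np.random.Generator):
    """Two vectors whose sample Pearson correlation is exactly rho."""
    z1 = rng.normal(size=n)
    z2 = rng.normal(size=n)
    z1 = (z1 - z1.mean()) / z1.std()
    z2 = z2 - z2.mean()
    z2 = z2 - (z2 @ z1) / (z1 @ z1) * z1
    z2 = z2 / z2.std()
    return z1, rho * z1 + np.sqrt(1 - rho**2) * z2
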