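import numpy as np
import pandas as pd
import pytest

from adipomod import (
    ExpressionMatrix,
    SyntheticDesign,
    TraitTable,
    generate_cohort,
    quantile_normalize,
)


def make_matrix(X, tissue="OTHER", normalized=False, probe_prefix="P", sample_prefix="S"):
    X = np.asarray(X, dtype=float)
    return ExpressionMatrix(
        values=pd.DataFrame(
            X,
            index=[f"{probe_prefix}{i}" for i in range(X.shape[0])],
            columns=[f"{sample_prefix}{j}" for j in range(X.shape[1])],
        ),
        tissue=tissue,
        normalized=normalized,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-design synthetic cohort shared across tests."""
    return generate_cohort(SyntheticDesign(), seed=11)


@pytest.fixture(scope="session")
def normalized_sat(default_cohort):
    return quantile_normalize(default_cohort.sat)


@pytest.fixture
def small_traits():
    rng = np.random.default_rng(5)
    n = 40
    df = pd.DataFrame(
        {
            "gender": rng.integers(0, 2, n).astype(float),
            "glucose": rng.standard_normal(n),
            "HDL_cholesterol": rng.standard_normal(n),
        },
        index=[f"S{j}" for j in range(n)],
    )
    return TraitTable(values=df)
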