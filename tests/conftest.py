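import numpy as np
import pandas as pd
import pytest

from countgs import MarkerMatrix, PhenotypeTable


@pytest.fixture
def tiny_markers():
    return MarkerMatrix(
        ["L1", "L2", "L3"],
        ["m1", "m2"],
        [[1, 0], [0, 1], [1, 1]],
    )


@pytest.fixture
def tiny_phenotypes():
    df = pd.DataFrame(
        {
            "line": ["L1", "L2", "L3", "L1", "L2", "L3"],
            "env": ["E1", "E1", "E1", "E2", "E2", "E2"],
            "y1": [1, 2, 3, 4, 5, 6],
            "y2": [0, 1, 0, 2, 1, 3],
        }
    )
    return PhenotypeTable(df, ["y1", "y2"])


@pytest.fixture
def poisson_problem():
    """Moderate linear Poisson regression problem with known coefficients."""
    rng = np.random.default_rng(42)
    n, d = 300, 6
    X = rng.normal(size=(n, d))
    beta = np.array([0.3, -0.25, 0.2, 0.0, 0.0, 0.15])
    eta = 0.8
    y = rng.poisson(np.exp(eta + X @ beta))
    return X, y, eta, beta
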