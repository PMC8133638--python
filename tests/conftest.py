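from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from seedcoex import ExpressionMatrix, SeedGeneSet, SyntheticConfig, generate_expression

DATA = Path(__file__).parent / "data"


@pytest.fixture
def data_dir() -> Path:
    return DATA


@pytest.fixture
def toy_matrix():
    from seedcoex import read_expression

    return read_expression(DATA / "toy_expression.tsv")


@pytest.fixture
def small_matrix():
    """4 hand-sized genes over 4 samples for scalar GCC checks."""
    df = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 4.0, 1.0],
            "s2": [2.0, 1.0, 3.0, 7.0],
            "s3": [3.0, 4.0, 2.0, 3.0],
            "s4": [4.0, 3.0, 1.0, 9.0],
        },
        index=["a", "b", "c", "d"],
    )
    return ExpressionMatrix(df)


@pytest.fixture(scope="session")
def small_synthetic():
    """One desk-scale synthetic dataset shared across tests (200 background)."""
    config = SyntheticConfig(n_background=200, n_below_filter=10, rng_seed=7)
    matrix, truth = generate_expression(config)
    return matrix, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)


def rank_oracle(x):
    """O(n^2) average-rank: 1 + #smaller + #equal-others / 2."""
    x = list(x)
    return np.array(
        [
            1.0
            + sum(1 for v in x if v < xi)
            + sum(1 for j, v in enumerate(x) if v == xi and j != i) / 2.0
            for i, xi in enumerate(x)
        ]
    )


def gcc_covariance_oracle(x, y):
    """Direct covariance-definition computation, scalar loops only."""
    x, y = list(map(float, x)), list(map(float, y))
    n = len(x)
    rx, ry = rank_oracle(x), rank_oracle(y)
    mx, mrx, mry = sum(x) / n, sum(rx) / n, sum(ry) / n
    num = sum((xi - mx) * (ryi - mry) for xi, ryi in zip(x, ry))
    den = sum((xi - mx) * (rxi - mrx) for xi, rxi in zip(x, rx))
    return num / den

def gcc_weighted_oracle(x, y):
    """Weighted-sorted-sum form for tie-free vectors (independent route)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    w = [2 * i - n - 1 for i in range(1, n + 1)]
    xs_by_y = x[np.argsort(y)]
    xs = np.sort(x)
    return sum(wi * v for wi, v in zip(w, xs_by_y)) / sum(wi * v for wi, v in zip(w, xs))
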