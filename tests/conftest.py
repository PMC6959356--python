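import numpy as np
import pandas as pd
import pytest

from csea import CellPartition, CseaParams, ExpressionMatrix, ScoreVector


@pytest.fixture
def six_cell():
    """Six cells with scores 3..-3 and S = {A, B, F}."""
    scores = ScoreVector(
        pd.Series({"A": 3.0, "B": 2.0, "C": 1.0, "D": -1.0, "E": -2.0, "F": -3.0}),
        signature_name="demo",
    )
    part = CellPartition(
        pd.Series(
            {"A": "MS", "B": "MS", "C": "co", "D": "co", "E": "co", "F": "MS"}
        ),
        set_of_interest="MS",
    )
    return scores, part


@pytest.fixture
def small_expr():
    """4 cells x 6 genes, deterministic values with per-cell variance."""
    rng = np.random.default_rng(42)
    values = rng.normal(0, 1, size=(4, 6)).round(3)
    return ExpressionMatrix(
        values,
        cell_ids=[f"c{i}" for i in range(4)],
        gene_ids=[f"g{i}" for i in range(6)],
    )


@pytest.fixture
def random_scores_partition():
    """Factory: n cells with continuous scores and a random proper subset S."""

    def make(n, n_h, seed):
        rng = np.random.default_rng(seed)
        ids = [f"c{i:04d}" for i in range(n)]
        scores = ScoreVector(pd.Series(rng.normal(size=n), index=ids), "rand")
        members = rng.choice(n, size=n_h, replace=False)
        labels = np.array(["out"] * n, dtype=object)
        labels[members] = "in"
        part = CellPartition(pd.Series(labels, index=ids), set_of_interest="in")
        return scores, part

    return make


@pytest.fixture
def default_params():
    return CseaParams(weight_exponent=1.0, n_permutations=100, rng_seed=0)
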