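"""Shared fixtures and the brute-force canonical-correlation oracle."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import optimize

from pathcca.io import ExpressionMatrix, GeneList, PathwayCollection


def brute_force_first_canonical_r(M: np.ndarray, N: np.ndarray,
                                  n_restarts: int = 12, seed: int = 0) -> float:
    """Numerically maximize |corr(Ma, Nb)| over weight vectors.

    Independent of the whitening/SVD route: plain gradient-based search on
    the correlation objective from many random starts (the objective is
    smooth and scale-invariant).  Suitable as an oracle for small p, q only.
    """
    p, q = M.shape[1], N.shape[1]
    rng = np.random.default_rng(seed)

    def neg_corr(v: np.ndarray) -> float:
        a, b = v[:p], v[p:]
        u, w = M @ a, N @ b
        su, sw = u.std(), w.std()
        if su < 1e-12 or sw < 1e-12:
            return 0.0
        return -abs(np.corrcoef(u, w)[0, 1])

    best = 0.0
    for _ in range(n_restarts):
        x0 = rng.standard_normal(p + q)
        res = optimize.minimize(neg_corr, x0, method="BFGS",
                                options={"gtol": 1e-12, "maxiter": 500})
        best = max(best, -res.fun)
    return best


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    """5 genes x 6 experiments with a planted correlated pair (g1, g4)."""
    base = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
    values = np.vstack([
        base,                                   # g1
        np.array([5.0, 3.0, 4.0, 1.0, 2.0, 0.0]),  # g2
        np.array([1.0, -1.0, 2.0, 0.5, 0.0, 3.0]),  # g3
        base + np.array([0.1, -0.1, 0.05, 0.0, -0.05, 0.1]),  # g4 ~ g1
        np.array([2.0, 2.5, 1.0, 3.0, 0.0, 1.5]),   # g5
    ])
    return ExpressionMatrix(
        ["g1", "g2", "g3", "g4", "g5"],
        [f"e{i}" for i in range(1, 7)],
        values,
    )


@pytest.fixture
def two_pathways() -> PathwayCollection:
    return PathwayCollection([
        ("pwA", "toy", ["g3", "g4"]),
        ("pwB", "toy", ["g5", "missing_gene"]),
    ])


@pytest.fixture
def disease_pair() -> GeneList:
    return GeneList(["g1", "g2"])
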