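"""Canonical correlation analysis between two multivariate gene sets.

Given two observation-aligned matrices M (n x p, e.g. disease genes across
experiments) and N (n x q, one pathway's genes), CCA finds weight vectors
a, b maximising corr(Ma, Nb); successive pairs are mutually uncorrelated.
The decomposition here whitens each set with the inverse square root of its
correlation matrix and takes the singular value decomposition of the
whitened cross-correlation, the standard dense algorithm.

Beyond the decomposition this module provides the Bartlett chi-square
approximation to Wilks' lambda for per-pair significance, structure
loadings (correlations between each canonical variate and the original
standardized variables), and the variance-extracted statistic: the mean
squared loading of a set's variables on one canonical pair, used to judge
how much of a whole gene set the pair "delegates".

All standard deviations use the sample (n-1) denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator


@dataclass
class CCAResult:
    """Output of one canonical correlation decomposition.

    AA, BB hold coefficient columns (variables x pairs) on standardized
    variables; r the canonical correlations (descending, in [0, 1]);
    U, V the canonical variates (observations x pairs, unit sample
    variance); r11, r22 the within-set correlation matrices.
    """

    AA: np.ndarray
    BB: np.ndarray
    r: np.ndarray
    U: np.ndarray
    V: np.ndarray
    r11: np.ndarray
    r22: np.ndarray
    n_obs: int
    p: int
    q: int

    @property
    def n_pairs(self) -> int:
        return len(self.r)


@dataclass
class PairSignificance:
    """Sequential Wilks'-lambda / Bartlett chi-square test per pair.

    Entry k tests the null that canonical correlations k, k+1, ... are all
    zero, given the first k pairs.
    """

    wilks_lambda: np.ndarray
    chi_square: np.ndarray
    dof: np.ndarray
    p_value: np.ndarray


def zscore_columns(X: np.ndarray, var_names=None) -> np.ndarray:
    """Standardize each column to mean 0, sample (ddof=1) sd 1.

    Raises on zero-variance columns, listing the offending variables, so
    callers decide explicitly whether to drop them.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D observations x variables matrix")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations to z-score")
    if np.isnan(X).any():
        raise ValueError("missing values present; drop them before z-scoring")
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [var_names[i] for i in zero] if var_names is not None else list(zero)
        raise ValueError(f"zero-variance columns: {names}")
    return (X - X.mean(axis=0)) / sd


def correlation_matrix(X: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the columns (variables x variables)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 observations")
    if X.shape[1] == 1:
        return np.ones((1, 1))
    R = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def _inv_sqrt(R: np.ndarray, reg: float, rank_tol: float) -> tuple[np.ndarray, int]:
    """Spectral pseudo-inverse square root of a correlation matrix.

    Eigenvalues below rank_tol times the largest are discarded; ``reg`` adds
    a ridge before inversion for near-singular sets (n < p compendia).
    """
    if reg:
        R = R + reg * np.eye(R.shape[0])
    lam, V = np.linalg.eigh(R)
    cutoff = rank_tol * lam.max() if lam.max() > 0 else np.inf
    keep = lam > cutoff
    rank = int(keep.sum())
    if rank == 0:
        return np.zeros_like(R), 0
    W = (V[:, keep] / np.sqrt(lam[keep])) @ V[:, keep].T
    return W, rank


class CanonicalCorrelation(BaseEstimator):
    """Canonical correlation analysis of two observation-aligned sets.

    Parameters
    ----------
    scale : bool, default True
        Z-score the columns of both sets before the decomposition.  Pass
        False when inputs are already standardized.
    reg : float, default 0.0
        Ridge added to each within-set correlation matrix before whitening;
        useful when observations barely exceed variables.
    rank_tol : float, default 1e-10
        Relative eigenvalue cutoff for the whitening pseudo-inverse.

    Attributes (after :meth:`fit`)
    ------------------------------
    x_weights_, y_weights_ : (p, k) and (q, k) canonical coefficients AA, BB
    correlations_ : (k,) canonical correlations, descending, in [0, 1]
    x_scores_, y_scores_ : (n, k) canonical variates U, V (unit variance)
    x_corr_, y_corr_ : within-set correlation matrices r11, r22
    x_loadings_, y_loadings_ : (k, p) / (k, q) structure loadings
    wilks_, chi2_, dof_, pvalues_ : per-pair Bartlett test
    variance_extracted_x_, variance_extracted_y_ : first-pair S statistics

    The sign of each pair is fixed deterministically: the largest-magnitude
    entry of the x-coefficient column is made positive, and the matching
    y column is negated together with it so corr(U_k, V_k) stays +r_k.
    """

    def __init__(self, scale: bool = True, reg: float = 0.0, rank_tol: float = 1e-10):
        self.scale = scale
        self.reg = reg
        self.rank_tol = rank_tol

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "CanonicalCorrelation":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2:
            raise ValueError("X and Y must be 2-D observations x variables matrices")
        if X.shape[0] != Y.shape[0]:
            raise ValueError(
                f"observation counts differ: X has {X.shape[0]}, Y has {Y.shape[0]}"
            )
        n = X.shape[0]
        if n <= 2:
            raise ValueError("need more than 2 observations")
        p, q = X.shape[1], Y.shape[1]
        if self.scale:
            X = zscore_columns(X)
            Y = zscore_columns(Y)
        r11 = correlation_matrix(X)
        r22 = correlation_matrix(Y)
        r12 = (X - X.mean(0)).T @ (Y - Y.mean(0)) / (
            (n - 1) * np.outer(X.std(0, ddof=1), Y.std(0, ddof=1))
        )

        W1, rank1 = _inv_sqrt(r11, self.reg, self.rank_tol)
        W2, rank2 = _inv_sqrt(r22, self.reg, self.rank_tol)
        k = min(rank1, rank2)
        if k == 0:
            raise ValueError("rank 0 after whitening; no canonical pairs exist")
        P, s, Qt = np.linalg.svd(W1 @ r12 @ W2)
        r = np.clip(s[:k], 0.0, 1.0)
        AA = W1 @ P[:, :k]
        BB = W2 @ Qt[:k, :].T
        # joint sign flip per pair, keyed on the x side, keeps corr(U,V)=+r
        for j in range(k):
            if AA[np.argmax(np.abs(AA[:, j])), j] < 0:
                AA[:, j] *= -1
                BB[:, j] *= -1

        self.n_obs_, self.p_, self.q_ = n, p, q
        self.x_weights_, self.y_weights_ = AA, BB
        self.correlations_ = r
        self.x_scores_ = X @ AA
        self.y_scores_ = Y @ BB
        self.x_corr_, self.y_corr_ = r11, r22
        self.x_loadings_ = AA.T @ r11
        self.y_loadings_ = BB.T @ r22
        sig = canonical_pvalues(r, n, p, q)
        self.wilks_ = sig.wilks_lambda
        self.chi2_ = sig.chi_square
        self.dof_ = sig.dof
        self.pvalues_ = sig.p_value
        self.variance_extracted_x_ = variance_extracted(self.x_loadings_, 0)
        self.variance_extracted_y_ = variance_extracted(self.y_loadings_, 0)
        return self

    def to_result(self) -> CCAResult:
        return CCAResult(
            AA=self.x_weights_, BB=self.y_weights_, r=self.correlations_,
            U=self.x_scores_, V=self.y_scores_,
            r11=self.x_corr_, r22=self.y_corr_,
            n_obs=self.n_obs_, p=self.p_, q=self.q_,
        )


def compute_cca(M: np.ndarray, N: np.ndarray, reg: float = 0.0,
                rank_tol: float = 1e-10) -> CCAResult:
    """CCA of pre-standardized M (n x p) and N (n x q); see the estimator."""
    est = CanonicalCorrelation(scale=False, reg=reg, rank_tol=rank_tol).fit(M, N)
    return est.to_result()


def canonical_pvalues(r: np.ndarray, n_obs: int, p: int, q: int) -> PairSignificance:
    """Bartlett chi-square test of each sequential Wilks' lambda.

    Lambda_k = prod_{i>=k} (1 - r_i^2);
    chi2_k = -(n - 1 - (p + q + 1)/2) * ln Lambda_k  on (p-k)(q-k) dof.
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("canonical correlations must lie in [0, 1]")
    if n_obs <= p + q:
        warnings.warn(
            f"n_obs={n_obs} does not exceed p+q={p + q}; "
            "Bartlett's approximation is unreliable",
            stacklevel=2,
        )
    k = len(r)
    one_minus = 1.0 - r**2
    # reversed cumulative product: Lambda_k includes pairs k..end
    lam = np.cumprod(one_minus[::-1])[::-1]
    factor = n_obs - 1 - (p + q + 1) / 2.0
    with np.errstate(divide="ignore"):
        chi2 = -factor * np.log(lam)
    dof = np.array([(p - i) * (q - i) for i in range(k)], dtype=int)
    pvals = stats.chi2.sf(chi2, dof)
    return PairSignificance(lam, chi2, dof, pvals)


def structure_loadings(result: CCAResult) -> tuple[np.ndarray, np.ndarray]:
    """Loadings r_1A = AA' r11 and r_2B = BB' r22 (pairs x variables).

    Entry (k, j) equals the correlation between variate k and standardized
    variable j.
    """
    if result.AA.shape[0] != result.r11.shape[0]:
        raise ValueError("AA rows do not match r11 dimension")
    if result.BB.shape[0] != result.r22.shape[0]:
        raise ValueError("BB rows do not match r22 dimension")
    return result.AA.T @ result.r11, result.BB.T @ result.r22


def variance_extracted(loadings: np.ndarray, k: int = 0) -> float:
    """Mean squared loading of one canonical pair over a set's variables.

    The S_a / S_b statistic: the share of a gene set's (standardized)
    variance carried by canonical pair ``k``; lies in [0, 1].
    """
    loadings = np.asarray(loadings, dtype=float)
    if loadings.ndim != 2 or loadings.size == 0:
        raise ValueError("loadings must be a non-empty pairs x variables matrix")
    if not 0 <= k < loadings.shape[0]:
        raise ValueError(f"pair index {k} out of range for {loadings.shape[0]} pairs")
    return float(np.mean(loadings[k] ** 2))
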