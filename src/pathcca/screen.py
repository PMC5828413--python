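"""Threshold screen of pathways against a disease gene set.

For every pathway with enough measured genes, the screen runs a canonical
correlation analysis between the disease set's expression profiles and the
pathway's, tests the first pair (Bartlett chi-square on Wilks' lambda),
computes the variance-extracted statistics S_a (pathway side) and S_b
(disease side), and keeps pathways clearing all four thresholds on
r, p, S_a and S_b.  Each passing pathway reports its representative genes:
the members with largest-magnitude first-pair coefficients, the count set
by round(n_genes * S_a).

Benjamini-Hochberg q-values are reported across pathways but never gate
the screen; the thresholds act on the raw first-pair p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .cca import CanonicalCorrelation, CCAResult, variance_extracted
from .io import ExpressionMatrix, GeneList, PathwayCollection

logger = logging.getLogger(__name__)


@dataclass
class ScreenThresholds:
    """Pass criteria: r >= r_min, p <= p_max, S_a >= sa_min, S_b >= sb_min.

    ``min_pathway_genes`` is the inclusive size filter applied before any
    CCA is run.
    """

    r_min: float = 0.5
    p_max: float = 0.001
    sa_min: float = 0.15
    sb_min: float = 0.15
    min_pathway_genes: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.r_min <= 1:
            raise ValueError("r_min must lie in [0, 1]")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must lie in (0, 1]")
        if not 0 <= self.sa_min <= 1 or not 0 <= self.sb_min <= 1:
            raise ValueError("sa_min and sb_min must lie in [0, 1]")
        if self.min_pathway_genes < 2:
            raise ValueError("min_pathway_genes must be at least 2")


#: named presets: "methods" follows the stricter printed protocol,
#: "results" the looser criteria actually applied to report pathways,
#: "default" the loosest combination consistent with every reported row.
PRESETS: dict[str, ScreenThresholds] = {
    "default": ScreenThresholds(0.5, 0.001, 0.15, 0.15, 10),
    "methods": ScreenThresholds(0.6, 1e-5, 0.3, 0.15, 10),
    "results": ScreenThresholds(0.5, 0.001, 0.2, 0.2, 10),
}


def get_preset(name: str) -> ScreenThresholds:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {sorted(PRESETS)}"
        ) from None


@dataclass
class PathwayScreenRecord:
    """One screen row: statistics and representative genes for a pathway."""

    pathway_id: str
    n_genes_used: int
    r: float
    p_value: float
    S_a: float
    S_b: float
    representative_genes: list[str]
    passed: bool
    q_value: float = math.nan
    error: str | None = None


def representative_gene_count(n_genes: int, s_a: float, passed: bool = False) -> int:
    """Number of representative genes: round(n_genes * S_a), half away
    from zero; a pathway that passed the screen always reports at least 1.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be at least 1")
    if not 0 <= s_a <= 1:
        raise ValueError("S_a must lie in [0, 1]")
    count = math.floor(n_genes * s_a + 0.5)
    if passed:
        count = max(count, 1)
    return count


def select_representative_genes(
    result: CCAResult, pathway_gene_ids: list[str], k: int,
    use_loadings: bool = False,
) -> list[str]:
    """The k pathway genes with largest-magnitude first-pair coefficient.

    Ordered by descending magnitude; exact ties broken by ascending gene
    ID.  With ``use_loadings`` the first-pair structure loadings replace
    the raw coefficients.
    """
    q = result.BB.shape[0]
    if len(pathway_gene_ids) != q:
        raise ValueError("pathway_gene_ids must align with the second set's columns")
    if k > q:
        raise ValueError(f"cannot select {k} genes from {q}")
    scores = (result.BB.T @ result.r22)[0] if use_loadings else result.BB[:, 0]
    order = sorted(
        range(q), key=lambda i: (-abs(scores[i]), pathway_gene_ids[i])
    )
    return [pathway_gene_ids[i] for i in order[:k]]


def filter_pathways(
    pathways: PathwayCollection, expr: ExpressionMatrix, min_genes: int
) -> PathwayCollection:
    """Restrict each pathway to measured genes; drop sets left too small."""
    measured = set(expr.gene_ids)
    kept: list[tuple[str, str, list[str]]] = []
    n_dropped = 0
    for pid, desc, members in pathways:
        present = [g for g in members if g in measured]
        if len(present) >= min_genes:
            kept.append((pid, desc, present))
        else:
            n_dropped += 1
            logger.info(
                "pathway %s dropped: %d of %d genes measured (min %d)",
                pid, len(present), len(members), min_genes,
            )
    if n_dropped:
        logger.info("size filter removed %d of %d pathways", n_dropped, len(pathways))
    return PathwayCollection(kept)


class PathwayScreen(BaseEstimator):
    """Screen every pathway in a collection against one disease gene set.

    Parameters
    ----------
    thresholds : ScreenThresholds or preset name, default "default"
    rep_from_loadings : bool, default False
        Rank representative genes by structure loadings instead of raw
        canonical coefficients.
    reg, rank_tol : forwarded to :class:`CanonicalCorrelation`.

    Attributes (after :meth:`fit`)
    ------------------------------
    records_ : list of PathwayScreenRecord, sorted by descending r
        (failed pathways, r = NaN, sort last; ties broken by pathway ID).
    n_disease_genes_used_ : disease genes measured, non-constant, analysed.
    """

    def __init__(self, thresholds: ScreenThresholds | str = "default",
                 rep_from_loadings: bool = False,
                 reg: float = 0.0, rank_tol: float = 1e-10):
        self.thresholds = thresholds
        self.rep_from_loadings = rep_from_loadings
        self.reg = reg
        self.rank_tol = rank_tol

    def _resolve_thresholds(self) -> ScreenThresholds:
        if isinstance(self.thresholds, str):
            return get_preset(self.thresholds)
        return self.thresholds

    def fit(self, expr: ExpressionMatrix, pathways: PathwayCollection,
            disease: GeneList) -> "PathwayScreen":
        thr = self._resolve_thresholds()
        measured = set(expr.gene_ids)
        disease_present = [g for g in disease if g in measured]
        n_missing = len(disease.gene_ids) - len(disease_present)
        if n_missing:
            logger.warning("%d disease genes not in the compendium", n_missing)
        disease_used = self._drop_constant(expr, disease_present, "disease set")
        if len(disease_used) < 2:
            raise ValueError(
                f"only {len(disease_used)} usable disease genes; need at least 2"
            )
        M = expr.submatrix(disease_used).T  # experiments x disease genes

        retained = filter_pathways(pathways, expr, thr.min_pathway_genes)
        records: list[PathwayScreenRecord] = []
        for pid, _, members in retained:
            records.append(self._screen_one(expr, M, disease_used, pid, members, thr))

        pvals = np.array([rec.p_value for rec in records], dtype=float)
        ok = ~np.isnan(pvals)
        if ok.any():
            qvals = np.full_like(pvals, math.nan)
            qvals[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
            for rec, q in zip(records, qvals):
                rec.q_value = float(q)
        records.sort(key=lambda rec: (
            math.isnan(rec.r), -(rec.r if not math.isnan(rec.r) else 0.0),
            rec.pathway_id,
        ))
        self.records_ = records
        self.n_disease_genes_used_ = len(disease_used)
        return self

    @staticmethod
    def _drop_constant(expr: ExpressionMatrix, genes: list[str], label: str) -> list[str]:
        if not genes:
            return []
        sub = expr.submatrix(genes)
        sd = sub.std(axis=1, ddof=1)
        kept = [g for g, s in zip(genes, sd) if s > 0]
        n_const = len(genes) - len(kept)
        if n_const:
            logger.info("%s: %d constant-expression genes dropped", label, n_const)
        return kept

    def _screen_one(self, expr, M, disease_used, pid, members, thr) -> PathwayScreenRecord:
        try:
            genes_used = self._drop_constant(expr, members, pid)
            if len(genes_used) < thr.min_pathway_genes:
                raise ValueError(
                    f"{len(genes_used)} non-constant genes < min {thr.min_pathway_genes}"
                )
            N = expr.submatrix(genes_used).T
            est = CanonicalCorrelation(reg=self.reg, rank_tol=self.rank_tol).fit(M, N)
            r = float(est.correlations_[0])
            p = float(est.pvalues_[0])
            s_a = est.variance_extracted_y_   # pathway side
            s_b = est.variance_extracted_x_   # disease side
            passed = (r >= thr.r_min and p <= thr.p_max
                      and s_a >= thr.sa_min and s_b >= thr.sb_min)
            k = representative_gene_count(len(genes_used), s_a, passed=passed)
            reps = select_representative_genes(
                est.to_result(), genes_used, min(k, len(genes_used)),
                use_loadings=self.rep_from_loadings,
            )
            return PathwayScreenRecord(
                pathway_id=pid, n_genes_used=len(genes_used), r=r, p_value=p,
                S_a=s_a, S_b=s_b, representative_genes=reps, passed=passed,
            )
        except ValueError as exc:
            logger.warning("pathway %s failed: %s", pid, exc)
            return PathwayScreenRecord(
                pathway_id=pid, n_genes_used=len(members), r=math.nan,
                p_value=math.nan, S_a=math.nan, S_b=math.nan,
                representative_genes=[], passed=False, error=str(exc),
            )


def screen_pathways(
    expr: ExpressionMatrix,
    pathways: PathwayCollection,
    disease: GeneList,
    thresholds: ScreenThresholds | str = "default",
    **kwargs,
) -> list[PathwayScreenRecord]:
    """Functional wrapper over :class:`PathwayScreen`."""
    return PathwayScreen(thresholds=thresholds, **kwargs).fit(
        expr, pathways, disease
    ).records_
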