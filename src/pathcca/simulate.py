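"""Synthetic expression compendia with planted set-level coexpression.

The generator emulates a COXPRESDB-style compendium: a disease gene set,
a collection of pathways, and background genes, observed over many
independent experiments.  Per experiment t a shared standard-normal factor
f_s(t) drives the disease genes and every *linked* pathway; each unlinked
pathway gets its own private factor; background genes are pure noise:

    disease gene:          x(t) = w * f_s(t)      + eps,  eps ~ N(0, sigma^2)
    linked-pathway gene:   x(t) = w * f_s(t)      + eps
    unlinked-pathway gene: x(t) = w * f_priv(t)   + eps
    background gene:       x(t) =                   eps

Two genes sharing one unit-variance factor with loadings w1, w2 then have
population correlation w1*w2 / sqrt((w1^2+sigma^2)(w2^2+sigma^2)); the
first canonical correlation between the disease set (p genes) and a linked
pathway (q genes) is w^2 / sqrt((w^2+sigma^2/p)(w^2+sigma^2/q)), since the
between-set covariance is rank one and the optimal weights are uniform.
These closed forms are the ground truth for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, GeneList, PathwayCollection

#: default pathway sizes: a fixed ramp over the 5-50 gene range typical of
#: curated metabolic pathways
_DEFAULT_SIZES = tuple(5 + 2 * i for i in range(20))  # 5, 7, ..., 43


@dataclass
class SimParams:
    """Parameters of one synthetic compendium.

    Defaults mirror a large curated compendium: 4000 experiments, a
    128-gene disease set, 20 pathways of 5-43 genes with the first linked,
    factor loading w=1 against noise sigma=1 (per-gene correlation 0.5
    between genes sharing a factor), and 100 pure-noise background genes.
    """

    n_experiments: int = 4000
    n_disease_genes: int = 128
    pathway_sizes: tuple[int, ...] = _DEFAULT_SIZES
    linked_pathways: tuple[int, ...] = (0,)
    w: float = 1.0
    sigma: float = 1.0
    n_background_genes: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.pathway_sizes = tuple(int(s) for s in self.pathway_sizes)
        self.linked_pathways = tuple(sorted(set(int(i) for i in self.linked_pathways)))
        if self.n_experiments < 2:
            raise ValueError("n_experiments must be at least 2")
        if self.n_disease_genes < 1:
            raise ValueError("n_disease_genes must be positive")
        if any(s < 1 for s in self.pathway_sizes):
            raise ValueError("pathway sizes must be positive")
        if any(i < 0 or i >= len(self.pathway_sizes) for i in self.linked_pathways):
            raise ValueError("linked_pathways indices out of range")
        if self.w <= 0:
            raise ValueError("loading strength w must be positive")
        if self.sigma <= 0:
            raise ValueError("noise sd sigma must be positive")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground truth planted by :func:`generate_compendium`."""

    linked_pathways: tuple[int, ...]
    rho_gene: float          #: population correlation of two factor-sharing genes
    rho_canonical: dict[int, float] = field(default_factory=dict)
    seed: int = 0


def theoretical_gene_correlation(w1: float, w2: float, sigma: float) -> float:
    """Population correlation of two genes loading one shared factor."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return w1 * w2 / math.sqrt((w1**2 + sigma**2) * (w2**2 + sigma**2))


def theoretical_canonical_correlation(w: float, sigma: float, p: int, q: int) -> float:
    """Population first canonical correlation of a p-gene set and a linked
    q-gene set, all genes loading the shared factor with strength w.

    The between-set covariance is w^2 * ones((p, q)) (rank one), so the
    optimal combination of each set is its mean, whose variance is
    w^2 + sigma^2 / size; only one nonzero canonical correlation exists.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if p < 1 or q < 1:
        raise ValueError("set sizes must be positive")
    return w**2 / math.sqrt((w**2 + sigma**2 / p) * (w**2 + sigma**2 / q))


def generate_compendium(
    params: SimParams,
) -> tuple[ExpressionMatrix, PathwayCollection, GeneList, SyntheticTruth]:
    """Draw one compendium; identical params (incl. seed) give identical output.

    Returns the expression matrix (disease genes first, then pathway genes,
    then background), the pathway collection, the disease gene list, and the
    planted truth.
    """
    rng = np.random.default_rng(params.seed)
    n, w, sd = params.n_experiments, params.w, params.sigma

    f_shared = rng.standard_normal(n)
    blocks: list[np.ndarray] = []
    gene_ids: list[str] = []

    dis_ids = [f"dis{i + 1:04d}" for i in range(params.n_disease_genes)]
    gene_ids.extend(dis_ids)
    blocks.append(w * f_shared[None, :]
                  + sd * rng.standard_normal((params.n_disease_genes, n)))

    entries: list[tuple[str, str, list[str]]] = []
    for j, size in enumerate(params.pathway_sizes):
        members = [f"pw{j + 1:02d}g{g + 1:03d}" for g in range(size)]
        entries.append((f"pathway_{j + 1:02d}", "synthetic", members))
        gene_ids.extend(members)
        factor = f_shared if j in params.linked_pathways else rng.standard_normal(n)
        blocks.append(w * factor[None, :] + sd * rng.standard_normal((size, n)))

    if params.n_background_genes:
        bg_ids = [f"bg{i + 1:04d}" for i in range(params.n_background_genes)]
        gene_ids.extend(bg_ids)
        blocks.append(sd * rng.standard_normal((params.n_background_genes, n)))

    values = np.vstack(blocks)
    experiment_ids = [f"exp{t + 1:05d}" for t in range(n)]
    expr = ExpressionMatrix(gene_ids, experiment_ids, values)
    pathways = PathwayCollection(entries)
    disease = GeneList(dis_ids)
    truth = SyntheticTruth(
        linked_pathways=params.linked_pathways,
        rho_gene=theoretical_gene_correlation(w, w, sd),
        rho_canonical={
            j: theoretical_canonical_correlation(
                w, sd, params.n_disease_genes, params.pathway_sizes[j]
            )
            for j in params.linked_pathways
        },
        seed=params.seed,
    )
    return expr, pathways, disease, truth
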