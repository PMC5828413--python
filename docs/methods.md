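# Methods

## Model and procedure

`pathcca` treats a gene's expression profile across an n-experiment
compendium as one observation vector, a gene set as a multivariate sample
(experiments are observations, genes are variables), and asks whether two
sets — a disease susceptibility set and one metabolic pathway — share a
common expression axis. The statistic is the first canonical correlation:
the maximum, over weight vectors a and b, of the Pearson correlation
between the combined profiles **M**a and **N**b of the standardized sets.

The decomposition whitens each set with the inverse square root of its
within-set correlation matrix (eigendecomposition; eigenvalues below
`rank_tol` = 1e-10 times the largest are discarded, so duplicated or
collinear genes reduce the number of pairs rather than blowing up the
weights) and takes the SVD of the whitened cross-correlation. Singular
values are clipped to [0, 1] and reported as canonical correlations;
coefficients are scaled so every variate has unit sample (n−1) variance.
An optional ridge `reg` (default 0) stabilizes whitening when genes
approach or exceed experiments; it is off by default because the intended
regime (hundreds to thousands of experiments, tens of genes per set) is
well-conditioned.

Sign indeterminacy is resolved jointly per pair: the largest-magnitude
entry of the first-set coefficient column is made positive and the
second-set column is negated together with it. Flipping the two sides
independently could turn corr(U_k, V_k) negative; the joint flip is
equally deterministic and preserves corr(U_k, V_k) = +r_k, which the
variance-extracted statistics and downstream screening rely on.

Significance uses Bartlett's chi-square approximation to the sequential
Wilks' Λ: Λ_k = Π_{i≥k}(1 − r_i²), χ²_k = −(n − 1 − (p+q+1)/2)·ln Λ_k on
(p−k)(q−k) degrees of freedom. This is the closed-form test canonical
correlation routines conventionally report; it assumes n comfortably
exceeds p + q (a warning is emitted otherwise). The screen thresholds the
first pair's p-value only; all pairs are computed and testable.

Structure loadings are r_1A = AAᵀ r11 and r_2B = BBᵀ r22 — entry (k, j) is
exactly the correlation between variate k and standardized variable j (a
property the tests enforce numerically). The variance-extracted statistic
S is the mean squared first-pair loading over a set's variables: the share
of the set's standardized variance the pair carries. S_a refers to the
pathway side, S_b to the disease side.

## Screening

Pathways are first restricted to genes measured in the compendium and
dropped when fewer than `min_pathway_genes` (default 10, inclusive)
survive. Constant-expression genes are removed per set with a logged
count — silent drops are the likeliest source of off-by-a-few gene-count
discrepancies in screens of this kind, so every exclusion is logged. A
pathway passes when r ≥ r_min, p ≤ p_max, S_a ≥ sa_min and S_b ≥ sb_min.

Threshold provenance is messy in practice, so thresholds are explicit
configuration with three named sets: `methods` (0.6, 1e-5, 0.3, 0.15),
`results` (0.5, 0.001, 0.2, 0.2), and the shipped `default` (0.5, 0.001,
0.15, 0.15) — the loosest combination consistent with every pathway row
the stricter sets are known to have admitted. Benjamini–Hochberg q-values
are reported across pathways as an extra column but never gate the
screen, which operates on the raw first-pair p as published protocols of
this design do.

Each record attaches representative genes: the round(q · S_a) members
(half away from zero; at least 1 for a passing pathway) with
largest-magnitude first-pair coefficients, ties broken by ascending gene
ID. Raw coefficients are the default ranking; a switch
(`rep_from_loadings`) substitutes structure loadings, which are more
stable under within-set collinearity but conflate a gene's weight with
its redundancy. The count rule uses S_a — the pathway-side statistic —
because it is the one that reproduces, across all seven published pathway
rows, the printed representative-gene counts (6, 3, 11, 5, 4, 5, 3); the
disease-side S_b fails this check (e.g. a 10-gene pathway with S_b = 0.93
printed 3 representatives, not 9).

## Network baseline and enrichment

The single-gene baseline connects a disease gene to a metabolic gene when
their Pearson correlation exceeds `r_min` (default 0.6). The threshold is
signed by default — negative coexpression is plausibly informative but is
not what a positive-correlation screen states — with an `absolute` mode
available. Components are maximal connected subgraphs (isolated nodes
excluded), ordered by size then smallest member ID; "hub" means maximum
degree, all ties reported, since subnetwork "centers" have no sharper
standard definition. Enrichment of the network-connected metabolic genes
is an upper-tail hypergeometric test per pathway with Benjamini–Hochberg
correction; the background defaults to the union of pathway genes
measured in the compendium, the most defensible choice when the original
enrichment used an external service with an unstated background.

## Synthetic compendia

The generator plants a single shared standard-normal factor f_s per
experiment: disease genes and linked-pathway genes are w·f_s + ε with
ε ~ N(0, σ²); each unlinked pathway gets a private factor of the same
strength; background genes are pure noise. Defaults mirror a large
curated compendium — 4000 experiments, a 128-gene disease set, 20
pathways spanning 5–43 genes, w = σ = 1, 100 background genes — while
tests pass the smaller condition sets they need explicitly.

Closed forms used as ground truth:

- gene–gene: ρ = w₁w₂/√((w₁²+σ²)(w₂²+σ²)), so w = σ gives ρ = 1/2;
- set–set first canonical correlation for p disease and q linked-pathway
  genes: ρ₁ = w²/√((w²+σ²/p)(w²+σ²/q)) — the between-set covariance is the
  rank-one matrix w²·1·1ᵀ, so the optimal weights are uniform and only one
  nonzero canonical correlation exists. For w = σ = 1, p = q = 10:
  ρ₁ = 1/1.1 ≈ 0.909.

What the simulator deliberately omits: microarray normalization
artifacts, batch effects, heavy-tailed or count-valued expression,
correlated noise between experiments, and overlapping pathway
memberships. Gaussian factors and noise are the simplest model consistent
with Pearson-correlation-based analysis of z-scored profiles. Passing
recovery tests on these compendia therefore demonstrates correctness of
the estimator and screen under the stated model, not robustness to real
compendium pathologies.

## Numerical and design choices

- Standard deviations use the sample (n−1) denominator everywhere,
  matching the zscore/corr conventions of common statistical platforms.
- Z-scoring raises on zero-variance columns rather than silently keeping
  or dropping them; callers (the screen) drop and log.
- Missing expression values are tolerated on input and any gene with ≥ 1
  missing value is dropped, with a logged count, before analysis.
- Null calibration: with no planted link, the Bartlett first-pair p-value
  at p = q = 5, n = 500 rejects at the nominal 5% rate within the
  binomial 99% envelope over replicate simulations (enforced in tests at
  200 replicates).
- Problem sizes in tests (n = 500–5000 experiments, sets of 5–10 genes,
  ≤ 200 replicates) are chosen so every statistical check has enough
  resolution for its tolerance — e.g. ±0.05 on a canonical correlation
  estimated at n = 5000 — while the whole suite stays fast enough to run
  on every change.
- The brute-force oracle for the first canonical correlation (multi-start
  gradient search on corr(Ma, Nb)) lives in the test suite, independent
  of the whitening/SVD path it validates.

## Known limitations

- The Bartlett test is asymptotic; with n near p + q its p-values are
  anticonservative, and the package only warns. Permutation p-values are
  out of scope.
- No sparse or regularized CCA: with q approaching n the first canonical
  correlation saturates toward 1 and the screen loses specificity; the
  ridge option mitigates conditioning, not overfitting.
- Screening on the first pair only: a pathway coupled to the disease set
  through a second, weaker axis is reported (all pairs are computed) but
  not thresholded.
- Gene identifiers are matched by exact string equality; no ID-mapping
  across naming systems is attempted.
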