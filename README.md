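# pathcca

Pathway-level coexpression screening of gene sets by canonical correlation
analysis.

## The problem

Single-gene coexpression networks connect a disease susceptibility gene to
a metabolic gene only when the two are strongly correlated on their own
(e.g. Pearson r > 0.6 across an expression compendium). But a pathway can
track a disease gene set *as a unit* — through a shared regulatory factor
spread thinly over many genes — while every individual gene pair stays
weakly correlated. `pathcca` screens for exactly this situation: it asks,
for each metabolic pathway, whether some linear combination of the
pathway's expression profiles is strongly correlated with some linear
combination of the disease set's profiles.

The intended user is anyone with (1) a genes × experiments expression
compendium (TSV), (2) pathway gene sets (GMT), and (3) a disease gene list
(one ID per line) — for example a COXPRESDB-style human compendium, KEGG
metabolic pathways, and literature-curated coronary-artery-disease
susceptibility genes.

## The method

For the disease set's standardized expression matrix **M** (experiments ×
p genes) and each pathway's **N**ᵢ (experiments × q genes), canonical
correlation analysis finds weight vectors a, b maximizing
corr(**M**a, **N**ᵢb). The implementation whitens each set by the inverse
square root of its correlation matrix (spectral pseudo-inverse, optional
ridge) and takes the SVD of the whitened cross-correlation. For the first
canonical pair (U₁, V₁) it reports:

- **r** — the first canonical correlation;
- **P** — Bartlett's chi-square approximation to Wilks' Λ:
  χ² = −(n − 1 − (p+q+1)/2)·ln Λₖ with Λₖ = Π_{i≥k}(1 − rᵢ²) on
  (p−k)(q−k) degrees of freedom;
- **S_a**, **S_b** — variance extracted: the mean squared structure
  loading (correlation between the variate and each standardized variable)
  of the pathway side and the disease side respectively, i.e. the share of
  each whole set the canonical pair "delegates";
- **representative genes** — the round(q · S_a) pathway members with
  largest-magnitude first-pair coefficients.

A pathway passes the screen when r ≥ r_min, P ≤ p_max, S_a ≥ sa_min and
S_b ≥ sb_min (shipped default 0.5 / 0.001 / 0.15 / 0.15; presets
`methods` = 0.6 / 1e-5 / 0.3 / 0.15 and `results` = 0.5 / 0.001 / 0.2 /
0.2), restricted to pathways with at least 10 measured genes. A bipartite
Pearson network (edges r > 0.6 between disease and metabolic genes), its
connected components and hub genes, and a hypergeometric enrichment test
with Benjamini–Hochberg correction provide the single-gene baseline the
set-level screen is compared against.

A latent-factor simulator generates compendia with known planted
structure: disease genes and *linked* pathways load one shared
standard-normal factor with strength w against noise σ; unlinked pathways
get private factors. Two factor-sharing genes then have population
correlation w²/(w²+σ²), and the disease↔linked-pathway first canonical
correlation is w²/√((w²+σ²/p)(w²+σ²/q)) — closed-form ground truth for
every downstream stage.

## Worked example

Simulate a compendium of 10 disease genes and five 10-gene pathways over
2000 experiments, with pathway 1 sharing the disease factor (w = σ = 1, so
the planted canonical correlation is 1/1.1 ≈ 0.909), then screen:

```sh
pathcca simulate --seed 7 --n-experiments 2000 --n-disease-genes 10 \
    --pathway-sizes 10,10,10,10,10 --linked 0 --n-background-genes 0 \
    --outdir demo
pathcca screen --expression demo/expression.tsv --pathways demo/pathways.gmt \
    --disease demo/disease_genes.txt --out demo/screen.tsv
```

`demo/screen.tsv` (q_value column elided):

```
pathway     n_genes  r       p_value     S_a     S_b     representative_genes                                passed
pathway_01  10       0.9068  0.0000e+00  0.5424  0.5437  pw01g004,pw01g009,pw01g008,pw01g003,pw01g005        True
pathway_04  10       0.1332  1.6917e-01  0.2567  0.1700  pw04g002,pw04g009,pw04g006                          False
pathway_03  10       0.1321  8.8084e-01  0.0748  0.0857  pw03g009                                            False
pathway_05  10       0.1097  8.7633e-01  0.0935  0.0954  pw05g004                                            False
pathway_02  10       0.1092  9.7674e-01  0.2563  0.1670  pw02g003,pw02g006,pw02g001                          False
```

The linked pathway is recovered with r = 0.907 (analytic 0.909), a
first-pair p-value at machine zero, and S statistics near the theoretical
(w² + σ²/q)/(w² + σ²) = 0.55; it reports round(10 × 0.5424) = 5 representative genes. The four
unlinked pathways sit at null-level r ≈ 0.11–0.13 and fail. The same run
is available programmatically:

```python
from pathcca import SimParams, generate_compendium, screen_pathways

expr, pathways, disease, truth = generate_compendium(
    SimParams(n_experiments=2000, n_disease_genes=10,
              pathway_sizes=(10,) * 5, linked_pathways=(0,),
              n_background_genes=0, seed=7))
records = screen_pathways(expr, pathways, disease)
```

`pathcca run --config cfg.yaml` chains simulate/load → screen → network →
enrichment and writes `screen_table.tsv`, `network_edges.tsv`,
`enrichment.tsv` and a `run_log.txt` recording parameters, seed and
dropped-gene counts; identical config and seed reproduce byte-identical
artifacts.

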