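# sccsubtypes

Molecular subtype discovery and downstream characterization for lung
squamous cell carcinoma (SCC) expression cohorts.

Lung SCC mostly lacks targetable driver mutations, and treatment development
depends on resolving the disease's heterogeneity into molecular subtypes.
This package implements, as a tested and reusable pipeline, the computational
chain used to split SCC cohorts into three expression subtypes and to work
out what distinguishes them: consensus non-negative matrix factorization
(NMF) with cophenetic rank selection against a randomized-data benchmark,
projection of a cell-line panel onto the discovered subtypes, a compound
sensitivity score over GI50 drug panels, cluster-versus-rest differential
microRNA analysis with cross-cohort intersection, label-permutation gene-set
enrichment, transcription-factor candidate nomination from miR-promoter
binding-site annotations, and inverse-correlation screening of candidate
microRNA targets.  A synthetic-data generator with planted ground truth
(cluster structure, signature genes, miR shifts, drug effects, one planted
TF, one planted miR→target coupling) makes every stage testable end to end
without external downloads.

It is written for computational biologists working with bulk expression
matrices (RNA-seq or arrays, log2 scale), drug-response panels and gene-set
collections.

## The model

Given a non-negative expression matrix *V* (genes × samples, low-expression
rows removed, rows min-shifted to ≥ 0), NMF factorizes *V ≈ WH* under the
generalized Kullback–Leibler divergence

    D(V‖WH) = Σᵢⱼ [ vᵢⱼ log(vᵢⱼ/(WH)ᵢⱼ) − vᵢⱼ + (WH)ᵢⱼ ]

with Brunet's multiplicative updates.  Columns of *W* are metagenes; sample
*j* belongs to the metagene with the largest coefficient in *H[:, j]*.  Over
many random restarts, the consensus matrix *C* records how often two samples
co-cluster; rank *k* is scored by the cophenetic correlation ρₖ between the
consensus distances 1 − *C* and the ultrametric distances of their
average-linkage dendrogram, and is accepted only if ρₖ exceeds the same
statistic computed on a row-permuted copy of the data by a clear margin.

Downstream, for a clustered cell-line panel the sensitivity score of
compound *c* in cluster *g* is

    score(c, g) = mean(−log₁₀ GI50 over cluster-g lines)
                − mean(−log₁₀ GI50 over all lines),

positive when the cluster is more sensitive than the panel.  Differential
microRNAs come from per-feature one-way ANOVA (Benjamini–Hochberg FDR) with
cluster-vs-rest fold changes 2^(Δ mean log2), intersected across cohorts.
Gene-set enrichment uses the weighted Kolmogorov–Smirnov statistic with
sample-label permutation; miR targets are screened by per-gene OLS against
the miR (inverse regulation = negative slope) plus a fold-change direction
filter across both cohorts.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from sccsubtypes import (SimulationConfig, simulate_study,
                         filter_low_expression, rank_survey_with_null,
                         select_rank, consensus_cluster)
from sccsubtypes.nmf import shift_nonnegative

study = simulate_study(SimulationConfig(master_seed=1))   # 3 planted subtypes
V = shift_nonnegative(filter_low_expression(study.mrna))  # 587 x 60 after filter

survey = rank_survey_with_null(V, 2, 6, n_runs=20, seed=1, max_iter=500)
print("selected rank:", select_rank(survey))

res = consensus_cluster(V, k=3, n_runs=20, seed=1)
print("cophenetic rho:", round(res.cophenetic, 4))
print("ARI vs planted labels:",
      adjusted_rand_score(study.truth.labels, res.assignment))
```

prints

```
selected rank: 3
cophenetic rho: 1.0
ARI vs planted labels: 1.0
```

i.e. the survey recovers the planted three-cluster structure, the consensus
matrix is perfectly block-structured (ρ = 1), and the sample assignment
matches the planted labels exactly.  The same objects feed the rest of the
chain (`sensitivity_score`, `diff_expr_table`, `gsea_permutation_test`,
`compile_master_list`, `inverse_correlation_screen`, ...), and the
`sccsubtypes` command-line tool exposes each stage
(`simulate`, `cluster`, `project`, `drugscore`, `diffexpr`, `intersect`,
`gsea`, `regnet`).

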