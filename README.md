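# gliomanet

Multi-stage network inference for dissecting regulatory switches between
low-grade and high-grade glioma — and, more generally, for any two-condition
expression study with a protein-interaction scaffold, a perturbation time
course and patient survival data.

Low- and high-grade gliomas differ not only in which genes are expressed but
in how regulators are wired to their targets. This package implements the
complete analysis arc for detecting such rewiring: restrict a
protein–protein interaction network to a differential-expression signature
and modularize it; reverse-engineer hub-anchored co-expression networks per
tumour grade and quantify each regulator's grade-specific connectivity;
extract response dynamics and time-delayed cluster correlations from an
implantation time course; integrate interaction, expression and
co-expression evidence into a single high-scoring subnetwork with a
prize-collecting Steiner tree; and test whether the implicated gene
stratifies patient survival. A synthetic-data generator with planted ground
truth makes every stage testable without access to clinical cohorts.

## The statistics at the core

**Differential expression.** Per-gene Welch *t*-tests with
Benjamini–Hochberg control; a gene enters the signature when
|log₂FC| > 1.5 and *q* < 0.01.

**Percolation hubs.** For each node *v* of the signature-restricted
interactome, score(v) = (S − 1 − S₋ᵥ)/(S − 1), where *S* is the size of the
largest connected component and *S₋ᵥ* the largest component after deleting
*v*. Nodes scoring above mean + 2 SD are hubs; the analysis network is the
hubs plus first neighbours, partitioned by greedy modularity maximization.

**Mutual-information networks.** MI(X, Y) in nats from equal-frequency
(rank) binning with B = ⌊n^⅓⌋ bins and Miller–Madow bias correction,
computed hub-vs-all per condition. Significance comes from a permutation
null whose upper tail is fitted with an exponential so thresholds at
p < 10⁻⁵…10⁻⁸ are reachable without 10⁷ permutations. Indirect edges are
pruned by the data-processing inequality: in any fully connected triangle
the edge with MI_ij < (1 − ε)·min(MI_ik, MI_jk) is removed. Hub
grade-specificity is d = (k̂_A − k̂_B)/(k̂_A + k̂_B) on degrees normalized by
each network's edge total; |d| > 0.4 calls a hub condition-specific.

**Time-course dynamics.** A two-step filter (log₂ range ≥ 1, then a
permutation-calibrated smoothness statistic at α = 0.001) feeds
partitioning-around-medoids clustering on correlation distance. Medoid
profiles are cubic-interpolated to 100 points; the earliest time the
profile moves 50% of its dynamic range classifies clusters as rapid
(≤ 12 h), intermediate (12–24 h] or delayed (36–48 h]. Cluster pairs are
linked when the maximum Spearman ρ over time shifts of 13–24 h exceeds 0.9.

**Prize-collecting Steiner integration.** Node prizes combine a
beta-uniform-mixture score on differential-expression p-values,
S_BUM(p) = (a − 1)(ln p − ln τ), with weighted indicators for bait-protein
interactors (β) and co-expression with the bait (γ). The module is the
connected subtree anchored at the bait maximizing Σ prizes − c·|edges|,
found by greedy path growth, strong pruning and set-level local search;
significance comes from prize permutation with both an empirical and a
normal-tail parametric p.

**Survival.** Kaplan–Meier curves, the two-group log-rank test, and an
optimal-cutpoint scan: every covariate split leaving ≥ 10% of patients per
side is scored by the log-rank statistic (the Cox score test for the binary
grouping), and the minimum-p split is reported together with a
permutation-adjusted p that corrects the scan's multiplicity.

## Worked example

```sh
gliomanet run --seed 1 --out runs/demo
```

runs the full pipeline on synthetic data with planted ground truth and
prints:

```
simulate: 300 nodes, 980 edges, 126 samples, 90 time-course genes
de: 58 genes selected
ppi: 0 hubs, 3 communities
minet: 7 gradeII-specific, 7 gradeIV-specific hubs
timecourse: 37 genes kept, 6 clusters, 7 significant lagged pairs
integrate: module of 66 nodes, net score 1757.76, empirical p 0.0099, parametric p 1.62e-05
survival: cutpoint at rank 98, log-rank p 1.12e-08 (adjusted 0.00498), HR 2.47
```

Reading the lines: the generator planted 60 differentially expressed genes
in a 300-gene universe with a 45 + 81 sample design; the signature recovers
58 of them. The interactome stage finds no single node whose deletion
shatters the (dense) differential subnetwork — hub calling is meaningful on
sparser graphs — and falls back to modularizing the signature network into
3 communities. The MI stage classifies all 14 planted regulators to their
correct condition (7 + 7). The time-course stage keeps the smooth planted
profiles, clusters them, and links lagged cluster pairs including the
planted 18 h delay. The integration stage finds a 66-node module around the
planted 25-gene subnetwork whose score no prize permutation matches
(empirical p at its 1/101 floor; the parametric tail puts it near 10⁻⁵).
The survival stage places the optimal cutpoint at rank 98 of 200 — the
planted hazard step is at the median — with a hazard-ratio estimate of 2.5
against a planted ratio of 3 under censoring.

Every artifact (expression matrix, networks, cluster summaries, prize
tables, scan curves) is written as TSV/GraphML next to a `manifest.json`
recording parameters, per-stage seeds and file digests; rerunning with the
same configuration reproduces every file byte-identically.

Subcommands `simulate`, `de`, `ppi-modules`, `mi-net`, `timecourse`,
`integrate` and `survival` expose each stage separately on user-supplied
TSV/GMT/GraphML files; see `gliomanet <cmd> --help`.

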