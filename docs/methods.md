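# Methods

This note records the models behind each stage, the defaults and why they
are set where they are, what the synthetic generator does and does not
emulate, and the numerical choices a maintainer would want to know.

## Differential expression (`gliomanet.expression`)

Per-gene two-sample *t*-tests use the Welch (unequal-variance) form: the
motivating design is unbalanced (45 low-grade vs 81 high-grade samples)
and variance homogeneity across tumour grades is not defensible a priori.
log₂ fold change is mean(B) − mean(A) on log2-scale input, with B the
higher grade, so positive values mean up in the aggressive tumour.
Benjamini–Hochberg q-values are computed by the step-up rule, clipped to 1
and order-preserving; NaN p-values are rejected rather than ranked. A gene
with zero variance in both groups gets p = 1 and a `zero_variance` flag —
degenerate evidence, not an error. Signature defaults (|log₂FC| > 1.5,
FDR < 1%) are the clinical-contrast thresholds; the siRNA-contrast
convention of FDR ≤ 5% is available by argument (a t-test/BH engine is
used for that contrast too, as a documented substitution for the
resampling-based DE tool the assay originally used).

Quantile normalization maps every sample onto the across-sample mean of
sorted columns; ties receive the average reference value over tied ranks.
The cross-hybridization filter consumes *net* (background-subtracted)
signals and removes a probe when the other-species signal exceeds 64 units
or contributes more than 15% of the total; a probe with zero total signal
carries no evidence and is kept. Gene-set enrichment is the one-sided
hypergeometric upper tail per set (sets intersected with the universe
first) with BH across sets at FDR 10%; annotation comes from user-supplied
GMT files, with no ontology download or term propagation.

## Interactome modularization (`gliomanet.ppi`)

The percolation score is implemented as normalized largest-component
disruption, score(v) = (S − 1 − S₋ᵥ)/(S − 1). The term is used in the
literature for more than one quantity (a betweenness-like percolation
centrality is the main alternative); the disruption reading is
parameter-free, matches the name, and is checked against an exhaustive
delete-one census in the tests, so it is the one implemented. Hubs are
called above mean + 2 sample standard deviations (n − 1 denominator).
A consequence worth knowing: on densely connected graphs no single
deletion shrinks the giant component, all scores are ~0 and no hubs are
called — the score is informative on sparse, signature-restricted
networks, which is where the pipeline applies it. Community detection is
greedy modularity maximization (the published GLaY partitioner's role
here is simply "community detection", and planted-module recovery is the
acceptance surface); communities below `min_size` (default 5) are dropped
from the report, and isolated nodes are excluded from the modularity
computation.

## Mutual-information networks (`gliomanet.minet`)

MI uses equal-frequency rank binning with B = max(2, ⌊n^⅓⌋) bins — robust
to monotone transforms of log-expression — plus the Miller–Madow
correction ((Kx−1)+(Ky−1)−(Kxy−1))/(2n) on occupied-bin counts, clipped at
zero. The estimator depends only on ranks, so its permutation null is
generated once per sample size by shuffling a rank vector; the tail above
the (1 − max(0.05, 20/n_perm)) quantile is summarized by its mean excess
(an exponential fit), which extrapolates thresholds and p-values far below
1/n_perm. The default working cutoff is p < 10⁻⁵, with 10⁻⁶…10⁻⁸ for
high-stringency static networks. DPI pruning evaluates all triangles
against the pre-pruning network simultaneously, so edge order cannot
matter; in a hub-anchored network the only representable triangles are
hub-incident ones.

The grade-specificity statistic normalizes each hub's degree by the total
hub-incident edge count of its network (grade networks differ in size),
then contrasts d = (k̂_A − k̂_B)/(k̂_A + k̂_B) ∈ [−1, 1]; the printed 0.4
cut is meaningful on this bounded scale. The underlying phrase
("proportion of connections between grades") admits more than one reading;
this bounded contrast is the implemented one. A hub with zero degree in
both networks has undefined d and is flagged, not guessed.

## Time-course dynamics (`gliomanet.timecourse`)

The two-step regulation filter keeps genes spanning ≥ 1 log₂ unit, then
removes noisy genes with a permutation-calibrated smoothness statistic:
var(window-3 moving-average fit)/var(residual), compared with the pooled
null obtained by time-shuffling all surviving profiles, at α = 0.001.
This stands in for an empirical-Bayes timecourse DE method that requires
replicate structure the single-series design lacks; the stand-in preserves
the filter's role (drop time-unstructured genes) and its level, and its
retention of pure-noise genes is verified to sit at ≈ α.

Clustering is partitioning around medoids (BUILD initialization + Voronoi
iteration) on correlation distance 1 − Pearson, written in-package because
the installed scikit-learn provides no PAM; mean silhouette width is
reported to guide the choice of k when it is not fixed. Medoids are actual
member profiles. Interpolation to 100 points uses a natural cubic spline
— piecewise, not one global high-degree polynomial, to avoid Runge
oscillation — with endpoints preserved exactly. Response time is the
earliest interpolated time at which the profile has moved 50% of its
dynamic range from its initial value; classes are rapid (≤ 12 h),
intermediate (12–24 h] and delayed (36–48 h] on the continuous axis, with
the (24, 36] gap and times past 48 h unclassified. Window upper edges are
softened by one grid step because the crossing detector reports the first
grid point past the true crossing.

Lagged correlation evaluates Spearman ρ at lag 0 and at every grid lag
whose absolute hour value lies in [13, 24], both directions, overlapping
segments only (≥ 10 points); the maximum signed ρ wins and a pair is
significant above 0.9. Signed maximum means anti-correlated pairs are
never significant; an `absolute` option exposes the alternative. Two
facts shape test design here: (i) Spearman is invariant to monotone
reshaping, so a *monotone* (sigmoid) profile pair is rank-perfect at every
lag and the procedure cannot localize their shift — lags are therefore
planted on transient "pulse" profiles (logistic rise times logistic
decay), which are also the realistic shape for implantation responses;
(ii) an 18 h lag is not a multiple of the 100-point grid step (≈ 1.09 h
for a 108 h span), so the best alignment is off by up to half a step and
the recovered ρ is high but not 1.

## Steiner integration (`gliomanet.steiner`)

P-values are modelled as a beta-uniform mixture f(p) = λ + (1 − λ)a p^(a−1),
fitted by maximum likelihood with a logistic reparametrization from
several starts. The FDR-controlled threshold is
τ = ((π̂ − FDR·λ̂)/(FDR·(1 − λ̂)))^(1/(â − 1)) with π̂ = λ̂ + (1 − λ̂)â, and
the node score (a − 1)(ln p − ln τ) is zero at τ and positive below it.
τ defaults to FDR 5%. The three-layer prize is additive:
S(v) = S_BUM(p_v) + β·[v is a bait interactor] + γ·coexpr(v), with β = γ = 1
by default and co-expression rescaled to [0, 1]; the additive form with
exposed weights is this package's reading of "integrate three independent
evidence sources", and is the single biggest interpretation in the
package. With β = γ = 0 the pipeline reduces to plain BUM-score module
detection, and a regression test pins that reduction.

The solver is rooted at the bait. Edge costs are uniform, which makes the
net score a function of the connected node set alone; the solver runs four
greedy growth passes (max-profit / nearest-target ordering × two
non-negative Dijkstra step metrics: prize-discount clipped at a floor, or
shifted by the largest prize), strong-prunes after every attachment,
keeps the best checkpoint, and then polishes the node set by deterministic
local search whose moves are single additions, star additions (a boundary
node together with its positive outside neighbours — the move that pays
for a negative hub through the prizes behind it), depth-2 stars,
non-articulation removals, and — on graphs up to 150 nodes — a stalled
perturb-and-repair pass that applies each candidate addition, cleans up by
removals, and accepts net improvements (this captures swaps where a new
bridge makes an old one redundant). The result is always a tree containing
the seed and never scores below the singleton. Against brute-force
enumeration on 10-node instances the solver attains the optimum on the
test batches; the suite asserts ≥ 95% of optimum.

Module significance permutes prizes over nodes (the evidence, not the
topology, is the randomized quantity; degree-preserving rewiring would
test a different null) and reports both the empirical p with the
(r + 1)/(n_perm + 1) pseudocount and a normal-tail parametric p from the
permuted score distribution — the parametric tail is how p-values far
below 1/n_perm remain representable.

## Survival analysis (`gliomanet.survival`)

Kaplan–Meier and the two-group log-rank test are implemented directly in
numpy — the cutpoint scan needs the log-rank statistic for every
admissible split and every permutation, and the vectorized form computes
all splits in one matrix product — with lifelines used as the independent
oracle in the tests (curves and p-values agree to numerical precision).
Tied event times use the standard simultaneous-risk-set convention. The
"maximally selected" cutpoint scan ranks patients by the covariate, scores
every split leaving ≥ 10% of the cohort per side (bounds exposed), and
returns the minimum-p split. Because the scanned minimum p is known to be
anti-conservative (the calibration test measures a ~40% nominal-5%
rejection rate under the null), a permutation-adjusted p — full scan
repeated under covariate permutation — is always reported alongside, and
is constrained to be ≥ the raw p. The hazard ratio of the chosen split
comes from a univariate Cox fit (lifelines).

## Synthetic data (`gliomanet.synthetic`)

The generator plants exactly what the downstream stages claim to detect.

* **Interactome**: Barabási–Albert preferential attachment (heavy-tailed
  degrees, the regime where hub detection is meaningful), with the planted
  module grown as a randomized BFS neighbourhood — a connected induced
  subgraph without altering the degree sequence — and optionally densified
  internally (`module_edge_prob`; the pipeline demo uses 0.3) so community
  detection has a planted answer. The m = 1 case stays a tree.
* **Two-condition expression**: 45 + 81 samples by default, mirroring the
  motivating clinical contrast (tests of MI recovery use 150 + 150, the
  regime the recovery tolerances are stated for). Half the planted
  regulators couple to their targets only in condition A, half only in
  condition B — the connectivity switch. Coupling is linear,
  target = a·hub + e with a = r/√(1 − r²) at unit variances, hitting the
  requested population correlation exactly; noise-free coupling degenerates
  to equality. A configurable gene subset receives a mean shift in
  condition B to create the DE signature.
* **Time course**: 10 points at 12 h spacing by default; cluster profiles
  are logistic in time, crossing half their range at the stated response
  time, with lag-followers as exact time-shifted copies of their source;
  the pulse shape exists for planting recoverable lags (see above).
* **Survival**: exponential event times with the hazard multiplied by the
  planted ratio above the covariate median, and independent uniform
  censoring up to a horizon (no horizon = no censoring).

What the generator does **not** emulate: probe-level microarray structure
(no RMA; expression starts at normalized log2 scale), batch effects,
heavy-tailed expression noise, correlated censoring, population structure
in survival covariates, or hub-target coupling that is nonlinear. Passing
recovery tests therefore demonstrates that the machinery detects what it
models, at synthetic noise levels — not that real cohorts would yield the
same power.

## Reproducibility

Every generator and every stochastic procedure takes an explicit integer
seed and uses one local `numpy.random.Generator`; there is no hidden
global state. The pipeline fans a single global seed out to per-stage
seeds by hashing stage names (CRC32, taken modulo 2³¹), so toggling one
stage never perturbs another's stream. The run manifest records
parameters, per-stage seeds and SHA-256 digests of all artifacts, and a
rerun from the manifest's configuration is byte-identical. Problem sizes
in the test suite and acceptance script (300-node graphs, 150 samples per
condition, 20-seed recovery batches, 100-replicate calibrations) are
chosen as the smallest sizes at which the stated tolerances are
statistically meaningful.

## Known limitations

* The percolation score is one reading of an ambiguous term; a
  betweenness-style percolation centrality would rank dense-graph nodes
  differently.
* The exponential tail extrapolation assumes the MI null's upper tail is
  approximately memoryless; thresholds at p ≪ 1/n_perm inherit that
  assumption.
* The PCST solver is a heuristic; optimality is verified only against
  small-instance brute force, and the perturb-and-repair pass is disabled
  above 150 nodes for cost reasons.
* The additive three-term prize and the β = γ = 1 defaults are an
  interpretation; sensitivity to these weights is exposed but not
  systematically mapped.
* `fixed_group_compare` accepts any externally supplied patient
  categorization and deliberately does not guess fold-change class
  boundaries.
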