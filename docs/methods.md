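# Methods

This note documents the statistical models, defaults, numerical choices and
known limitations of `regtrail`, and what the synthetic fixtures do and do
not emulate.

## Coordinates and interval assignment

All internal coordinates are 0-based half-open, matching BED; GTF input
(1-based closed) is converted at the parsing boundary. A gene's TSS is the
most-5′ transcript start: the minimum transcript start on the `+` strand,
the maximum transcript end on the `−` strand. Only `transcript` features
define TSS candidates; exons are ignored. Soft-masked (lowercase) genome
sequence is uppercased, not skipped — candidate regions already encode
accessibility, so repeat masking is treated as orthogonal.

Regulator binding sites are assigned to a gene when they overlap, by at
least 1 bp, an acceptance interval around the TSS. Four built-in schemes
mirror the promoter-window conventions of the common RTI databases:
±1 kb, ±5 kb, ±10 kb, and −10 kb/+1 kb. Asymmetric schemes are oriented by
gene strand — "upstream" means 5′ of the gene — because a promoter-proximal
window applied in fixed genome orientation would face the wrong way for
half the genes. Whether upstream services orient these windows by strand is
not documented anywhere we could verify, so genome-fixed orientation is
available via `orient_by_strand=False`, and a midpoint-containment mode is
available besides the default 1-bp-overlap rule. The acceptance interval
`[tss−a, tss+b]` is treated as a closed position interval. Duplicate
site→gene assignments collapse to a single edge: RTI edges are binary.

## Over-representation tests

With universe size *N*, regulator target count *K*, hit-list size *n* and
overlap *k*, the three tests are: upper-tail hypergeometric *P*(*X* ≥ *k*);
one-sided Fisher on the 2×2 table `[[k, n−k], [K−k, N−K−n+k]]`
(mathematically identical to the hypergeometric tail; both are exposed
because users expect both names); and the upper-tail binomial with
*p*₀ = *K*/*N*. The binomial model does not bound *k* by *K*, so its
implementation only requires 0 ≤ *k* ≤ *n*; the Fisher implementation
clamps *k* to the hypergeometric support minimum max(0, K+n−N) so that
below-support tails return 1 instead of failing on an impossible table.
Only over-representation is computed; under-representation has no use in
this workflow and is omitted.

Eight adjustment methods are exposed (Bonferroni, Šidák, Holm, Holm–Šidák,
Hochberg, Hommel, Benjamini–Hochberg, Benjamini–Yekutieli), backed by
`statsmodels.stats.multitest`. Benjamini–Yekutieli is the default because
regulator target sets overlap heavily, and BY controls FDR under arbitrary
dependence. Regulators with fewer than `min_targets = 2` targets in the
universe are reported only on request — singleton sets produce degenerate
tail tests. Rows sort by (adjusted p, raw p, overlap descending, name).

## Differential expression scores

Fold change assumes log-scale input and is the plain mean difference. The
z-score divides by the pooled standard deviation (a control-only-sd variant
would be asymmetric in the groups); the signal-to-noise ratio divides by
the sum of within-group sds. The independent t is Welch's (no
equal-variance assumption is warranted); the paired t requires a paired
design. Both Wilcoxon statistics are reported as z-values with tie-corrected
variances; the signed-rank drops zero differences. Genes whose score is
undefined (zero spread) are reported with NaN and an explanatory note,
never silently dropped.

The shrinkage t replaces each gene's pooled variance v_g with
v*_g = λ* v_median + (1 − λ*) v_g, where
λ* = min(1, Σ_g Vâr(v_g) / Σ_g (v_g − v_median)²). The variance of each
empirical variance is estimated with the standard unbiased moment
estimator, n/(n−1)³ · Σ_k (w_k − w̄)², applied to the pooled within-group
centered observations (w_k the squared centered values, n the total sample
count). When all per-gene variances coincide, λ* shrinks onto the common
value and the statistic reduces exactly to the classical pooled t — a
property the tests assert. This estimator stabilizes variances at small
sample sizes, the regime where a plain t-statistic rewards
accidentally-quiet genes.

## Regulatory impact factors

RIF1 weights the squared change in regulator–gene correlation between
conditions by each gene's phenotypic impact factor
PIF_j = ½(ē1_j+ē2_j)(ē1_j−ē2_j); RIF2 contrasts the squared
expression-weighted correlations. Both are averaged over the DE genes and
z-standardized across the reported regulators (sample sd). Correlations
require at least 3 samples per group; regulators with zero variance in
either group are skipped with a warning, and standardization is over the
reported regulators only. A DE gene that is constant within one group has
an undefined correlation there; its contribution is treated as zero rather
than poisoning the whole regulator.

Note that both RIF columns are antisymmetric under swapping case and
control: PIF changes sign while the squared correlation change does not, so
RIF1 flips along with RIF2. The activating/repressing label — the sign of
the regulator's mean within-group correlation with the DE genes — is a
pragmatic choice; no canonical definition exists for this output, and the
mean correlation is the most direct reading of "does this regulator move
with its targets".

## TRAP affinity scoring

PCM quality filtering removes matrices whose total information content per
column (against a uniform background, raw counts, 0·log 0 = 0) falls below
0.25 bits. We deliberately filter *low*-information matrices: an
uninformative PCM matches everywhere and contributes only noise, and the
filter's purpose is to exclude low-quality motifs. Among a TF's primary
motifs only the most informative is kept (ties: shorter motif, then motif
ID); secondary binding motifs that pass the filter are kept alongside,
since some TFs genuinely bind two distinct sequence patterns.

Energies follow the Berg–von Hippel mismatch formulation with the published
TRAP constants: λ = 0.7, ln R₀ = 0.584·m − 5.66, pseudocount 1. All three
are exposed as parameters. Occupancies are summed over every offset on both
strands (the reverse strand scores the reverse complement with the same
matrix); windows containing a non-ACGT character contribute zero, and
sequences shorter than the motif score zero.

Gene scores aggregate candidate regions within a window (default 50 kb)
centered on the most-5′ TSS, weighted by exp(−d/d₀) with d₀ = 5 000 bp and
d the distance from region midpoint to TSS. Midpoint distance (rather than
nearest-edge) matches the decay formulation's intent of weighting the
region as a whole; both choices coincide as regions shrink. BED
score/signal columns are ignored — regions are weighted uniformly. Affinity
scores are not length-normalized per region; a longer region genuinely
offers more binding sites.

## INVOKE

Observations are genes: multi-sample expression is averaged to one response
per gene per run. Both features and response pass through log2(x+1) by
default; features are then z-scored (zero-variance columns dropped with a
warning, using a small relative tolerance since summing identical floats
leaves ~1e−16 residual spread) and the response is centered.

Hyperparameters are selected by inner cross-validation minimizing mean MSE
— the objective the penalized fit optimizes — over the elastic-net mixing
grid {0, 0.1, …, 1} and a 100-point log-spaced λ path from λ_max (the
smallest λ zeroing all coefficients, with the mixing parameter floored at
0.001 in the path formula) down to λ_max·10⁻⁴. Ties break toward the first
grid point and the larger (more regularized) λ. Lasso and ridge are the
grid pinned to {1} and {0}; the ridge member is computed in closed form via
SVD, the others via coordinate-descent paths (`sklearn.linear_model.enet_path`).
All partitions are seeded shuffled K-folds, so identical seed and data give
identical folds, hyperparameters, metrics and coefficients.

Reported coefficients come from a final full-data fit at hyperparameters
selected by inner CV on all genes; per-fold coefficients are retained in
the report for inspection. (Averaging coefficients across outer folds is
the main alternative; the full-data fit was chosen because it yields one
self-consistent sparse model rather than an average of differently-sparse
ones.) The |coefficient| ≥ 0.025 display threshold affects reporting and
plotting only, never the model.

## Synthetic fixtures

The generators are pure functions of a seeded `FixtureSpec`; written files
are byte-identical across reruns. Defaults describe a small but realistic
toy problem: 60 genes, 10 regulators with 5–15 targets, 20 samples per
group, log2-scale expression with baseline N(8, 2), noise sd 0.5, planted
DE effect 2.0 log2 units; a 600 kb uniform-composition genome with 8-bp
motifs planted five times per region near a chosen gene; 40 TFs with 6
planted coefficients from ±[0.5, 2] and noise at half the signal sd for the
regression fixture.

Two structural choices matter for interpretation. The correlation-flip
regulator's targets are included among the planted DE genes, because the
RIF formulas weight correlation changes by differential expression — a
regulator whose targets do not change expression is invisible to RIF by
construction. Its coupling term is standardized to twice the noise sd so
within-case correlations sit near 0.9. Second, the regression fixture emits
its response as 2^(signal+offset) − 1 with an offset keeping the raw scale
non-negative, so the modeling pipeline's own log2(x+1) transform and
centering recover exactly the planted linear model.

What the fixtures do **not** emulate: read-level sampling noise, library
size and composition effects, GC bias, chromatin state, linked genes,
realistic motif co-occurrence, or correlated regulator activity. Passing
recovery tests therefore demonstrates correctness of the computations and
sensible behavior under idealized signal/noise, not performance on real
data.

## Problem sizes and determinism

The default verification runs use: the full exact-test grid N ≤ 12
(≈3 200 instances against rational-arithmetic enumeration), 200 RIF
simulations, 200 random 50-bp sequences and 100 planted-motif genomes for
TRAP, 50 genes × 200 sites per interval-scheme fixture, and 1 000–2 000
gene regressions with 25 noisy replicates. These sizes make every check
exhaustive or statistically stable while keeping a full verification run in
the minutes range on a single core. Every stochastic step takes an explicit
seed; there is no hidden global state.

## Known limitations

- Enhancer–gene assignment is purely distance-based; chromatin-conformation
  (Hi-C) informed assignment is out of scope.
- Identifiers are taken as-is; callers must supply consistent gene IDs
  across expression, annotation and RTI inputs.
- The binomial test treats target membership as independent draws, which is
  an approximation to the hypergeometric sampling; it is provided for
  completeness and comparability.
- RIF statistics need moderate per-group sample sizes (correlations at
  n < 10 are noisy); the generator's 20-per-group default reflects the
  regime where the method is informative.
- INVOKE models expression as linear in (log, standardized) affinity scores
  with no TF–TF interactions; coefficients are descriptive feature
  importances, not causal effects, and no significance is attached to them.
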