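# Methods

`bjnet` re-implements, as a tested library, the comparative co-expression
analysis of two *Brassica juncea* cultivars with contrasting nitrogen-use
efficiency (high-NUE "PB", low-NUE "PJK") under graded nitrate supply
(0, 0.25, 2 and 4 mM KNO3 across six timepoints, 21 RNA-seq libraries per
cultivar). The pipeline consumes a gene x sample FPKM matrix; everything
upstream (read QC, assembly, FPKM estimation) is out of scope.

## Expression scale

All network computations run on log2(FPKM + 1). The offset stabilizes
zeros and the log stabilizes Pearson correlation against the heavy right
tail of FPKM; fold-change calling, by contrast, operates on the linear
FPKM scale with a pseudocount of 1 on each group mean. Fold changes are
computed as a difference of logs, log2(m_t + c) − log2(m_c + c), so that
swapping the groups negates every value exactly; the 2-fold gate is
boundary-inclusive with a 1e-9 tolerance in log space (an exact 2-fold
ratio such as 3 vs 0.5 would otherwise miss the boundary by one ulp).

## Filtering

Genes with more than 10 % missing values or variance at or below 1e-12
are removed (the variance floor, rather than an exact zero test, catches
constant genes whose floating-point variance is ~1e-30). Sample outliers
are detected in the sample-sample correlation network: adjacency
(1 + cor)/2, connectivity row sums, standardized; samples below −2.5
standard deviations are dropped. Residual missing values are mean-imputed
per gene, so downstream code can treat NA as an error.

## Network construction

Unsigned weighted networks: a_ij = |cor(x_i, x_j)|^β with a_ii defined as
0 for all sums. Topological overlap follows the standard form

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    l_ij = Σ_u a_iu a_uj (u ∉ {i, j}),   k_i = Σ_u a_iu,

with TOM_ii = 1 and DistTOM = 1 − TOM as the clustering dissimilarity.
Because the adjacency diagonal is zero, the matrix product A·A computes
l_ij with the self-terms already excluded; the implementation is verified
against a brute-force triple loop to 1e-10 on random matrices.

### Choice of β

`soft_threshold_scan` implements the pickSoftThreshold-style rule: for
each candidate power (default 1–20) the connectivity distribution is
binned into 10 equal-width bins, log10(frequency) is regressed on
log10(mean k), and the signed fit index −sign(slope)·R² is reported; the
chosen power is the smallest candidate reaching 0.80, else the best
fitting candidate with a warning.

The pipeline runs this scan as a diagnostic but does **not** use its
choice on synthetic data. The planted-block generator produces a bimodal
connectivity distribution (module genes vs background), not a scale-free
one, so the fit index is uninformative there: across seeds the first
crossing lands anywhere from β = 1 (an over-dense network in which
modules are inseparable) to β = 20 (mean connectivity below 1, every
gene isolated). When the scale-free criterion is inapplicable or
ambiguous, the field's standard fallback is a power chosen by sample
count; for unsigned networks this is 9 below 20 samples, 8 for 20–29,
7 for 30–39 and 6 from 40 up (`default_unsigned_power`). At the study's
21 samples per cultivar the pipeline therefore builds both networks at
β = 8. Real FPKM data analyzed through the `bjnet network --power auto`
CLI path still uses the scan.

### Comparability

Before comparing networks, the two datasets are restricted to their
common gene set and checked for comparability: Pearson correlation
across genes of (i) mean expression and (ii) whole-network connectivity
at each cultivar's power, with two-sided p-values from the t transform
t = r·sqrt((n−2)/(1−r²)). On synthetic data the mean-expression
correlation is ≈ 1 (shared per-gene baselines) and the connectivity
correlation is intermediate (≈ 0.5), mirroring the pattern reported for
the real datasets.

## Module detection

Average-linkage (UPGMA) clustering on DistTOM via
`scipy.cluster.hierarchy.linkage`; an independent naive UPGMA oracle in
the test suite confirms merge heights. scipy's nearest-neighbor-chain
implementation is deterministic for a given input; on exactly tied
dissimilarities its merge order may differ from a textbook
smallest-index rule, which never affects cut memberships at the heights
used here.

The tree cut is a static-height simplification of dynamic tree cut: the
dendrogram is cut at a fraction of its maximum merge height, with
`deep_split` 0–4 mapping to 0.95, 0.90, 0.85, 0.80, 0.75. Clusters below
`min_module_size` (default 30) become "grey"; a PAM-like stage then
re-attaches each grey gene to the module with the smallest average
DistTOM, provided that average lies below the cut height. Surviving
modules are renamed by decreasing size using the conventional WGCNA
color palette. The default `deep_split` is 2 (cut at 0.85), matching the
default of the published dynamic tree cut and sitting comfortably above
typical within-module merge heights (≈ 0.7 at β = 8 for well-formed
modules) while excluding background genes whose chance correlations
place them near, but above, the cut. The full published hybrid
algorithm (adaptive cluster shape criteria) is intentionally not
reproduced; the simplified cut recovers block-structured truth at desk
scale, which is the regime this package targets.

Module eigengenes are the unit-norm first right singular vectors of the
gene-standardized module submatrix, sign-oriented to correlate
non-negatively with the module's mean profile; the explained-variance
fraction is reported. Eigengene-based module merging is available as a
post-process idea but deliberately off: the study describes no merge
step.

## Module–trait statistics

The nitrate trait is, by default, z-scored log(1 + mM KNO3) per sample
(`dose_log`); `dose_linear` and `binary` encodings are available. A
module is significant when |r| ≥ 0.4 and p ≤ 0.05 — the study's gates —
with the sign retained (reported modules include down-regulated ones).
Gene significance GS = |cor(gene, trait)|; zero-variance genes get GS 0
with a warning. Intramodular connectivity kIM sums adjacency within the
module; K = kIM / max kIM puts the top hub of each module at exactly
K = 1, as in the study's hub tables. Hub-TF tables restrict to
TF-annotated genes and rank by K, ties broken by GS then gene id.

## Preservation

Module definitions from the reference cultivar are applied to the test
network. Matching uses an overlap contingency table with upper-tail
hypergeometric cell p-values (population = common genes, draws =
reference module size, successes = test module size); the best match
minimizes p with larger overlap breaking ties.

Preservation strength is a permutation Zsummary built from two
statistics measured on the module's genes: mean off-diagonal adjacency
in the test network (density) and the Pearson correlation of
intramodular connectivity between reference and test (connectivity
pattern). Null gene sets of identical size are drawn without replacement
from the common genes outside the module (default 200 draws,
seed-controlled, pool ordered by gene id so results are invariant to
input gene order); each statistic is standardized by its null mean and
sd, and Zsummary is the average of the two Z scores. Interpretation
thresholds follow convention: > 10 strong, 2–10 weak to moderate, < 2
none. This is a deliberate two-statistic simplification of the published
modulePreservation composite, which averages many density and
connectivity statistics; parity with the full composite is a non-goal.
A consequence worth knowing: in the single-factor generator all
non-hub members share one loading, so the kIM pattern within a module is
mostly estimation noise and Zconnectivity hovers near 0 even for
perfectly preserved modules — Zsummary is then driven by density, which
is the statistic that actually separates preserved (Z ≈ 100+), shuffled
(Z ≈ 0) and random gene sets in practice.

## Enrichment

Singular enrichment analysis with flat annotation labels: for each term
present in the (annotated) study set, p = P(X ≥ k) under a
hypergeometric draw from the annotated background, Bonferroni-corrected
over the terms actually tested, significance at corrected p ≤ 0.05.
The background is the annotated gene universe, not the whole
transcriptome, and no GO-graph propagation is performed — annotations
are treated as opaque labels, which matches how the generator plants
them.

## qPCR

CT tables are long-format with the reference gene (a BjUbq9-like
constant housekeeping gene) as ordinary rows. Technical replicates are
averaged on the cycle scale before differencing (Livak convention);
ΔCT = CT_target − CT_reference, ΔΔCT = ΔCT_treated − ΔCT_control,
ratio = 2^−ΔΔCT with amplification efficiency fixed at 2. Concordance
with RNA-seq is the Pearson correlation of log2 ratios against log2 fold
changes. Exact noiseless concordance (r = 1 to machine precision) holds
for single-library contrasts, which is the study's condition — each
biological condition was pooled into one sequencing library — because
group means of logs and logs of group means coincide only for groups of
one.

## Synthetic data generator

A single latent factor per module, chosen so every downstream statistic
has a closed-form expectation:

* Design: per cultivar, 3 treated doses x 6 timepoints + 3 control
  libraries = 21 samples, as in the study.
* Eigengenes e_m(s): nitrate-responsive modules use
  (dose_effect · z(log(1+mM)) + ε)/sqrt(1+dose_effect²), others pure
  noise; each realization is standardized to unit sample variance, so
  that module tightness is a design constant rather than a property of a
  21-sample random draw (without this, roughly one seed in four produced
  a module whose realized eigengene variance was low enough for the
  whole module to dissolve).
* Genes: x_gs = baseline_g + u·e_m(s) + σ·ε with u = membership_strength
  (default 0.8) and σ = noise_sd (default 0.4), giving within-module
  correlation u²/(u²+σ²) ≈ 0.8 — typical of a well-defined module.
  Background genes are i.i.d. noise around their baseline;
  FPKM = 2^x − 1 clipped at 0 yields log-normal-like marginals.
* dose_effect defaults to 1.0: the latent eigengene-trait correlation is
  then ≈ 0.71 and observed module-trait correlations land in the ±0.4-0.8
  range, the same scale as the correlations reported for the real
  modules (≈ ±0.5); it also keeps the two responsive eigengenes from
  correlating so strongly with each other (0.5 rather than 0.8) that no
  clustering could separate their modules.
* Hubs: per module, the first `n_hubs_per_module` members get loading
  min(0.99, u·(1+hub_boost)) **and** residual noise σ·hub_noise_frac
  (default 0.25). The noise reduction is essential, not cosmetic: with
  21 samples the sampling noise of a Pearson correlation (sd ≈ 0.1)
  exceeds the correlation advantage a higher loading alone confers, and
  loading-only hubs reach a top-5 K rank in only ~10 % of seeds. A hub
  in the sense of the study's tables (K ≈ 0.93-1) is a gene whose profile
  tracks the module eigengene almost perfectly, which requires both high
  loading and low residual noise; with both planted, recovery is ~100 %.
* Annotations: each of 20 GO terms is assigned at base rate 0.05;
  each module's planted term at 10x the odds. TF families cover 10 % of
  genes plus every planted hub.
* Preservation: a fixed fraction of modules (default 0.6 → 3 of 5) keeps
  its membership in the second cultivar; the rest are re-planted on
  fresh background genes, so the reference members become pure noise in
  the test network.
* A constant-FPKM reference gene ("BjUbq9") is appended for the qPCR
  stage; the variance filter removes it from network analysis
  automatically.

What the generator does **not** emulate: count noise (FPKM is treated as
exact), replicate structure, batch effects, correlated background genes,
scale-free degree structure, overlapping or nested modules, and any
genome-specific content. Passing tests therefore demonstrate that the
statistics recover planted structure under a clean factor model, not
that they would resolve modules in arbitrary real data.

## Problem sizes and defaults

The default study-scale configuration is 2,000 genes with five planted
modules of 80 (two nitrate-responsive, three preserved across
cultivars), which keeps a dense TOM, UPGMA and 200-permutation
preservation runs comfortable on a laptop; multi-seed calibration suites
use 600 genes with four modules of 60. Module recovery at the defaults
is ARI ≈ 0.99 with the exact planted module count on every seed
examined. The dense-matrix implementation targets ≤ ~5,000 genes;
block-wise paths for larger gene sets are out of scope.

## Reproducibility

A single `rng_seed` drives the generator; the pipeline derives fixed
per-stage offsets from it (preservation permutations, qPCR noise), so a
stage can be re-run in isolation bit-identically. Manifests omit wall
times so identical runs produce identical bytes.
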