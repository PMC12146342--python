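# Methods

This note documents the models, conventions, and numerical choices behind
`rscukit`, and what the synthetic-study generator does and does not emulate.

## Transcriptome-weighted usage and RSCU

A sample's codon demand is `W(c) = Σ_g TPM(g)·n_g(c)` over the genes of one
gene set, normalized to 1,000 weighted codons (codon-usage-table
convention; the normalization denominator is the total weighted codon
count, so the normalized profile is invariant to global TPM rescaling).
Genes with TPM = 0 contribute nothing but are not removed. Weighting uses
one TPM column per sample; no cross-sample averaging happens before
weighting, because the statistics compare RSCU distributions *across*
samples.

RSCU is computed per synonymous family: `rscu(c) = k·W(c)/Σ_syn W`. Stop
codons are excluded. A family with zero total usage yields *undefined*
(NaN) rather than 0 — a zero would masquerade as strong underrepresentation
in sparse data. Since RSCU is scale-invariant, it is identical whether
computed from raw or per-1,000 usage. Representation thresholds are
inclusive: ≥ 1.5 over, ≤ 0.5 under (configurable); Met and Trp always have
RSCU 1 when expressed and are retained in profiles but excluded from the
PCA features.

CDS are read in frame 0 with no internal-stop checking (curated CDS are
assumed); stop-codon triplets, if present, are counted and then removed at
feature selection. Duplicate FASTA ids keep the first record with a
warning; lowercase sequences are uppercased; `U` is rejected (DNA
convention).

## Batch adjustment

Library of origin (sequence-archive accession prefix SRR/ERR/DRR, or an
explicit `batch` metadata column) defines batches. The adjustment is the
parametric empirical-Bayes location/scale model: standardize each feature
against the grand mean and pooled residual variance, estimate per-batch
additive and multiplicative effects, shrink them across features (normal
prior for locations, inverse-gamma for scales, moment-matched
hyperparameters, iterative conditional solution to 1e-4), remove them, and
restore the grand location/scale. One batch in, identity out;
zero-variance features pass through; singleton batches raise an error
unless `merge_singletons` pools them into the largest batch (EB variance is
undefined at n = 1). Correction is applied to the RSCU matrix that feeds
the PCA, once per analysis. Nonparametric ComBat and covariate-protected
designs are out of scope.

## PCA and interpretation rules

Features are the 59 sense codons excluding ATG and TGG. Standardization
uses the population (n) denominator, the common ML-scaler convention; the
choice only rescales features uniformly. The component count is
K = min(5, smallest k with cumulative explained variance ≥ 0.80).
Components have indeterminate sign; each is fixed so its largest-|loading|
entry is positive, making the "+corr/−corr" codon sets reproducible.

Reporting rules: codons with |loading| ≥ 0.2 are grouped by amino acid, and
an amino acid is highlighted only when ≥ 2 of its synonymous codons pass on
that component (both signs pooled by default; per-sign counting is an
option). Samples are singled out when a signed component score exceeds 5
strictly; an absolute-value mode exists for negative-quadrant samples.
Nucleotide preference of a codon set is ranked at the third (wobble)
position — where synonymous variation concentrates — with `>` between
strictly ordered counts, `=` for ties, ties displayed alphabetically; an
all-positions mode is available.

## Cluster number, methods, validation

Four heuristics are computed on k-means reference partitions (the only
partition family for which inertia is defined) over k = 2..min(10, n−1):
silhouette (max), Calinski–Harabasz (max), inertia elbow, Davies–Bouldin
(min). The elbow is the maximum-curvature point of the inertia curve,
located as the largest deviation from the chord joining the curve's
endpoints after normalization to the unit square; the curve is anchored at
k = 1 (total sum of squares) so an elbow at the low end of the range is
visible. Consensus: a k named by ≥ 2 heuristics wins (smaller k on a 2–2
tie, by parsimony); otherwise the lower median of the votes (cluster counts
are integers). A failed heuristic (no elbow) abstains.

- **k-means**: stage 1 draws 30 % of samples and runs 5 random
  initializations capped at 3 Lloyd iterations, keeping the lowest-inertia
  centers; stage 2 refines on all samples to tolerance 1e-6. If the
  subsample is smaller than k, stage 1 uses all samples (logged).
- **Spectral**: rows are L2-normalized; neighbors = ⌊n/4⌋ (min 1); both a
  Gaussian kernel and a nearest-neighbor graph are fitted and the labeling
  with the higher silhouette kept; a disconnected graph falls back to the
  kernel with a warning.
- **DBSCAN**: min_samples = 2K (K = PCA dimensionality); eps is the knee of
  the ascending min_samples-th nearest-neighbor distance curve (same chord
  rule); absent a knee, an explicit eps is required. Noise keeps label −1;
  an all-noise result is flagged degenerate.
- **Agglomerative**: Ward linkage on Euclidean distances, tree cut at k;
  the linkage tree is retained and exportable as Newick.

Validation computes ARI, AMI, V-measure, homogeneity and completeness
against reference labelings (tissue state, i.e. which gene set weighted the
profile, and embryonic stage). Noise points count as their own category —
dropping them would inflate agreement. The best method maximizes the mean
of the five metrics averaged over the two references; ties break by
tissue-state ARI, then the fixed order agglomerative, k-means, spectral,
DBSCAN.

## Codon statistics

The Mann–Whitney statistic is `U = #{x_i > y_j} + ½#{x_i = y_j}`, computed
via pooled mid-ranks. The exact two-sided p-value is
`P(|U − n₁n₂/2| ≥ |u_obs − n₁n₂/2|)` under the permutation null over all
C(n₁+n₂, n₁) group assignments, ties handled by the same statistic on the
pooled data. Implementation: full enumeration when C ≤ 2×10⁶ (vectorized
over pooled ranks); otherwise the exact shift-algorithm distribution when
there are no ties (the null is then symmetric, so the distance-based
two-sided p equals the doubled one-sided exact p); otherwise a seeded
10⁵-permutation Monte-Carlo p with an add-one correction. The method used
is recorded per test. When U equals its null mean exactly, p = 1 by
definition.

Bonferroni is `min(1, N·p)` with N defaulting to the number of tests
actually run in one comparison family; a larger (global) N may be supplied.
Cohen's *d* uses the unequal-variance denominator `sqrt((s₁²+s₂²)/2)` with
(n−1) variances (a pooled variant exists). Effect bins on |d| are
contiguous: [0, 0.2) very small, [0.2, 0.36) small, [0.36, 0.66) medium,
[0.66, 1.0] large, > 1 very large. Group comparison runs a pooled
(all-sample) test per codon plus per-stage tests when strata are given; the
headline fraction-significant is the pooled per-codon fraction, and
per-stage significant results define each stage's contribution share.
Codons with undefined RSCU or fewer than two defined values per group are
skipped and reported. FDR procedures are intentionally absent.

## Synthetic studies

The generator emulates a bulk-RNA-seq codon-usage study with ground truth
at every stage. Defaults (chosen once as a modest but realistic desk-scale
study): 40 genes per set, CDS length uniform on 200–400 codons, baseline
per-family codon preferences drawn from a Dirichlet with concentration 8
(moderate bias), an RSCU shift of 0.4 planted in six two-fold-family target
codons, nine stages (E10–E18) × 2 samples, log-normal TPM (μ = 3, σ = 1 on
the natural-log scale), a log-linear stage gradient (slope 0.1/stage) on a
random third of genes, two archive batches (SRR/ERR, round-robin) with an
additive log-TPM shift of 0.5, and 4 blacklisted pseudogenes.

Two design points matter for interpretation:

- **Coupled gene sets.** The disease set re-encodes the *same* protein
  sequences as the healthy set under the shifted preferences, using the
  same per-position uniform variates (inverse-CDF sampling). At shift 0 the
  two sets are byte-identical — the null is exchangeable exactly — and
  divergence is confined to the shifted families, growing smoothly with the
  shift. Independently drawn sets would differ in realized codon
  composition even at shift 0, a real (if incidental) difference that
  per-codon tests would legitimately detect; the coupled design isolates
  the planted effect. Consequently the null calibration validates that the
  machinery produces no spurious significance, not sampling variability of
  a between-set comparison.
- **Feasibility redraws.** A target family whose baseline preference
  leaves no room for the planted shift (p + δ/k > 0.95) is redrawn from the
  Dirichlet (deterministically under the seed) before shifting.

The planted shift moves a target codon's expected RSCU by δ
(preference p → p + δ/k, rest of the family rescaled); requests that push a
preference to 1 or shift a whole family are rejected. Expression noise is
log-normal (the standard multiplicative bulk-abundance model) and batch
effects are additive on the log scale, which propagates into weighted-usage
perturbations for the batch stage to remove. The generator does not emulate
read-level noise, isoform structure, gene–gene correlation, or single-cell
sparsity — passing tests demonstrate the pipeline's correctness and
sensitivity under this model, not performance on real libraries.

## Validation problem sizes

The test suite and acceptance script size their simulations for a single
CPU: 1,000 random profiles for RSCU conservation; 50 random instances for
the weighting and Mann–Whitney oracles (group sizes ≤ 7, where full
enumeration is cheap); two 50-sample batches for the batch contract;
60–64-point planted clustering datasets; 100 replicate studies (4 stages
× 2 samples) for null calibration and 50 (5 stages × 4 samples, 20
profiles per group) for power at shift 0.4; and one full pipeline run,
executed twice, for end-to-end reproducibility. The end-to-end recovery
check uses a pure planted 2-group construction (shift 0.8, expression noise
σ = 0.5, no stage gradient, 120 genes per set; batch effects still
planted), so that the two-group structure unambiguously dominates the
retained score space. Two effects make this necessary. First, TPM-weight
fluctuations induce *correlated*, low-rank noise across codons, so
per-codon separation can be 15σ while the multivariate separation along
the leading noise direction is only 2–3σ. Second, standardization gives
every no-signal codon unit variance however small its raw noise, and with
few genes the correlation keeps a handful of large noise components in the
capped 5-component space; a larger gene pool flattens that noise spectrum
(higher effective rank). Under moderate conditions the consensus heuristic
therefore sometimes (correctly, given the geometry) proposes k = 3–5 and
sub-splits a state group.

## Known limitations

- The density-based method's eps rule needs a genuine density gap; on
  smoothly decaying (e.g. Gaussian) clusters the k-distance curve has no
  sharp knee and fringe points become noise.
- Spectral clustering's row normalization projects scores onto the unit
  sphere; structure that differs only in radius from the origin collapses.
- The exact-test Monte-Carlo fallback (large, tied samples) gives
  resolution limited by 10⁵ permutations (p ≥ 1e-5).
- Batch adjustment assumes no batch–group confounding; with confounding it
  will remove biology along with the batch effect.
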