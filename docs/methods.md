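# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
study does and does not establish.

## Data model and conventions

Expression matrices are dense gene-by-sample tables carrying an explicit
scale flag, either linear RPKM or log2(RPKM+1); the log transform is a
pipeline stage that refuses to run twice. Missing values are not permitted
— the readers fail rather than impute. Genomic coordinates are 0-based
half-open (BED-native) everywhere; "at least 1 bp of overlap" therefore
means `min(end) − max(start) ≥ 1`, and book-ended intervals share no base.
Survival times carry a declared unit (`# time_unit=...` header line) and
are never converted.

## Signature extraction

Three filters applied in sequence to the TAM expression matrix:

1. *Expression floor* — drop genes whose maximum log2(RPKM+1) over samples
   is < 1 (equality kept). Unit: log2(RPKM+1); default 1 means the gene
   never reaches 1 RPKM.
2. *Activity correlation* — per matched tumor sample, mesenchymal activity
   is the mean gene-wise z of a mesenchymal reference set; a TAM gene is
   kept iff its Pearson r with that activity is > 0.7 **and** its
   two-sided p (t-distribution, n−2 df) is < 0.05, both strict. The
   two-sided p is kept even though selection is one-directional, matching
   the conjunction as stated. TAM samples are matched to tumor samples by
   an explicit pairing key, never by column order. A config flag restricts
   the correlation to condition samples only; the default uses all matched
   pairs.
3. *Stromal filter* — the qualitative notion "uniquely expressed by
   non-malignant cells" is operationalized with two thresholds on
   two-compartment PDX profiles: stromal-compartment mean log2 ≥ 1 and
   stromal − tumor mean difference ≥ 1 (i.e. ≥ 2-fold linear). Both are
   config-exposed; candidates absent from a PDX matrix are excluded with a
   warning rather than an error.

Per-stage survivor counts are returned and logged so the filter ladder is
auditable against the inputs.

## Scoring

The single-sample scorer is the mean of gene-wise z-scores (ddof = 1),
deterministic and location/scale-invariant per gene; rank-based
single-sample GSEA variants are monotone-equivalent for the downstream
median/tertile stratification and are deliberately out of scope.
Master-regulator activity is mean z over positive targets minus mean z
over negative targets (zero if a regulon half is empty). Stratification
uses strict cuts with ties going low; the tertile rule uses order
statistics, so with distinct scores exactly ⌊n/3⌋ samples land in each
outer group. The degenerate all-zero-delta longitudinal case reports
(t = 0, p = 1) so permutation loops remain well defined. Pairwise group
comparisons are Welch t with Benjamini–Hochberg adjustment.

## Active binding network

Motif occurrences (pre-thresholded upstream — motif scanning itself is out
of scope), a TSS table, and one or more chromatin-state segmentations are
combined: promoter windows are TSS ± `promoter_flank` (default 5000 bp,
symmetric, strand-ignored, truncated at 0); an edge TF → gene requires a
motif site overlapping the window and at least one active-state segment by
≥ `min_overlap` bases (default 1). The active-state whitelist is an exact
string-match config value (default: TssA, TssFlnkm, TssFlnkU, TssFlnkD,
Tx, EnhG1, EnhG2, EnhA1m, EnhA1) so any segmentation dialect can be
accommodated. Several segmentations are pooled by union by default (a site
active in any epigenome counts), switchable to intersection. Edge support
counts (site, promoter-window) pairs whose site is active; a site
overlapping two active segments counts once.

## Network inference

Per target, a least-squares gradient-boosted tree ensemble (scikit-learn;
200 trees, depth 2, shrinkage 0.05, 0.9 row subsampling — desk-scale
defaults, all config-exposed) is fit on the target's ABN parents plus
*shadow features*: row-permuted copies of the real TF columns. Feature
importance is cumulative impurity (squared-error) reduction, normalized
jointly over real and shadow features, so real importances sum to ≤ 1 with
the remainder attributed to shadows. An edge survives iff its importance
strictly exceeds the target's maximum shadow importance. This
permutation-null gate replaces the refinement heuristics of the published
boosting-based network tools with a self-contained definition of the same
intent: prune prior edges unsupported by expression.

Shadows default to 8× the number of candidate TFs, capped at 64. The count
matters: with as many shadows as real features, an all-noise target would
beat the max-shadow gate half the time by exchangeability; at 8× the false
pass rate is ≈ 1/9 per target before the boosting's own concentration,
and the measured decoy-edge retention on the default synthetic system is
≈ 0.02–0.03.

Edge signs come from the Spearman correlation of TF and target expression
(robust to residual skew on the log scale); an exact zero is logged and
assigned +1. Regulons are per-TF target sets sorted by weight, truncated
at 150, split by sign, and dropped below 10 targets.

Inference is intended to run on a large cohort without condition structure
(the synthetic study provides a 60-sample cohort for this) while the
differential ranking uses the small condition-vs-control design; regulons
inferred on one matrix are scored on the other.

## Master regulators

The ranking metric is the per-gene Welch t (condition minus control;
config-switchable to signal-to-noise), ties broken lexicographically for
full determinism. The enrichment score is the classic weighted
Kolmogorov–Smirnov running sum with weight exponent 1; the signed extreme
deviation is reported, with ties between the positive and negative extreme
(within 1e-9) resolved to the positive side so independent implementations
agree. Negative (repressed) targets are scored on the sign-flipped
ranking; the combined ES is the support-weighted mean of the two halves.

Significance uses a **gene-set permutation null** — random same-size sets,
add-one smoothing p = (1+k)/(n_perm+1) — not sample permutation: with 3
vs 6 samples only 84 relabellings exist, far too few for p < 0.05 at
regulon scale. The p is one-sided in the *enrichment* direction: the
signed-regulon construction already orients a true condition-active
regulator positive, a depleted regulon gets p near 1, and the null
rejection rate stays at the nominal level (a direction-matched one-sided p
would double it). NES divides the ES by the mean |null ES| of the same
sign. The master-regulator flag uses the raw permutation p at α = 0.05,
with BH q reported alongside, since the emulated workflow flags at raw
P < 0.05 across hundreds of TFs.

## Survival and outcome statistics

Kaplan–Meier curves and the log-rank test are delegated to lifelines (the
test suite checks both against textbook product-limit and hypergeometric
oracles). Stratification defaults to a median split; the tertile option
mirrors common cohort practice. Alteration enrichment uses the two-sided
Fisher exact test by the point-probability method (sum of table
probabilities ≤ the observed), sample odds ratios with Haldane–Anscombe
+0.5 when a cell is zero, BH across genes, and pathway-level
altered-in-any-member fractions per group.

The limiting-dilution estimator fits the single-hit Poisson model
ln(fraction negative) = −f · dose by least squares through the origin over
non-degenerate doses (0% or 100% negative wells carry no log-scale slope
information and are excluded with a warning). The common "x-intercept of
the regression" phrasing for this assay conflicts with the single-hit
model that the standard ELDA tool implements; the single-hit fit is what
is implemented here. The Wald CI is computed on log f with delta-method
variances for the per-dose log fractions and inverse-variance weighting.

## Synthetic study

The generators emulate the study conditions end to end: 3 condition vs 6
control TAM profiles with matched tumor profiles; a 20-TF × 300-target
regulatory system with 4 planted condition-active regulators (regulon
sizes 10–30, edge weights 0.5–1.5, 70% activating, target noise sd 0.5);
a binding prior holding the true edges plus 3× decoys; 60 signature genes
among 80 planted stromal genes, 150 background genes, and 40
low-expression genes; 8+8 PDX compartment samples; 91 longitudinal pairs
(30 mesenchymal transitions, 1σ shift); 373 patients with hazard
h0 · HR^z(score), HR = 2 per sd, baseline median 12 months, administrative
censoring at 60; and binomial limiting-dilution counts. One root seed
derives per-generator substreams by fixed offsets, and identical
(config, seed) reproduces every output byte for byte. Expression is
exported in linear RPKM via 2^x − 1 floored at 0 so the pipeline's own log
transform is exercised.

Two constructions are exact rather than merely in-expectation, so the
planted structure is re-measurable on the emitted data at these small
sample sizes:

* planted signature genes are built by projection to have sample Pearson
  correlation with the latent mesenchymal activity exactly equal to the
  drawn target r (uniform in [0.75, 0.95]); at n = 9 the sampling spread
  of an approximate construction (sd ≈ 0.1) would otherwise swamp the
  planted window;
* the condition shift of planted regulators is planted exactly by
  removing the within-condition mean of the TF noise, so the realized
  group difference equals `effect_size` (2 sd); with 3 condition samples a
  purely random realization has sd ≈ 0.8 and the planted effect would be a
  seed lottery. Target-level noise remains fully random.

What the synthetic study does **not** emulate: RNA-seq count noise
(negative-binomial dispersion), gene–gene correlation beyond the planted
regulatory structure, batch effects, single-cell data, or genome-scale
interval counts. Passing recovery tests therefore demonstrates the
pipeline's correctness and calibration under its stated generative
assumptions, not its power on real cohorts.

## Numerical choices and degenerate inputs

Welch t with zero variance in both groups is 0 for equal means and capped
at ±1e12 otherwise (the ranking requires finite statistics). GSEA hit
weights that sum to zero (all-zero statistics at the hits) fall back to
uniform increments. Permutation p is never below 1/(n_perm+1). Constant
genes are excluded from z-scoring with a warning and are unselectable in
the correlation filter. Boosting on a constant target returns zero
importances. All stochastic steps derive their seeds from a single root
seed via `numpy.random.SeedSequence`.

## Problem sizes

The default test and acceptance runs use the 20 × 300 system with a
60-sample inference cohort, 1000 permutations for master-regulator calls,
200-replicate calibration loops at 499 permutations, 10,000 wells per dose
for limiting-dilution recovery, and 373-patient survival simulations —
sizes chosen so the full suite and the acceptance script each complete in
minutes on a single CPU while leaving the planted effects comfortably
detectable.
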