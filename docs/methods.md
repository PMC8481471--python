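# Methods

This note documents the models, conventions and design choices behind
`lipidflex`, in the order the analysis runs.

## Annotation grammar and vocabulary

Annotations follow the shorthand `class C:DB;OH`: total carbons, double
bonds and hydroxyls summed over all hydrocarbon moieties. Subspecies
resolve individual chains, joined by `_` (sn-position unresolved) or `/`
(sn-resolved); for ether classes (`PC O-`, `PE O-`, …) the first chain of a
resolved annotation is alkyl. The class registry is closed and holds the 24
classes the platform quantifies (glycerophospholipids with lyso- and ether
variants, CL, DAG/TAG/CE, sterol, Cer/HexCer/SM); unknown tokens are hard
errors rather than pass-through, because a silently accepted typo would be
aggregated as a new class downstream. Sterol (`ST`) carries no numeric
block: totals are zero and it is excluded from all chain-derived features.
The sphingoid long-chain base is treated as a chain like any acyl moiety;
hydroxyl counts live on the base. The formatter emits a canonical form
(single space, `;OH` always present) and `format(parse(s)) == s` holds on
canonical strings; the parser additionally tolerates repeated spaces.

## QC

* **Blank/signal rule** (acquisition level, per batch): a species is kept
  only if its mean study amount strictly exceeds `blank_fold` (default 5)
  times the mean blank amount; failing species are zeroed in that batch's
  study samples. Signal-to-noise is instrument-side information that
  cannot be recomputed from molar amounts, so the S/N > 5 rule is applied
  only when an S/N series is supplied, and logged as skipped otherwise.
* **Occupancy rule** (dataset level, per sample type): a species is kept
  for a sample type iff at least one sex × diet × genotype cell shows
  > `min_amount` (default 1 pmol) in ≥ 2 of its 3 biological replicates.
  Failing (sample type, species) cells are zeroed; species kept nowhere are
  dropped. All thresholds are strict inequalities — boundary values fail.
  Both filters are idempotent and never increase an amount; decisions are
  appended to a tab-separated filter log.
* **Batch correction** is multiplicative: per species, every batch is
  rescaled so its reference-sample median matches the across-batch median
  of those medians. When acquisition order is available, a *global*
  per-batch linear drift in log signal is first fitted on the reference
  samples and divided out. The drift model is deliberately global (one
  slope per batch, estimated from the median log-level of all species):
  per-species lines through a handful of reference points amplify noise
  and can inject order-correlated artefacts into downstream factor
  regressions. Batches with fewer than two references are left untouched
  with a warning.
* **RSD summaries**: per species and replicate group, RSD = 100·sd/mean
  (sd with n−1); the summary is the median over species, reported per
  batch (reference samples; technical repeatability) or per sample type
  (biological triplicate cells). Note that with n = 3 the sd estimate's
  median is ≈ 0.83 σ, so observed median RSDs sit slightly below the
  generating coefficient of variation.

## Feature condensation

After filtering, amounts are renormalised per sample to mol% (so the
100-sum invariant always holds on the analysed species set). Each class is
condensed to abundance (mol%), weighted-mean double bonds and weighted-mean
carbons; weighted means are computed on species-level totals, with
subspecies collapsed and merged first, so the indices are per *total*
hydrocarbon moiety. A class absent from a sample has abundance 0 but
*undefined* (NaN) chain indices — absence is not zero unsaturation.
Fatty-acid profiles weight each chain occurrence by the lipid's amount
(a TAG contributes its amount once per chain) and use only chain-resolved
lipids; species-level-only lipids are excluded since their chain split is
unknown. PCA is centered, unit-variance (n−1 convention) via SVD;
zero-variance or incomplete features are dropped with a warning, loadings
are orthonormal and variance-explained fractions non-increasing. A
storage-lipid-free variant (drop CE/DAG/TAG, renormalise) targets membrane
composition.

## Plasticity

For each (class, sample type) with the class observed in ≥ 2 samples, the
raw range is max−min of each chain index over all samples of that sample
type, all conditions pooled. Ranges are scaled affinely to [1, 10] per
feature type — `1 + 9·(raw − min)/(max − min)` — and multiplied, giving a
score in [1, 100]. The scaling pool is the full set of (class, sample
type) cells per feature type (`scaling_scope="pooled"`); a per-organ pool
is available as a config switch, since the verbal definition ("widest
range across organs") is ambiguous between the two. Adipose tissue is
excluded by default (its storage-dominated composition leaves too few
informative classes); the exclusion list is configurable, as is omission
of the minor lyso-classes from display output. Only the chain indices
enter the score; abundance variation is part of the verbal concept of
plasticity but not of the computed product, so it is deliberately not
mixed in.

## Flexibility and interaction models

Within each sample type, features are z-scored (mean 0, sd 1, n−1) and fit
per feature by OLS on treatment-coded factors — reference levels female,
low-protein, inbred, coded 0 — so β is the covariate-adjusted shift of the
non-reference level in within-organ standard deviations. p-values use the
t distribution with residual df (n − parameters). No multiple-testing
correction is applied by default, matching the raw-p selection thresholds
(p < 0.01 main effects, p < 0.05 interaction terms); Benjamini–Hochberg is
available but off. Flexibility per (organ, factor) is Σ|β| over features
significant for that factor's term; it is monotone in α and zero iff
nothing is selected. Interaction models add one product term
(diet×genotype or diet×sex) and require a full factorial design. Note that
with treatment coding an interaction term is *not* orthogonal to its main
effects, so a main-effects fit on interaction-bearing data absorbs part of
the interaction into the main βs — expected OLS behaviour, relevant when
interpreting the main-effects flexibility map of an interacting system.

Numerical edge case: when a feature is fit exactly (residual variance at
machine-noise level, as in noise-free simulations), the t-ratio of two
rounding errors is meaningless; such terms are resolved exactly (p = 0 for
nonzero β, p = 1 for zero β).

The variance decomposition regresses every species' mol% (pooled over all
organs) on sample type (dummies) + sex + diet + genotype and averages
per-species variance fractions; sequential (incremental R², order as
listed) is the default and agrees with the partial method on balanced
designs, where the blocks are orthogonal.

## Organ–blood correlation and clustering

Samples are paired by animal across organ and blood matrices, spanning
both diets (diet is the varying stimulus; per-diet stratification is a
config option). For each shared lipid, both variables and the covariates
(sex, genotype) are rank-transformed; the ranks of x and y are
residualised on the covariates (with intercept) and the residuals
correlated — the partial Spearman ρ — with p from the t approximation at
df = n − 2 − #covariates. With no informative covariates this reduces
exactly to plain Spearman. Only significant (p < 0.05) *positive*
correlations count as "reflected in blood". For clustering, organs become
vectors over the lipids kept in at least one organ, with non-kept cells
zeroed so all organs share one space, and plasma added as a ρ = 1
self-correlation reference row; complete-linkage hierarchical clustering
on Euclidean distances yields the dendrogram and leaf order.

## Synthetic data generator

The generator emulates the structure of the factorial study: 10 sample
types × 2 diets × 2 sexes × 2 genotypes × 3 replicates = 240 study
samples, the same 24 animals sampled for every organ, four analytical
batches (plasma and adipose separate, remaining organs split in two) each
with 3 reference and 2 blank samples, references interleaved through the
acquisition order.

* **Class profiles.** Each organ has a baseline class-mol% template with a
  coverage gradient of 11–24 classes and ~150–370 species per organ. The
  templates are qualitative organ fingerprints (brain rich in PE O-,
  HexCer and sterol; lung in short, saturated PC and PG; adipose > 90%
  TAG; intestine lyso-rich; blood CE/LPC-rich); they are synthetic
  constructions, not measurements.
* **Species realisation.** A class is four "anchor" species at the corners
  of a ±2-carbon × ±1-double-bond window plus ~12 filler species with
  fixed Dirichlet weights (filler fraction 0.3, identical across organs so
  the lipid vocabulary is shared). Anchor mixing weights are solved per
  sample so the class's weighted-mean carbon and double-bond indices hit
  `template mean + Σ effects·x + N(0, spread)` exactly (filler composition
  compensated); chain-index features are therefore controllable to
  arbitrary precision in the noise-free limit.
* **Noise.** Species amounts get lognormal noise with per-organ σ of
  0.14–0.285 (log scale), chosen so median triplicate RSDs span ≈ 12–26%
  with brain/full blood tightest and kidney/spleen loosest. Reference
  samples use σ = 0.05 (technical only).
* **Effects.** Injected effects are specified in z units and converted to
  raw shifts with the analytically expected realised sd — template spread
  plus the species-noise contribution propagated through the weighted mean
  (κ_db = 0.37 σ, κ_c = 0.74 σ) or, for abundance, the class-total log
  noise (≈ 0.45 σ). Abundance effects act multiplicatively on the class
  total and are restricted to modest-share, uncoupled classes: a log-fold
  shift on a dominant class propagates into every other class's mol%
  through compositional closure, and a coupling latent would inflate the
  feature's variance. The default effect set reproduces the qualitative
  organ pattern (full blood and liver most flexible; brain affected by
  genotype only, on sphingolipids and sterol; lung and adipose nearly
  inert) with per-organ total masses on a well-separated ladder
  (≈ 1…22.5), a power consideration that makes rank recovery identifiable
  against the false-positive noise floor of the p < 0.01 selection.
* **Coupling.** Per-animal latent factors shared between the listed sample
  types multiply a class's total; default strengths (0.15–0.22, near the
  species noise) give per-species organ–blood correlations around 0.5–0.7
  for coupled classes (liver TAG/PC/PI with both blood matrices; CE, LPC,
  SM between plasma and full blood), so the default run shows liver ≈ 10%
  positively correlated lipids versus ≲ 5% elsewhere and < 1–3% in brain.
* **What it does not emulate:** isotope patterns or instrument response,
  litter/cage structure, missing-not-at-random dropout, correlated noise
  across species beyond the class level, or real organ mol% values.
  Passing recovery tests therefore demonstrates correctness of the
  analysis chain under a plausible noise model, not agreement with any
  measured mouse dataset.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use the full 240-sample design;
calibration runs use 10⁴ null features at n = 24, recovery runs 10³
features and 20 simulation replicates (rank recovery is assessed on
replicate-averaged scores, the natural estimate when replicates are
available). One full generation-plus-analysis replicate takes about a
second; the whole acceptance script completes in well under a minute. All
randomness flows from a single seed through `numpy.random.default_rng`;
identical configs give byte-identical datasets.

## Known limitations

* Batch correction assumes the reference material covers the species of
  interest; species absent from references are aligned only by the global
  drift term.
* S/N filtering depends entirely on supplied metadata.
* The flexibility score inherits the arbitrariness of the significance
  cutoff; it is reported together with the number of selected features,
  and the α = 1 limit (sum of all |β|) is available as a smooth
  alternative.
* Partial Spearman p-values use the t approximation, adequate for n ≥ ~10;
  no exact permutation option is provided.
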