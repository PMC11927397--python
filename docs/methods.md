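# Methods

## Profile ingestion and detection filtering

Taxonomic tables are merged MetaPhlAn-style TSVs (clade rows, sample
columns); only terminal species-level (`s__`) rows are kept and clade
prefixes stripped.  Functional tables follow the HUMAnN pathabundance
dialect with community rows and stratified `pathway|taxon` rows.
`UNMAPPED`/`UNINTEGRATED` rows are bookkeeping, not biology: they are
dropped before anything else and community abundances renormalized to
percent of the retained total (stratified rows are rescaled by the same
factor so strata remain commensurate with their parent).  A stratified row
without a community parent synthesizes the parent as the sum of its strata,
with a warning — orphans usually indicate a truncated export, and silently
dropping attribution data would bias the contributions feature downward.

Detection filtering zeroes species cells < 0.1 % abundance and function
cells whose community abundance < 0.01 % or whose pathway coverage < 20 %.
Choices made where the procedure is underdetermined:

* thresholds are **inclusive** — a cell exactly at a threshold survives;
* coverage acts at the pathway level and zeroes the stratified children
  with the parent: per-stratum coverage does not exist, and a child cannot
  be more reliable than its parent;
* **no renormalization after zeroing** — filtering is a detection decision,
  not a compositional transformation, and renormalizing would let one
  filtered cell perturb every feature of the sample;
* missing coverage entries are treated as 1.0 with a warning (absence of
  evidence of poor coverage).

Filtering is therefore idempotent and never increases a cell.

## Reference assets

**Core functions** are pathways whose pooled healthy prevalence strictly
exceeds the threshold (default 0.8, read as "more than 80 %"; the boundary
is excluded).  Prevalence pools all healthy samples weighted by cohort
size; a `require_all_cohorts` switch additionally demands the per-cohort
prevalence to clear the threshold, for stricter cross-cohort universality.

**Healthy pairs** come from per-cohort SparCC correlations on filtered
healthy taxonomic tables.  A pair qualifies iff ρ > 0.1 in *at least one*
healthy cohort and ρ ≥ 0 in *every* healthy cohort in which both species
occur.  The two clauses are deliberately asymmetric: the positive clause
detects the association, the non-negativity clause vetoes pairs with any
evidence of antagonism in health.  Cohorts too small for SparCC (< 8
samples or < 3 species) are skipped with a warning.  With several cohorts
the default candidate set is species present in at least two cohorts; a
`species_subset` hook accepts an externally computed relevance selection
instead.

## SparCC

Implemented from the log-ratio variance estimator: with
t_ij = Var[log(x_i/x_j)], basis variances w_i² solve the linear system
obtained by assuming most pairs uncorrelated, and
ρ_ij = (w_i² + w_j² − t_ij) / (2 w_i w_j), clipped to [−1, 1].  Pairs whose
|ρ| exceeds 0.7 are excluded from the basis system iteratively (up to 10
rounds) and the variances re-solved.  Zeros are replaced by a pseudo-count
of 1e-6 on fractions; the final estimate is the median over 20 draws — the
point estimate plus 19 Dirichlet resamples at an effective depth of 2000
counts, which propagates compositional sampling noise into the estimate.
All parameters are exposed; the defaults follow common SparCC practice.
Species order is canonicalized internally so results do not depend on
column or cohort ordering.

## Features, model and protocols

All six features are presence/absence summaries of filtered profiles;
degenerate samples (no species or no functions) score 0 rather than
erroring, so shallow samples remain scorable.  The denominator of
`Func_contributions_per_species` is the species count of the filtered
*taxonomic* profile — the sample's species census — not the set of taxa in
stratified rows; `unclassified` strata are not species contributions and
are ignored by the numerator.  The GMHI species lists (7 health-prevalent,
43 health-scarce) are bundled as published assets and can be overridden.

The classifier is a random forest of 500 CART trees with √p features per
split and unlimited depth, seeded for determinism (hyperparameters
exposed).  The health score is the forest's predicted probability of the
healthy class.  Protocols:

* **LOOCV** — per-sample scores from forests never shown the sample; each
  fold is seeded from the held-out sample id, so scores are invariant to
  row order (rows are also canonicalized before fitting, as tree bagging
  depends on data order).
* **Leave-one-cohort-out** — per held-out cohort AUC and accuracy; the
  operating threshold for accuracy is Youden's J computed on stratified
  5-fold CV scores of the *training* cohorts only (never the held-out
  data).
* **Threshold calibration** — the final index threshold is the arithmetic
  mean of the per-iteration training thresholds.
* **Youden's J** — maximized over midpoints of consecutive sorted unique
  scores plus sentinels; ties resolve to the smallest maximizing
  candidate.
* **Winning margins** — per-cohort AUC differences of the index against a
  named competitor or the mean of the others, averaged separately over
  cohorts won and lost; exact ties belong to neither set; a Welch t-test
  compares the two margin sets.
* **Permutation importance** — mean held-out-fold AUC drop per permuted
  feature over stratified 5-fold CV, with ranks (1 = most important, ties
  broken by column order so ranks are a permutation of 1..p).

## Shadow-feature relevance (Boruta)

Each round appends a permuted shadow copy of every feature, fits a forest
(50 trees — refitted every round, so lighter than the scoring forest), and
scores a hit when a feature's permutation importance exceeds the round's
maximum shadow importance.  Importance is the AUC drop on a held-out
stratified half of the samples: training-set importance would let memorized
noise masquerade as signal and inflate the null confirmation rate.  After
n rounds, a two-sided binomial test against p = 0.5, Bonferroni-corrected
over the features under test, assigns Confirmed / Rejected; undecided
features stay Tentative.  Constant features are auto-Rejected; fewer than
5 rounds is an error.  Defaults: 100 rounds, α = 0.05 (the test suite and
acceptance script use 30 rounds, which keeps a full error-control study
within minutes at n = 200 while leaving the planted-feature test at
p ≈ 10⁻⁹ before correction).

## Rarefaction and depth sweeps

Rarefaction subsamples count profiles without replacement (multivariate
hypergeometric), reaching the requested taxonomic depth exactly; the
stratified functional pool is rarefied to the proportionally scaled depth.
This operates at the count-profile level — read-level subsampling with
re-annotation is upstream of this package.  Depth sweeps rarefy
**nestedly** (each depth subsamples the previous draw), which makes
per-sample detection monotone along the depth axis, then re-apply the
standard filters, recompute features and score every method.  The summary
reports per-sample score range and standard deviation across depths and
flags threshold crossings of the index score.

## Synthetic cohorts

The generator emulates the structure the method exploits, with defaults
frozen as the package's study conditions:

* 100 healthy / 100 dysbiotic samples per cohort;
* 45 common species: three 10-species **co-abundance modules** (within-
  module log-abundance correlation 0.65, joint presence 0.95 in health),
  5 + 8 species named from the GMHI good/bad lists with class-dependent
  prevalence (good 0.85 → 0.30, bad 0.40 → 0.75), and 2 generic species —
  plus 150 rare species (fractions 1e-6–5e-5) that sit below the detection
  filter but erode under rarefaction;
* log-normal basis abundances (μ spread 0.9, within-species σ 0.8) closed
  to compositions, so SparCC's compositional correction is exercised;
* 80 pathways, 30 of them core with prevalence 0.95 in health vs 0.55 in
  dysbiosis (non-core 0.35 in both);
* dysbiosis additionally disrupts 60 % of modules per sample (co-presence
  broken, abundances decorrelated), scales all presence probabilities by
  0.7 (the richness drop), and halves the stratified-contribution
  intensity (3.0 → 1.5 entries per species);
* integer read counts are multinomial at ~200k depth, with an
  `unclassified` stratum carrying each pathway's unattributed remainder so
  count-derived community abundances equal the analytic ones.

Planted pairs are modules rather than isolated pairs for two reasons: real
healthy co-occurrence networks are modular (butyrate-producer guilds), and
the SparCC null spread at n = 200 (≈ 0.06 s.d.) makes isolated pairs at the
ρ > 0.1 rule unrecoverable at useful precision — the planted:null pair
ratio must be raised, and blocks raise it quadratically.  A
`GeneratorConfig.null()` scenario equalizes every class-specific parameter
(for error-control studies), and `GeneratorConfig.depth_stable()` is a
panel with fewer, more even species (min present fraction ≈ 0.3 %, three
times the species filter) whose detection-based features saturate above
roughly 20k reads, emulating the clearly healthy deep controls a depth
sweep is run on.

What the generator does **not** emulate: phylogenetic structure, strain
variation, compositional overdispersion beyond log-normality,
batch/protocol effects between cohorts (cohort differences are mean-
abundance jitter only), and covariance between taxonomic and functional
profiles of the same organism (pathway presence is sampled independently
of the species that would carry it).  Passing tests therefore demonstrate
correctness of the machinery and recoverability of planted structure, not
clinical performance on real cohorts.

## Problem sizes and numerical choices

The test suite and acceptance script run the method at desk scale, chosen
so every study completes in minutes on one CPU: 20-species/200-sample
SparCC oracles over 20 seeds, 200-sample reference recovery, three
120-sample cohorts for leave-one-cohort-out, 20-seed shadow-feature error
control at 30 rounds, and 6-sample depth sweeps over four depths.
Tolerances in tests reflect binomial/sampling noise at those sizes.

Known limitations: SparCC's sparsity assumption biases module-pair
correlations downward when modules are large relative to the panel;
the GMHI implementation follows the published richness-weighted log-ratio
with an ε = 1e-5 pseudo-count and is not bit-compatible with any specific
plugin; hiPCA-style comparators are not implemented (externally computed
scores can be supplied to the margin analysis); and model files are Python
pickles — load only files you created.
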