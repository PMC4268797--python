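# Methods

## The analysis model

The package targets a multi-cohort screening design: one expression matrix of
miRNA intensities (features × samples), one annotation table assigning each
sample a class label (one control class, many disease classes, and optionally
classes excluded from analysis), and downstream validation assets (a qRT-PCR
CT table, a miRNA–target interaction table, gene sets).

All screening statistics are per-feature two-group contrasts:

- **t-test.** Two-tailed unpaired, Welch (unequal-variance) by default with a
  pooled Student option (`equal_var=True`).  Which variant a given published
  analysis used is often unstated; Welch is the safer default for cohorts with
  very different sizes and variances, and the choice is exposed everywhere.
  Constant-valued groups are detected by exact range (`ptp == 0`), not by a
  variance threshold, because floating-point summation can leave a variance of
  ~1e-31 on a constant vector.  Both groups constant with equal means is a
  degenerate input (scalar API: error; matrix API: t = 0, p = 1, flagged
  `degenerate` so one dead feature cannot abort an 848-feature screen).
- **Multiple testing.** Benjamini–Hochberg step-up, applied *within* each
  comparison across its features — never globally across comparisons — so
  per-disease significance counts are comparable across diseases.  The
  implementation delegates to `statsmodels`' `fdr_bh`; the test suite checks
  it against a literal step-up enumeration.
- **AUC.** The normalized Mann–Whitney statistic with midrank ties.  Two
  orientations are carried: `auc_oriented` = P(case > control) (below 0.5 for
  downregulation) and the discriminative `auc = max(o, 1−o)` matching ROC
  tools that auto-orient the curve — which is why a strongly *down*regulated
  marker is still reported with AUC > 0.5.
- **Bootstrap CI.** Stratified (within-group) resampling with replacement,
  percentile interval, 2,000 replicates, nominal 95%.  The percentile method
  was chosen over normal approximation because the AUC's sampling distribution
  is skewed near the boundaries; empirical coverage at n = 50/50 measures
  ≈ 0.94 over 200 simulations (recomputed by the acceptance script).
- **Fold change.** Ratio of group medians (case/control).  Medians are robust
  to the spike-contaminated features the generator plants, but for exactly
  those features the group *mean* carries the signal, so both are reported.

## Cross-disease machinery

Each eligible disease is contrasted against controls independently (own BH
adjustment).  A feature's profile is (n_down, n_up): in how many diseases it
is significantly down/up.  From the profiles:

- **Balloon table**: count of features per (n_down, n_up) cell, restricted to
  n_down + n_up ≥ 8 by default (≈ 40% of 19 diseases; the threshold is an
  integer parameter).
- **General disease markers**: max(n_up, n_down) ≥ 8 *and* the minority count
  is exactly 0 (`require_consistent`).  The direction-consistency rule encodes
  the empirical observation that cross-disease dysregulation is strongly
  anti-correlated — markers are either up or down in diseases generally,
  rarely both.
- **Stable markers**: one-way fixed-effects ANOVA across all eligible classes
  (controls included), BH across features; `stable` ⇔ adjusted p ≥ α.  ANOVA
  direction is meaningless here; stability is purely non-significance.
- **Pairwise signatures**: all unordered pairs of eligible classes (controls
  count as a class; excluded classes don't), each pair's significant set after
  its own BH.  Uniqueness is exact set comparison.

Excluded classes ("long-lived": age-biased; "others": mixed/unclear
diagnoses) are carried in the annotation as `include_pooled` /
`include_pairwise` flags rather than dropped, so any stage can opt in.
Whether such cohorts belong in the ANOVA is genuinely open; the default
excludes them, with a flag to include.

## Classifier

Stratified k-fold (default 10) cross-validation of an SVM, repeated (default
10×) with re-drawn folds, over growing prefixes of a t-test-ranked feature
list ("stepwise-forward filter selection": the filter statistic is computed
independently of the classifier, and subsets grow by rank prefix; a greedy
wrapper search is out of scope).  Defaults: RBF kernel (linear available —
published descriptions of this procedure name both, which is surfaced here
rather than hidden), cost C = 1, bandwidth γ = 1/(n_features · Var(X))
(scikit-learn's `scale`).

Three design points deserve emphasis:

- **Equal-cohort subsampling**: the larger class is subsampled without
  replacement to the smaller's size once per repetition, before folds are
  drawn, so accuracy is interpretable against a 0.5 chance level.
- **Ranking placement**: by default the ranking is recomputed inside each
  training split (`within_fold`), keeping held-out folds untouched by
  selection.  A `global` mode ranks once on all data; on pure noise it shows
  the classic selection-bias optimism (≈ 0.64 vs ≈ 0.50 accuracy in the test
  suite's fixture) and exists to document that distinction and to mimic
  procedures whose published description is ambiguous.
- **Permutation nulls**: per (subset size, repetition), the identical
  procedure runs on randomly permuted labels (default 10 permutation runs),
  giving a matched null distribution for every metric.

Sensitivity is recall of the case class, specificity recall of the control
class; the per-size ROC pools decision values across held-out folds.  The
best run (maximal AUC, ties broken by first repetition) exports its pooled
per-sample decision values.

## qRT-PCR: 2^−ΔΔCT

ΔCT = CT_target − CT_reference per sample; ΔΔCT = mean ΔCT(case) − mean
ΔCT(control).  (Per-sample-ΔΔCT-then-average and difference-of-group-means
are algebraically identical for means; the latter is implemented.)  Because
higher CT means *less* template, the Livak quantity 2^−ΔΔCT and the sign
printed in validation tables ("negative ΔΔCT, downregulated x-fold") point in
opposite directions.  Rather than assert either sign convention, the module
reports the magnitude 2^|ΔΔCT| plus an explicit `direction` field with
negative ΔΔCT read as downregulation, which reproduces every printed
(ΔΔCT, fold) pair consistently.  The group test is a Welch t-test on the
per-sample ΔCT values (the underlying test of published validations is
typically unnamed); BH across the tested diseases.

## Target network

The interaction table is user-supplied (curated databases churn across
versions and licenses; nothing is bundled).  Edges are deduplicated,
restricted to the query miRNA set and optionally to an evidence tag
(e.g. `reporter_assay`).  Hub targets are genes hit by ≥ k query miRNAs.
Over-representation is an upper-tail hypergeometric test per gene set,
P(overlap ≥ observed), BH across sets; the default universe is every gene in
the interaction table, overridable.  Database-version-dependent counts (how
many interactions a given marker set yields, which pathways surface) are
observations about the supplied tables, not fixed outputs of the method.

## Synthetic cohorts: what they emulate, and what they don't

`default_study_design()` ships the 22-cohort table this package is built
around: 94 controls, 19 disease cohorts (10 cancers, 9 non-cancer; sizes from
13 to 124), 15 long-lived individuals and 149 "others", totalling 1,049
samples — transcribed verbatim from the source cohort table, including
entries that look surprising (Wilms tumor n = 124; lung cancer coded "C24").
`default_signal_spec()` plants, among 848 features:

- **34 general markers** (22 down, 12 up), shifted 1.5σ in the first 14 of 19
  diseases — enough diseases to clear the ≥ 8 calling threshold with slack on
  both sides;
- **10 disease-specific markers** (2σ in one disease each);
- **19 stable markers**: zero shift, noise SD scaled by 0.3;
- **5 near-background features**: mean at background level 5.4, and with
  probability 0.2 a *patient* sample's value is multiplied by 8 — a mixture
  mechanism that reproduces "median near background, mean clearly above it",
  the simplest generator of that heavy-tailed pattern;
- the rest: pure noise at baseline 10, SD 2 (the intensity scale of deposited
  arrays is platform-dependent; the generator's scale is arbitrary and the
  downstream statistics are rank- or ratio-based where scale matters).

Noise is Gaussian, clamped at zero.  Gaussian noise keeps closed-form checks
available: a shift δ against noise σ has true AUC Φ(δ/(σ√2)), which the tests
verify empirically (δ = σ = 2 → 0.760).  The generator does **not** emulate
batch/center effects, array normalization artifacts, correlated features, or
non-Gaussian intensity distributions — so passing tests demonstrate that the
*statistics* behave as specified under their own assumptions, not that any
particular real cohort would yield particular values.  Headline numbers from
real screening cohorts (e.g. a specific marker's AUC, counts of significant
miRNAs) depend on the deposited data and are deliberately not acceptance
targets here.

The qPCR generator plants group-level ΔΔCT effects directly: reference CTs
around 25, control ΔCT of 5 cycles, per-measurement noise SD 0.5 cycles
(typical qPCR technical spread), so estimated ΔΔCT converges to the planted
value at rate σ√(2/n).

**RNG contract**: one root seed; every stage (and every classifier
repetition) derives an independent generator via
`SeedSequence([seed, crc32(label), ...])`, so adding a stage never perturbs
another stage's draws, and equal seeds give bit-identical pipelines (the
manifest records SHA-256 of every output to make this checkable).

## Numerical choices and degenerate inputs

- p-values are clamped to [tiny, 1]; BH inputs must lie in (0, 1].
- Zero-variance features flow through matrix screens as p = 1, AUC 0.5,
  `degenerate = True` instead of raising.
- Ranking ties in `filter_rank`: ascending p, then descending |t|, then
  feature position — fully deterministic and label-encoding invariant.
- Fold change with a zero control median propagates `inf` rather than
  erroring; intensities are nonnegative by construction.
- ORA p-values are exact hypergeometric tail sums (no simulation).

## Problem sizes used in checks

The self-checks and the acceptance script run at deliberately modest sizes
chosen to give stable statistics: 200 simulations × 2,000 bootstrap
replicates at n = 50/50 for CI coverage; 2,000 features for null calibration;
one 848 × 1,049 cohort realization for recovery and bookkeeping checks;
10 permutation runs at subset size 5 on 848 noise features for the classifier
null; 100–500 random instances for each brute-force oracle comparison.
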