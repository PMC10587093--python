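# Methods

This note records the statistical conventions, defaults and design choices
behind `evpanel`, in the order the pipeline runs them.

## Censored panel data

Multiplex immunoassay readouts are left-censored: a biomarker below its
lower limit of detection (LLoD) yields no usable concentration. Missing
values and explicit below-LLoD flags are treated identically — both are
imputed to the biomarker's LLoD — because an immunoassay pipeline cannot
distinguish a failed well from a true non-detection at this layer. The
imputation mask is preserved through all I/O so downstream stages can
reason about reliability. Concentrations are stored untransformed (pg/mL);
the log2 transform is applied by the classifier, which is safe because all
post-imputation values are ≥ LLoD > 0, so no pseudo-count is ever needed.

## Feature filters

* **Reliability**: a biomarker is kept when its imputation fraction is
  ≤ `max_imputed_fraction` (inclusive). Default 0.5; the stricter
  locked-model setting (0.3, with correlation cutoff 0.5) ships as
  `LOCKED_MODEL_FILTERS`.
* **Redundancy**: Pearson *r* is computed on raw post-imputation
  concentrations (imputed cells participate at their LLoD value; no
  exclusion rule is applied). The threshold is interpreted on |r| since
  redundancy is symmetric in sign. Violating pairs are resolved by the
  two-sample Kolmogorov–Smirnov statistic of each member against the binary
  response, with the two-sided asymptotic Kolmogorov p-value; the member
  with the larger p (weaker separation) is dropped. Cliques are handled
  greedily in descending |r|, which matches the pairwise rule and
  terminates deterministically; exact p ties drop the later biomarker in
  schema order. The asymptotic p is adequate at the ≥ 30 samples per class
  this pipeline assumes, and the p-values are used only ordinally, so no
  multiple-testing correction is applied. A constant-valued biomarker has
  undefined r; it is logged and treated as uncorrelated.

Whether the correlation should be computed on raw or log scale is a
genuinely open choice; raw scale is used here, and on log-normal data the
ordering of strong correlations is essentially unchanged (the redundancy
filter only acts above 0.9).

## Cross-validated model selection

The plan is `n_reps` (default 100) repetitions of `n_folds` (default 5)
stratified folds, fixed once from a seed so every candidate sees identical
splits; per-fold class counts deviate from perfect balance by at most one
patient. Within each fold both filters and any scaling transform are fit on
the training portion only and applied frozen to the held-out fold — the
single most important property of the engine, guarded by a test that runs
the whole pipeline on label-permuted data and checks that mean held-out
pAUC is statistically indistinguishable from chance (0.005).

Metrics per held-out fold: pAUC over specificities 90–100 % (unnormalized
trapezoidal area over FPR ∈ [0, 0.1], linear interpolation at the band
edge; a perfect classifier scores 0.10, chance scores 0.005), AUC
(concordance probability, ties ½), and sensitivity at the cutoff reaching
91 % specificity on the fold's training controls. Aggregation is the plain
mean over all folds of all repetitions. McClish normalization of the pAUC
is omitted: candidate ranking is unaffected by the affine rescaling.

The shipped candidate grid registers regularized logistic regression
(C ∈ {0.1, 1, 10} on log2 data) plus small random-forest and
gradient-boosting configurations; SVM is registered with a minimal default
and a neural-network family exists only as a registry stub. The grid is
configuration-driven — the interesting surface is the protocol, not the
hyperparameter search.

**Permutation importance**: per Training–Validation fold pair, each feature
column of the held-out matrix is shuffled 10 times; the feature's score is
the mean loss from the fold baselines in pAUC, AUC and sensitivity,
averaged over all folds. The sensitivity baseline uses the fold-level
91 %-specificity cutoff fit on the training portion.

**RFE**: features are log2-transformed and standardized internally (for
ranking only); at each step the logistic fit drops the feature with the
smallest absolute standardized coefficient until the target panel size
(default 7) remains. With exactly duplicated columns the ridge-penalized
fit splits their weight, so both survive while the pool is large and one is
eliminated once the halved coefficient ranks last — the final panel
contains one member of such a pair whenever the target size forces a
choice. RFE runs once on the full training set after candidate selection
(not inside CV), matching the lock-then-validate protocol.

## Locked classifier

The final model is an unpenalized logistic regression on log2
concentrations. Under perfect separation the unpenalized likelihood
diverges; the fit falls back to a ridge (L2, C=1) penalty and records that
it did. Scores are clipped to the open unit interval at float resolution so
the score contract (0,1) survives saturation. The cutoff is the smallest
observed training-control score whose training specificity reaches the
target (default 0.91); classification is score ≥ cutoff, and the ≥
convention (rather than >) is applied consistently everywhere, including
the cutoff table. Applying a locked model involves no refitting of any
kind.

Sensitivity and specificity (overall and per stage) carry two-sided 95 %
Wilson score intervals using the exact normal quantile; tables round to one
decimal in percent. AUC intervals are percentile bootstrap with 2000
replicates, stratified by class (cases and controls resampled separately
with sizes preserved) so no resample is degenerate; a non-stratified mode
redraws and logs single-class resamples. BCa was considered and rejected —
the percentile interval is the simplest method consistent with a plain
"bootstrap CI" specification.

## Perturbation robustness

Within-patient CV per biomarker = sample sd (n−1 denominator) / mean of a
patient's replicates, averaged unweighted across patients (median also
reported). Note the estimator is biased low for small replicate counts
(E[sd] = c₄(k)·σ; c₄(3) ≈ 0.886), so with the default triplicates a true CV
of 0.10 is recovered as ≈ 0.089; no c₄ correction is applied, keeping the
plain sd/mean convention.

The noise model is multiplicative and mean-preserving: with probability
0.68 a cell's factor is 1+u, u ~ U(−CV, CV); otherwise 1+s·v with s = ±1
equiprobable and v ~ U(CV, 2·CV). The 68/32 split is an independent
Bernoulli per cell ("68 % of the data" read as an expected fraction); an
exact-partition mode is available behind a flag. Values pushed
non-positive (only possible when CV > 0.5 in the outer band) are clamped to
the LLoD and logged; values that merely fall below the LLoD are left as-is
— no re-imputation occurs, since perturbation emulates remeasurement noise,
not re-assay. Labels, stages and the mask are untouched. The study applies
the frozen classifier to `n_sets` (default 100) perturbed copies of
whatever dataset is passed (by default the training data) and reports
mean/min/max of AUC, specificity and overall/stage I/stage II sensitivity,
retaining per-set values for audit.

## Synthetic cohort generator

The generator emulates the data structure this pipeline assumes, at the
study's training scale: 39 stage I + 66 stage II cases vs 545 controls and
52 biomarkers by default. Concentrations are log-normal (positive,
right-skewed, as immunoassay panels are), built as
log₂x = μ + L z + δ·case, where μ is a per-marker baseline drawn once from
a *population* seed (deliberately separate from the sampling seed, so
cohorts drawn with different seeds are matched draws from one population —
exactly what a training/validation pair requires), L induces equicorrelated
marker blocks via shared latent factors, and δ holds the planted case
shifts in log2 units.

Defaults, chosen once as a realistic difficult-but-detectable panel: seven
informative markers with shifts 3.0, 2.5, 2.0, 2.0, 1.5, 1.5, 1.2 on a
marker log2-sd of 1 (single-marker AUCs ≈ 0.80–0.98 by
Φ(shift/(σ√2))); one r = 0.95 non-informative near-duplicate pair
exercising the redundancy filter; one r = 0.6 triple below the filter
threshold; two markers with 60 % of controls censored (removed by the
reliability filter) and mild 5–20 % censoring elsewhere; within-patient CVs
of 0.05–0.15, typical bead-assay precision; triplicate replicates.
Censoring sets each marker's LLoD at the configured quantile of its control
distribution and then applies the same imputation rule as real data, so
mask semantics are identical. Replicate noise is a mean-preserving
log-normal factor whose CV equals the configured value exactly.

What the generator does **not** emulate: the real study's marker
identities, effect sizes, covariance beyond the configured blocks,
batch/plate effects, assay drift, or covariate structure (age, sex,
diabetes, pancreatitis). Passing tests therefore demonstrate that the
machinery is correct and leakage-free under a known truth — not that any
particular real-world panel will reach the performance seen on synthetic
data, which saturates near AUC 1 by design so that selection and locking
behaviour is unambiguous.

## Problem sizes in the shipped analyses

The numbered analysis scripts default to a light cross-validation depth
(10 repetitions; 3 in the README example) because the candidate ranking on
the default synthetic study is already stable there; the full 100×5 design
is a single flag away (`--n-reps 100`). The acceptance script runs the
logistic candidate at 2 repetitions × 5 folds and the full 100-set
perturbation study; all its randomness derives from one `--seed`.

## Known limitations

* The KS p-value is asymptotic; for very small strata (< ~20 per class) the
  exact two-sample p would differ, though the ordinal use within pairs is
  robust.
* The greedy clique resolution is order-dependent only through |r| and KS p;
  exact ties fall back to schema order for reproducibility.
* `threshold_for_specificity` picks an observed score, so the achieved
  specificity can exceed the target when control scores are sparse near the
  quantile; with heavy score ties it can only reach 0 or 1.
* Perturbation leaves the imputation mask frozen, so a perturbed dataset's
  mask describes provenance of the unperturbed values.
* The unpenalized locked fit saturates scores on separable data; the locked
  cutoff can then be numerically tiny. This is cosmetic — calls and
  operating points are unaffected — but real deployments may prefer the
  ridge candidate's calibrated scores.
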