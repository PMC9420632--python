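# Methods

This note documents the statistical procedures implemented in `metabomark`,
the assumptions behind the synthetic-cohort generator, and the numerical and
design choices made where conventions differ between tools.

## Preprocessing

The canonical chain is *censor → 80% rule → impute → (optional normalize) →
log → Pareto*, in that order; provenance records the sequence because the
steps do not commute.

- **Intensity censoring** acts per cell: an observation with absolute
  intensity strictly below `min_intensity` (default 1000 counts) is treated
  as not detected. The comparison is strict — a cell equal to the threshold
  survives.
- **80% rule**: a feature is kept when observed in at least
  `floor(0.8 · n_samples)` samples. Floor is the default convention (for a
  176-sample cohort the threshold is 140); ceil is available for cohorts
  following the stricter reading.
- **Half-minimum imputation** fills each kept feature's missing cells with
  half that feature's minimum observed intensity, pooled across all samples
  regardless of group. This is a deliberate left-censoring surrogate: a
  missing peak was most likely below the detection limit, so the fill sits
  below every observed value.
- **Sample normalization** defaults to *none*. A per-sample median option
  (each sample divided by its median intensity, rescaled to the grand
  median) is provided for dilution correction, but the default pipeline
  leaves dilution to the OPLS-DA orthogonal component instead, keeping raw
  intensities interpretable for fold changes and critical points.
- **Log + Pareto**: with L the log (base 10 by default; natural log
  available) of the imputed table, column j is transformed to
  (L·j − mean)/√sd with the n−1 sd. Each scaled column therefore has
  variance equal to the sd of its log column — Pareto scaling damps
  high-variance features less aggressively than unit-variance scaling.
  Constant columns are set to zero and flagged rather than erroring: they
  carry no information but should not abort a run. The log base is recorded
  in provenance because VIP and p values are invariant to it while critical
  points are not.

Fold changes and ROC critical points are always computed on the **raw
imputed intensities**, never on the scaled matrix.

## Latent-variable models

**Two-class OPLS-DA.** The class response is a single centred ±1 column y.
With w = X′y/‖X′y‖, each orthogonal component is extracted as the part of
the predictive loading orthogonal to w: t = Xw, p = X′t/t′t,
w⊥ = p − (w′p)w (normalized), t⊥ = Xw⊥, p⊥ = X′t⊥/t⊥′t⊥, and X is deflated
by t⊥p⊥′. Two consequences follow from this construction: every orthogonal
score is *exactly* uncorrelated with y, and deflation leaves X′y unchanged,
so w never needs re-estimation. After removing the configured number of
orthogonal components a single predictive component (t, p, c) is fit.
R²X counts predictive plus orthogonal explained sums of squares (all score
vectors are mutually orthogonal, so contributions add); R²Y = c²t′t/y′y.
With zero orthogonal components the model coincides with one-component
PLS-DA (verified against scikit-learn's PLS in the test suite).

**Multi-class PLS-DA.** G ≥ 3 groups are coded as G centred indicator
columns; a NIPALS PLS2 with n_components (default G − 1) fits the
regression, with convergence declared when successive score vectors change
by < 1e−12 relative, or after 500 iterations. No orthogonal filtering is
attempted for multi-class designs; they report a single R²X/R²Y pair.

**VIP.** vip_j = √(p · Σₐ ωₐ w²ⱼₐ / Σₐ ωₐ), with unit-norm weight vectors
and component weights ωₐ equal to the explained response sum of squares.
For OPLS-DA the default basis is the predictive component only — VIP is then
purely discriminatory importance. The `all_components` basis additionally
pools orthogonal weights, weighted by their explained X sum of squares;
since orthogonal components explain no response variance, some weighting of
X-structure is the only non-degenerate way to include them. Under either
basis mean(VIP²) = 1 holds identically, so VIP > 1 marks
above-average contributors.

## Validation

**Q².** Stratified k-fold (default 7 folds, seeded shuffling; an error is
raised when folds exceed the smallest class). Each fold refits the model
with the same component structure on the training rows, predicts the
held-out rows of the centred dummy on the regression scale (no
class-assignment thresholding), and shifts predictions from the training
centring to the full-data centring before accumulating PRESS;
Q² = 1 − PRESS/SSY against the full centred dummy. Q² ≤ R²Y up to numerical
slack, since prediction cannot beat fit.

**Permutation test.** Default 200 rounds. Each round draws a uniform
permutation of the labels (the identity permutation is rejected and
redrawn; requesting more rounds than distinct permutations errors), refits
the model, and records its R²Y, its cross-validated Q², and the mean
absolute column-wise correlation between permuted and original centred
dummies. Least-squares lines of R²Y and Q² versus correlation — anchored by
the unpermuted model at correlation 1 — yield the reported intercepts. A
plot mirroring the conventional permutation display is available.

**Validity checklist.** Four flags, all required: R²X > 0.5 (the model
describes most of the measured variation), R²Y > Q², R²Y − Q² < 0.3 (no
gross overfitting), permutation Q² intercept < 0.05. An invalid model does
not abort the pipeline; reports are produced and prominently flagged.

## Univariate screening and selection

Two-group contrasts use the two-sided Mann–Whitney U test: the exact null
distribution when both n ≤ 8 with no ties, otherwise the normal
approximation with tie and continuity corrections (scipy's implementation
behind this module's surface). Three- and four-group contrasts use Mood's
median test — counts above versus at-or-below the pooled median in a k × 2
table, Pearson chi-square with k − 1 df, ties counted in the "≤ median"
cell. Designs beyond four groups are rejected unless explicitly overridden.

Bonferroni control divides α (default 0.05) by the family size, which
defaults to the number of VIP > 1 features — the subset that enters
testing — rather than the full feature count; both conventions are
available. Fold change defaults to the ratio of group means (medians
optional) of raw intensities; for the mean summary FC(a,b)·FC(b,a) = 1.

Selection ranks candidates passing both VIP > 1 and the corrected p
threshold by descending VIP, then ascending p, then feature id, keeps the
top k (default 4), and annotates each with a ROC record. ROC thresholds sit
at midpoints between consecutive distinct pooled values plus ±∞ sentinels;
AUC uses the rank method (identical to trapezoidal integration, half credit
for ties) and the direction is auto-oriented so AUC ≥ 0.5 — necessary
because strong markers may be either elevated or depleted in cases. Youden
ties are broken toward the finite threshold nearest the midpoint of the two
group medians; ties are rare on continuous data.

## Synthetic cohort generator

The generator emulates the structure this analysis assumes, not any real
cohort: intensity(i,j) = exp(μⱼ + log FC·[spiked] + sᵢ + εᵢⱼ) with

- μⱼ ~ U(2, 14) on the natural-log scale: observed intensities span roughly
  1e3–1e6 counts while the weakest features sit mostly below the detection
  limit, so that with the default limit of 1000 about half of 155 features
  survive the 80% rule — matching the attrition typical of such studies;
- sᵢ ~ N(0, 0.7²), a per-sample dilution offset shared by all features.
  This is the dominant correlated-variation component of plasma profiling
  data, and precisely the kind of class-irrelevant structure OPLS-DA's
  orthogonal component exists to absorb; without it no low-rank model could
  honestly reach R²X > 0.5 on mostly-noise features. Set it to 0 for fully
  independent features;
- εᵢⱼ ~ N(0, 0.5²), per-measurement biological/technical spread;
- spikes multiply the baseline *before* noise, so the expected group-mean
  ratio of a spiked feature equals its configured fold change exactly;
- missingness arises only from left-censoring at the detection limit
  (default 1000), the mechanism that actually produces missing peaks in
  spectra; an optional MCAR rate exists for testing. m/z labels are
  cosmetic uniform draws in [50, 1000] Da.

Default group sizes are 16/32/80/48 (a case group, two comparison disease
groups, healthy controls). The intensity distribution is an assumption —
log-normality is conventional but not established for this data type — so
passing tests demonstrate correctness of the procedures under the stated
generative model, not performance on real cohorts. Real data adds batch and
drift effects, heteroscedastic noise, correlated metabolite blocks and
annotation ambiguity, none of which are simulated.

The reference evaluation study (`metabomark.studies`) fixes a screening
contrast of 16 cases vs 48 controls over 80 post-filter features (baselines
U(8, 14), all above the detection limit), four markers spiked at fold
changes 5.45–8.12, 7-fold Q², 200 permutation rounds, and 50 replicates for
rate estimates — sizes chosen to estimate recovery and rejection rates with
roughly ±5% resolution while keeping a full evaluation under a minute.

## Numerical choices and degenerate inputs

- NIPALS convergence: 1e−12 relative change or 500 iterations.
- Presence thresholds guard against binary-float artefacts
  (0.8 × 15 = 12.000000000000002) by rounding the product to 9 decimals
  before floor/ceil.
- Zero-variance columns: zeroed and flagged in Pareto scaling; an all-equal
  pooled sample is rejected by the median test (degenerate table); a
  feature with no observed values cannot be imputed and errors with its id.
- Orthogonal extraction stops early when nothing orthogonal to w remains
  (rank exhaustion), rather than fabricating null components.
- All stochastic stages (fold assignment, permutations, simulation) consume
  explicit seeds; the pipeline runner splits one root seed per stage by
  hashing, so runs are bit-reproducible and independent stages decoupled.

## Known limitations

- Multi-class designs use plain PLS-DA; no multi-class OPLS variant.
- No batch/drift correction, QC-sample filtering, FDR alternatives to
  Bonferroni, multi-marker panels, or confidence intervals on AUC.
- Q² is computed on the dummy-regression scale; misclassification-style
  cross-validation metrics are not provided.
- The permutation intercept convention (line anchored by the real model at
  correlation 1) is one of several in circulation; with many permutations
  the choice is immaterial, but single-digit-round tests should not rely on
  the intercept.
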