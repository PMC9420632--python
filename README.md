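# metabomark

Biomarker discovery for untargeted plasma metabolomics.

Untargeted (QTOF-MS-style) metabolomics yields a samples × features table of
absolute peak intensities for low-molecular-weight metabolites. Finding the
few metabolites that separate a disease group from controls — candidate
diagnostic biomarkers — requires a chain of well-defined steps, each of which
this package implements as a tested, reusable function:

1. **Preprocessing** — censor peaks with absolute intensity below a detection
   threshold (default 1000 counts), keep only features observed in ≥ 80% of
   samples (the *80% rule*), fill remaining gaps with half the feature's
   minimum observed intensity, then log-transform and **Pareto-scale**
   (centre each log column and divide by √sd).
2. **Multivariate modelling** — two-class **OPLS-DA** (orthogonal projections
   to latent structures discriminant analysis), which splits X into one
   class-predictive component and components uncorrelated with class (e.g. a
   per-sample dilution factor); multi-class designs use PLS-DA. Model fit is
   summarized by R²X and R²Y (explained sums of squares of X and of the
   centred class dummy Y).
3. **Validation** — stratified 7-fold cross-validation gives
   Q² = 1 − PRESS/SSY; a 200-round label-permutation test regresses permuted
   R²Y/Q² on label correlation. A model is accepted only if R²X > 0.5,
   R²Y > Q², R²Y − Q² < 0.3 and the permutation Q² intercept < 0.05.
4. **Screening** — per-metabolite **VIP** (variable importance in
   projection, mean VIP² = 1; VIP > 1 flags influential metabolites),
   two-sided **Mann–Whitney U** tests (Mood's median test for 3–4 groups)
   with a **Bonferroni**-corrected p threshold, and raw-intensity **fold
   changes**.
5. **Selection** — candidates passing both VIP > 1 and the corrected p cut
   are ranked and annotated with a single-metabolite **ROC** analysis:
   rank-method AUC (= U/(n₁n₂)) and the "critical point", the intensity
   threshold maximizing the Youden index J = sensitivity + specificity − 1.

Because public cohort data for this design is typically unavailable, the
package ships a first-class synthetic-cohort generator
(`metabomark.simulate`) that reproduces the assumed statistical structure —
four groups of 16/32/80/48 samples, ~155 log-normal features spanning
1e3–1e6 counts, a shared per-sample dilution factor, spiked fold changes,
and missingness by left-censoring at the detection limit — so every stage is
testable end to end.

## Worked example

A screening-style comparison — 16 cases vs 48 healthy controls, 80
metabolites, three spiked markers (two elevated at fold change 8.12 and
6.03, one depleted at 0.25):

```python
from metabomark import (
    SimulationConfig, simulate_feature_table, run_preprocess,
    ModelSpec, cross_validate_q2, permutation_test, check_validity,
    compute_vip, univariate_screen, build_report,
)

cfg = SimulationConfig(
    group_sizes={"PMC": 16, "HPG": 48},
    n_features=80,
    log_mean_range=(8, 14),
    spike_plan=[(0, "PMC", 8.12), (1, "PMC", 6.03), (2, "PMC", 0.25)],
    seed=42,
)
table = simulate_feature_table(cfg)
imputed, scaled, prep = run_preprocess(table)
print(f"kept {prep.n_features_kept}/{prep.n_features_in} features, "
      f"imputed {prep.n_cells_imputed} cells")

groups = table.groups.to_numpy()
spec = ModelSpec("oplsda", n_orthogonal=1)
model = spec.fit(scaled, groups)
cv = cross_validate_q2(scaled, groups, spec, n_folds=7, seed=1)
perm = permutation_test(scaled, groups, spec, n_permutations=200, seed=2)
validity = check_validity(model, cv, perm)
print(f"R2X={model.r2x:.3f}  R2Y={model.r2y:.3f}  Q2={cv.q2:.3f}  "
      f"Q2 intercept={perm.intercept_q2:.3f}  valid={validity.valid}")

vip = compute_vip(model)
records = univariate_screen(imputed, vip, case_label="PMC")
report = build_report(imputed, records, top_k=3, case_label="PMC")
print(report.to_frame().round(3).to_string(index=False))
```

Output:

```
kept 80/80 features, imputed 21 cells
R2X=0.654  R2Y=0.889  Q2=0.791  Q2 intercept=-0.371  valid=True
Metabolites  Fold change   VIP  p Value  AUC of ROC  Critical point  Sensitivity  Specificity  Youden index
      F0001        6.616 4.984      0.0       0.956      797823.231        0.938        0.875         0.812
      F0002        6.285 4.718      0.0       0.926      162212.621        0.750        0.938         0.688
      F0003        0.198 4.148      0.0       0.893      232586.936        0.812        0.896         0.708
```

Reading the table: all three spiked metabolites are recovered with VIP ≫ 1
and Bonferroni-significant p values; empirical fold changes (6.6, 6.3, 0.20)
track the configured spikes; each marker alone discriminates cases from
controls with AUC ≈ 0.9, and the critical point is the raw-intensity cut
that maximizes J. The model itself passes the four-flag validity checklist
(R²X > 0.5, R²Y > Q², small gap, negative permutation Q² intercept).

The same workflow is scriptable from the shell:

```bash
metabomark simulate --seed 3 --group PMC:16 --group HPG:48 --spike 0:PMC:8.12 \
    --out-data data.csv --out-metadata meta.csv
metabomark compare --config pipeline.yaml
```

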