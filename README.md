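# gutclock

Aging clocks from gut-microbiome metagenomes. `gutclock` builds an age
regression model from two compositional "views" of the same stool samples —
a species-level taxonomic profile and a metabolic-pathway profile — and
identifies the features that drive the prediction. It is aimed at
microbiome researchers who want a confounder-aware, multi-view aging clock
pipeline that can be validated end to end on synthetic cohorts before being
pointed at real curated metagenome collections.

## What it does

1. **Confounder screening.** Host and technical covariates are quantified
   against Bray–Curtis community dissimilarity with sequential
   (`adonis`-style) PERMANOVA, `d ~ covariate + platform + extraction kit`,
   with free permutation of sample labels. Because pooled cohorts enrich
   particular geographies in particular age ranges, countries are regrouped
   to UN M49 subregions and subregions are then removed iteratively — most
   age-informative first, ranked by random-forest feature importance on the
   one-hot subregion design — until geography no longer predicts age
   (cross-validated R² < 0.01).
2. **Compositional preprocessing.** Zeros are multiplicatively replaced
   (zeros → δ, nonzero parts rescaled so each row still sums to 1) and each
   profile is mapped by the centered log-ratio transform,
   `clr(x)_i = ln x_i − (1/D) Σ_j ln x_j`. One-hot covariates are appended
   after the CLR step; they are not compositional parts.
3. **Base-regressor bench.** Twelve heterogeneous regressors (LR, Lasso,
   EN, BR, SVM, LSVM, DT, RF, GBRT, XGB, XGBRF, LGB) are compared under
   repeated cross-validation (10×5 by default) on R² and MAE, with paired
   Wilcoxon signed-rank tests and Bonferroni correction.
4. **Feature selection.** Univariate F-tests, mutual information, and five
   model-importance selectors are adjudicated by: fewest significantly
   degraded regressors → most improved → smallest retained dimension.
5. **Two-stage stacking with multi-view fusion.** Stage 1 fits each base
   learner k-fold out-of-fold (OOF), producing a "predicted training set"
   in which no sample was seen by the model that predicted it; stage 2 fits
   a generalizer (ordinary linear regression by default) on the OOF
   columns. Views are fused either by concatenating designs before
   stacking (EM1) or by stacking each view independently and fusing OOF
   predictions in stage 2 (EM2); EM2 only needs the sample intersection at
   the generalizer, so partially overlapping views are used in full.
6. **Biomarker discovery.** Each feature of the frozen model is shuffled 50
   times on held-out samples; the drop in R² is its permutation feature
   importance. Significant features (paired Wilcoxon vs the intact
   baseline, Bonferroni across both views jointly, positive mean drop) are
   ranked and annotated with Spearman's ρ against age.

A first-class synthetic-cohort generator produces two-view compositional
cohorts with adult age distributions (18–107 years, median ≈ 52),
calibrated subregion–age confounding, and planted monotone biomarkers with
known signs, so every stage above is testable without external data.

## Worked example

```python
import pandas as pd
from gutclock import (
    SyntheticConfig, generate_cohort, multiplicative_replacement, clr_transform,
    screen_subregions, multiview_stack, predict_ensemble, score_predictions,
    interpret_model, biomarker_table, CvScheme, LearnerSpec,
)

cohort = generate_cohort(SyntheticConfig(
    n_samples=400, n_species=60, n_pathways=40, n_signal_features_per_view=8,
    confound_strength=0.10, confounded_subregions=("CE", "WE"),
    signal_effect=0.04, seed=7,
))

screen = screen_subregions(cohort.metadata, min_bin_size=30, threshold=0.01,
                           cv=CvScheme(10, 5, 7), seed=7)
print(f"removed subregions: {[e[0] for e in screen.epochs]}")
print(f"retained subregions: {screen.retained_subregions} "
      f"(geography->age R2 = {screen.final_assoc_r2:.3f})")

keep = screen.retained_sample_ids
clr = lambda v: clr_transform(multiplicative_replacement(v.subset_samples(keep))).frame
designs = {"species": clr(cohort.species_view), "pathway": clr(cohort.pathway_view)}
y = pd.Series(cohort.ages, index=cohort.metadata.sample_ids).loc[keep]

train, test = y.index[:220], y.index[220:]
model = multiview_stack({k: d.loc[train] for k, d in designs.items()}, y.loc[train],
                        generalizer="LR", strategy="EM2", seed=7,
                        specs=[LearnerSpec(n) for n in ("Lasso", "GBRT", "LGB")])
pred = predict_ensemble(model, {k: d.loc[test] for k, d in designs.items()})
r2, mae = score_predictions(y.loc[test], pred)
print(f"held-out R2 = {r2:.3f}, MAE = {mae:.2f} years")

records = interpret_model(model, {k: d.loc[test] for k, d in designs.items()},
                          y.loc[test], n_shuffles=50, seed=7)
print(biomarker_table([r for r in records if r.significant]).head(5).to_string(index=False))
```

Output:

```
removed subregions: ['WE']
retained subregions: ['CE', 'EA', 'NA', 'NE', 'SE'] (geography->age R2 = -0.029)
held-out R2 = 0.842, MAE = 5.16 years
feature_id    view  mean_delta_r2   p_adjusted  significant  rank  spearman_rho  spearman_p_adjusted
   pw_0021 pathway       0.040193 7.556929e-08         True     1      0.588696         5.066436e-08
   pw_0024 pathway       0.030745 7.556929e-08         True     2     -0.548366         1.035036e-06
   pw_0012 pathway       0.027268 7.556929e-08         True     3     -0.628737         1.633167e-09
   sp_0055 species       0.025573 7.556929e-08         True     4      0.593037         3.571042e-08
   sp_0059 species       0.023582 7.556929e-08         True     5     -0.674447         1.678208e-11
```

The screen removed the one heavily age-enriched subregion that exceeded the
decoupling threshold, after which geography carries no age information
(R² ≈ −0.03). The two-view stack predicts held-out age to within ~5.2
years on this cohort, and the top permutation-importance biomarkers are
planted features whose Spearman trends match the signs they were planted
with (negative ρ for decreasing features, positive for increasing ones).

There is also a CLI for running the stages from the shell — see
`gutclock --help` (`simulate`, `screen`, `bench`, `select`, `train`,
`interpret`, `run-all`).

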