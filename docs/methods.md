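# Methods

This note documents the statistical machinery implemented in `gutclock`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical details that matter for
reproducing results.

## Synthetic cohorts

`gutclock.synthetic.generate_cohort` emulates a pooled, multi-cohort stool
metagenome resource as a single population:

* **Ages** are drawn from a Beta(2, b) distribution scaled to the
  configured range (default 18–107 years), with b solved from the median
  approximation so the sample median lands near the target (default 52
  years — the demography of large public adult stool collections).
* **Abundances.** Feature j of sample i has log-abundance
  `mu_j + s_j·g_j(age_i) + delta_{r(i),j} + eps_ij` with per-feature
  baselines `mu_j ~ N(0, 2)` (heavy-tailed profiles after exponentiation),
  noise `eps ~ N(0, noise_dispersion)` (default 1.0), and optional
  subregion shifts `delta ~ N(0, 0.5)` on 20% of features (geography
  structure in the community, independent of age). Rows are exponentiated
  and closed to sum 1; entries below the sparsity floor (default 1e-5
  relative abundance) are zeroed first and the row re-closed, so the
  zero-replacement path is always exercised.
* **Planted signal.** `n_signal_features_per_view` features per view get a
  monotone age trend `g_j`: a linear ramp of `signal_effect` log-units per
  year (default 0.01 — about a 2.4-fold abundance change across the adult
  range), or, for a configurable fraction, a monotone step at a random age
  cut. Signs alternate and are recorded in the cohort's truth table. An
  optional per-view age window makes a view informative only over part of
  the age range, which is how complementary two-view cohorts are built.
* **Confounding.** Subregion labels are drawn from an age-dependent
  categorical distribution: with mixture probability m a sample is
  assigned the subregion owning its age-quantile band, otherwise it is
  drawn from the nominal sampling weights. m is calibrated by bisection
  on the cohort's own age and assignment draws (common random numbers), so
  the age variance explained by subregion (eta-squared) hits
  `confound_strength` without pre-run realization noise; an unreachable
  target raises.
  `confounded_subregions` restricts the banding to a subset of regions,
  reproducing the realistic pattern of specific cohorts enriching specific
  age ranges.

What the generator does **not** emulate: taxon co-occurrence and
phylogenetic structure, per-cohort batch effects beyond the subregion
shifts, non-monotone age trends, and the long tail of extremely rare taxa.
Tests passing on these cohorts therefore demonstrate the correctness and
calibration of the machinery, not performance on real metagenomes.

## Compositional preprocessing

Zeros are replaced multiplicatively (via scikit-bio): zeros become delta
and nonzero entries are scaled by `1 − z·delta` (z = zeros in the row), so
closure is preserved exactly. The default delta is `1/D²` capped at half
the smallest observed positive entry — small enough never to dominate a
real part; it is configurable because results can be mildly sensitive to
it. The centered log-ratio transform then maps each row to
`ln x − mean(ln x)`; outputs are re-centered to make row sums zero at
1e-10 rather than relying on the library's 1e-15-level residuals.
Indicator covariates (one-hot subregion) are appended after the CLR —
indicators are not parts of a composition and must not enter the log-ratio
geometry.

## PERMANOVA

`adonis_permanova` partitions the Gower-centered matrix of squared
Bray-Curtis distances sequentially (Type-I) over an ordered term list, the
semantics of `vegan::adonis2(..., by="terms")`. Categorical terms enter as
centered dummy blocks, continuous terms (age, BMI) as centered single
columns; each term's incremental orthonormal basis is obtained by QR with
a rank tolerance of `1e-8 · max|R|`. Pseudo-F uses the residual mean
square; p-values come from free permutation of sample labels (default
9999), computed by permuting the basis vectors and evaluating quadratic
forms in BLAS-sized chunks. Permutations whose statistic ties the
observed one within `1e-8 · max(1, |F|)` count as exceedances — label
permutations that merely rename groups reproduce F exactly, and dropping
such ties to floating-point noise makes the test anticonservative.
Correctness is cross-checked in the test suite against exhaustive
enumeration on 6 samples, against scikit-bio's one-way PERMANOVA, and
against `vegan::adonis2` on a multi-term formula.

Covariate effects are assessed one formula per covariate
(`d ~ covariate + platform + extraction_kit`), Bonferroni-corrected across
covariates. The formula order is the default; a confounders-first order
is available via `confounders_first=True` since effect sizes "adjusted
for" technical factors can also be read that way. Samples missing a term
are dropped listwise for that formula.

## Geography/age decoupling

Countries are regrouped to UN M49 subregions (mapping shipped as TSV).
Bins with at most `min_bin_size` samples (default 200) are dropped for
statistical power. The screen then loops: a random forest predicts age
from the one-hot subregion design under repeated 10×5 CV; if mean R² is
below the threshold (default 0.01) or one bin remains it stops, otherwise
the subregion with the largest summed impurity importance (importances
summed over a subregion's indicator columns, since the removal unit is
the subregion) is removed with its samples. Retained sets are nested by
construction and every epoch is recorded.

## Regressor bench and paired testing

The registry holds twelve regressors under each library's documented
defaults; no hyperparameter tuning is performed anywhere, so all
comparisons are of default-configured learners. Repeated k-fold CV
(default 10 repeats × 5 folds) derives the fold partition of repeat r from
`base_seed + r`; all learners share the partitions, making per-split
pairing valid. Held-out R² uses the fold's own mean for the total sum of
squares. Model comparisons use the Wilcoxon signed-rank test on paired
per-split differences (the paired analogue of the rank-sum test), with
zero differences discarded, the exact null for up to 25 tie-free pairs and
the normal approximation otherwise, and Bonferroni correction across
whatever family of comparisons is being run.

## Feature selection

FR ranks by univariate linear F statistic, MI by mutual information
(constant features are forced to score zero), and the five model-based
selectors by fitted importances. The default keep rule retains features
scoring above the mean score — the conventional `SelectFromModel`
threshold — with `top_k` and `positive` rules available. Each selector is
scored by refitting every bench regressor on the reduced design under the
shared CV scheme; a regressor is "degraded"/"improved" only when the
Bonferroni-adjusted paired p is below 0.05. The adjudicator orders
selectors by fewest degraded, then most improved, then smallest retained
dimension, then name (a deterministic total order). When selection is
embedded in a downstream evaluation it is fit on training folds only;
fitting selection on all samples would leak label information into the
evaluation.

## Stacking and multi-view fusion

Stage 1 splits the training set into k=5 shuffled folds shared by all nine
base learners (Lasso, EN, BR, SVM, RF, GBRT, XGB, XGBRF, LGB); each
learner's held-out predictions form its OOF column, and its k fold models'
mean prediction is used for new samples. Stage 2 fits the generalizer on
the OOF columns; SA (simple average) is the no-fit baseline, and a
decision-tree generalizer is allowed but warns, because a tree fitted on
OOF columns overfits badly. EM1 concatenates view designs before
stacking; EM2 stacks each view on all of its own labelled samples and
fits the generalizer on the concatenated OOF columns over the sample
intersection, which is why EM2 tolerates partially overlapping views.

All reported stacking performance comes from `outer_cv_evaluate`, which
re-runs the entire procedure (stage-1 folds included) inside each outer
training set — the only nesting that keeps the outer score leakage-free.
Stage-1 OOF matrices are computed once per view per outer split and shared
across generalizers and view subsets, so ensemble-vs-single,
single-vs-multi-view and generalizer comparisons are paired on identical
splits. Stage-1 split seeds derive from the outer seed, repeat and fold
indices.

## Permutation feature importance

PFI operates on the model's input representation (post-CLR,
post-selection columns), so a frozen model can be interrogated without
re-running the transform stack; one-hot covariate columns are excluded by
default (they are covariates, not biomarkers). Each candidate column is
shuffled 50 times across the evaluation samples — held out from
generalizer training to avoid optimistic deltas — and the drop in R² is
recorded per shuffle; all shuffles of a feature are scored in one batched
prediction pass per frozen model. Per-feature shuffle streams are keyed
by (seed, view, feature id), so results are independent of traversal
order. Significance is a paired Wilcoxon of permuted scores against the
intact baseline, Bonferroni across all tested features of both views
jointly (the stricter reading); features whose shuffling helps are never
significant. Constant columns yield deltas of exactly zero.

One property of PFI worth stating plainly: the null hypothesis is
"shuffling this column does not change the model's performance", so the
significant set contains every feature the frozen model measurably relies
on — including features with no marginal age association that a flexible
learner partly overfit, and features that acquire weak age signal through
the CLR's shared log-geometric-mean term. On synthetic cohorts the
planted features separate cleanly by magnitude (they occupy the top ranks
in every recovery run), but family-wise error control over the PFI tests
is not a guarantee that every significant feature is a planted one. Rank
and effect size, not bare significance, are the biomarker evidence.

## Study conditions of the packaged experiments

`gutclock.experiments` pre-registers the simulation settings used by the
test suite and `scripts/acceptance.py`:

* decoupling: n=1500, six subregions, age enrichment (target R²=0.10,
  about the country-level association seen in pooled cohorts) planted in
  two regions; screen at threshold 0.01 under 10×5 CV; the final
  association re-measured with a fresh 10×5 scheme and independent seed.
* PERMANOVA calibration: 500 null datasets of 24 compositions, two-level
  label, 199 permutations each, alpha 0.05.
* stacking: n=800, 40 species + 30 pathway features, 12 planted features
  per view with disjoint age windows (below vs above the median) and half
  step-shaped trends; outer 2×5 CV; all seven generalizers and all nine
  single learners scored on the shared splits.
* PFI recovery: 20 runs of n=400 cohorts (40+25 features, 4 planted per
  view, slope 0.05/year), compact Lasso/GBRT/LGB stacks trained on 70%
  and interpreted on the held-out 30% with 50 shuffles.
* Spearman trends: n=500, 120+80 features, 10 planted per view at slope
  0.02/year, Bonferroni across the 20 planted features.

These sizes keep the full suite within tens of minutes on one CPU while
leaving each comparison enough resolution; enlarging them tightens the
estimates but does not change any qualitative outcome.

## Known limitations

* Real-data performance claims are out of scope: the package validates
  machinery on synthetic cohorts; numbers on curated metagenome
  collections depend on cohort curation choices it does not make.
* PERMANOVA permutations are free; blocked/strata designs (e.g. permuting
  within cohorts) are not implemented.
* The stacking implementation supports n views in principle but is tested
  with two.
* Learner hyperparameters are library defaults throughout; a tuned bench
  would shift absolute scores, though the paired-comparison machinery
  would apply unchanged.
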