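"""Heterogeneous regressor registry and the repeated cross-validation harness.

Twelve base regressors are supported: ordinary least squares (LR), Lasso,
Elastic Net (EN), Bayesian Ridge (BR), support-vector regression with RBF
(SVM) and linear (LSVM) kernels, a decision tree (DT), random forest (RF),
gradient-boosted trees (GBRT), XGBoost in boosting (XGB) and random-forest
(XGBRF) modes, and LightGBM (LGB).  Hyperparameters are each library's
documented defaults; a :class:`LearnerSpec` may override any of them and the
effective parameters are serializable for run manifests.

Model comparison uses repeated k-fold cross-validation (default 10 repeats
of 5 folds) with R^2 and mean absolute error per held-out fold, and a paired
Wilcoxon signed-rank test across the shared splits with Bonferroni
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import (
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import BayesianRidge, ElasticNet, Lasso, LinearRegression
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.model_selection import KFold
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

import lightgbm as lgb
import xgboost as xgb

__all__ = [
    "LEARNER_REGISTRY",
    "LearnerSpec",
    "CvScheme",
    "CvScores",
    "make_learner",
    "score_predictions",
    "repeated_cv",
    "run_bench",
    "paired_test",
    "wilcoxon_signed_rank",
]


def _lr(seed, params):
    return LinearRegression(**params)


def _lasso(seed, params):
    return Lasso(random_state=seed, **params)


def _en(seed, params):
    return ElasticNet(random_state=seed, **params)


def _br(seed, params):
    return BayesianRidge(**params)


def _svm(seed, params):
    return SVR(**params)


def _lsvm(seed, params):
    return SVR(kernel="linear", **params)


def _dt(seed, params):
    return DecisionTreeRegressor(random_state=seed, **params)


def _rf(seed, params):
    return RandomForestRegressor(random_state=seed, **params)


def _gbrt(seed, params):
    return GradientBoostingRegressor(random_state=seed, **params)


def _xgb(seed, params):
    return xgb.XGBRegressor(random_state=seed, verbosity=0, **params)


def _xgbrf(seed, params):
    return xgb.XGBRFRegressor(random_state=seed, verbosity=0, **params)


class _QuietLGBM(lgb.LGBMRegressor):
    """LGBMRegressor without the spurious feature-name warning.

    lightgbm registers synthetic ``Column_i`` feature names even when fit on
    a plain ndarray, so every subsequent ndarray predict would emit a
    sklearn feature-name mismatch warning despite nothing being wrong.
    """

    def predict(self, X, **kwargs):
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.filterwarnings(
                "ignore", message="X does not have valid feature names"
            )
            return super().predict(X, **kwargs)


def _lgb(seed, params):
    return _QuietLGBM(random_state=seed, verbose=-1, **params)


LEARNER_REGISTRY = {
    "LR": _lr,
    "Lasso": _lasso,
    "EN": _en,
    "BR": _br,
    "SVM": _svm,
    "LSVM": _lsvm,
    "DT": _dt,
    "RF": _rf,
    "GBRT": _gbrt,
    "XGB": _xgb,
    "XGBRF": _xgbrf,
    "LGB": _lgb,
}

#: the nine pre-verified stage-1 learners used in the stacking ensemble
STACK_BASE_LEARNERS = ("Lasso", "EN", "BR", "SVM", "RF", "GBRT", "XGB", "XGBRF", "LGB")


@dataclass(frozen=True)
class LearnerSpec:
    """A named regressor with optional hyperparameter overrides."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in LEARNER_REGISTRY:
            raise ValueError(
                f"unknown learner {self.name!r}; registry: "
                f"{sorted(LEARNER_REGISTRY)}"
            )

    def with_seed(self, seed: int) -> "LearnerSpec":
        return LearnerSpec(self.name, dict(self.hyperparameters), seed)


def make_learner(spec: LearnerSpec):
    """Instantiate a fit/predict estimator for ``spec``.

    Stochastic learners are seeded from ``spec.seed`` so repeated
    construction is deterministic.
    """
    return LEARNER_REGISTRY[spec.name](spec.seed, dict(spec.hyperparameters))


@dataclass(frozen=True)
class CvScheme:
    """Repeated k-fold scheme: fold partitions for repeat ``r`` are drawn
    with seed ``base_seed + r`` so score lists are reproducible and pairable
    across learners."""

    n_repeats: int = 10
    n_folds: int = 5
    base_seed: int = 0

    def splits(self, n_samples: int):
        """Yield (repeat, fold, train_idx, test_idx) over all splits."""
        if self.n_folds > n_samples:
            raise ValueError(
                f"n_folds={self.n_folds} exceeds n_samples={n_samples}"
            )
        for r in range(self.n_repeats):
            kf = KFold(
                n_splits=self.n_folds, shuffle=True, random_state=self.base_seed + r
            )
            for f, (tr, te) in enumerate(kf.split(np.arange(n_samples))):
                yield r, f, tr, te

    @property
    def n_splits(self) -> int:
        return self.n_repeats * self.n_folds


@dataclass
class CvScores:
    """Per-split R^2 and MAE lists from a repeated-CV run."""

    r2: list
    mae: list
    scheme: CvScheme
    learner: str = ""

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.r2))

    @property
    def mean_mae(self) -> float:
        return float(np.mean(self.mae))


def score_predictions(y_true, y_pred) -> tuple[float, float]:
    """(R^2, MAE) of predicted versus true ages.

    R^2 uses the evaluation set's own mean for the total sum of squares.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D and of equal length")
    if y_true.size < 2:
        raise ValueError("need at least two observations")
    if np.ptp(y_true) == 0:
        raise ValueError("R^2 undefined: y_true is constant")
    return float(r2_score(y_true, y_pred)), float(mean_absolute_error(y_true, y_pred))


def _as_array(X) -> np.ndarray:
    if hasattr(X, "values") and not isinstance(X, np.ndarray):
        return np.asarray(X.values, dtype=float)
    return np.asarray(X, dtype=float)


def repeated_cv(spec: LearnerSpec, X, y, scheme: CvScheme | None = None) -> CvScores:
    """Score ``spec`` under repeated k-fold CV, returning all split scores.

    A fresh estimator is fit per split on the k-1 training folds and scored
    on the held-out fold.  Identical ``scheme`` (and spec seed) gives
    identical score lists, which makes paired tests across learners valid.
    """
    scheme = scheme or CvScheme()
    X = _as_array(X)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("X and y are not aligned")
    r2s, maes = [], []
    for r, f, tr, te in scheme.splits(X.shape[0]):
        model = make_learner(spec.with_seed(spec.seed + r))
        model.fit(X[tr], y[tr])
        r2, mae = score_predictions(y[te], model.predict(X[te]))
        r2s.append(r2)
        maes.append(mae)
    return CvScores(r2=r2s, mae=maes, scheme=scheme, learner=spec.name)


def run_bench(
    specs: list, X, y, scheme: CvScheme | None = None
) -> pd.DataFrame:
    """Benchmark several learners under one shared CV scheme.

    Returns a long-format table (learner, repeat, fold, r2, mae).
    """
    scheme = scheme or CvScheme()
    rows = []
    for spec in specs:
        scores = repeated_cv(spec, X, y, scheme)
        for i, (r2, mae) in enumerate(zip(scores.r2, scores.mae)):
            rows.append(
                {
                    "learner": spec.name,
                    "repeat": i // scheme.n_folds,
                    "fold": i % scheme.n_folds,
                    "r2": r2,
                    "mae": mae,
                }
            )
    return pd.DataFrame(rows)


def wilcoxon_signed_rank(diffs: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired differences.

    Zero differences are discarded; the exact null distribution is used for
    up to 25 effective (tie-free) pairs, the normal approximation otherwise.
    Returns 1.0 when every difference is zero.
    """
    diffs = np.asarray(diffs, dtype=float)
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return 1.0
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        nz, zero_method="wilcox", alternative="two-sided", method=method
    )
    return float(res.pvalue)


def paired_test(
    scores_a: CvScores, scores_b: CvScores, n_comparisons: int = 1
) -> float:
    """Bonferroni-adjusted paired Wilcoxon signed-rank p between two score
    lists obtained under the same CV splits.

    The comparison language in ensemble benchmarking is often "paired
    Wilcoxon rank-sum"; since rank-sum is an unpaired test, the paired
    signed-rank test on per-split differences is what is computed here.
    """
    if scores_a.scheme != scores_b.scheme:
        raise ValueError("score lists come from different CV schemes; pairing invalid")
    a, b = np.asarray(scores_a.r2), np.asarray(scores_b.r2)
    if a.shape != b.shape:
        raise ValueError("score lists have different lengths")
    p = wilcoxon_signed_rank(a - b)
    return min(1.0, p * max(1, n_comparisons))
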