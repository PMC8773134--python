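"""Feature selection methods and the adjudication rule for choosing one.

Seven selectors are compared: univariate linear F-tests (FR), mutual
information (MI), and importance-based selection from five fitted tree
models (RF, GBRT, XGB, XGBRF, LGB).  Each selector is scored by how every
base regressor's repeated-CV performance changes on the reduced design,
with a Bonferroni-corrected paired Wilcoxon verdict per regressor
(degraded / unchanged / improved).  The adjudicator then prefers, in order:
fewest degraded regressors, most improved regressors, smallest retained
dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_regression, mutual_info_regression

from .bench import CvScheme, LearnerSpec, make_learner, paired_test, repeated_cv

__all__ = [
    "SELECTION_METHODS",
    "SelectionOutcome",
    "select_features",
    "evaluate_selection",
    "adjudicate",
]

SELECTION_METHODS = ("FR", "MI", "RF", "GBRT", "XGB", "XGBRF", "LGB")
_MODEL_BASED = ("RF", "GBRT", "XGB", "XGBRF", "LGB")


@dataclass
class SelectionOutcome:
    """One selector's retained features and per-regressor performance deltas."""

    method: str
    selected_feature_ids: list
    n_features: int
    deltas: pd.DataFrame = field(default_factory=pd.DataFrame)
    # deltas columns: learner, r2_before, r2_after, p_adjusted, verdict

    @property
    def n_degraded(self) -> int:
        return int((self.deltas["verdict"] == "degraded").sum()) if len(self.deltas) else 0

    @property
    def n_improved(self) -> int:
        return int((self.deltas["verdict"] == "improved").sum()) if len(self.deltas) else 0


def _scores(method: str, X: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    if method == "FR":
        f_stat, _ = f_regression(X, y)
        return np.nan_to_num(f_stat, nan=0.0)
    if method == "MI":
        scores = mutual_info_regression(X, y, random_state=seed)
        scores[np.ptp(X, axis=0) == 0] = 0.0  # constants carry no information
        return scores
    spec = LearnerSpec(method, seed=seed)
    model = make_learner(spec)
    model.fit(X, y)
    importances = np.asarray(model.feature_importances_, dtype=float)
    total = importances.sum()
    return importances / total if total > 0 else importances


def select_features(
    method: str,
    X,
    y,
    keep_rule: str | tuple = "mean",
    seed: int = 0,
) -> list:
    """Return the feature ids kept by ``method``.

    ``keep_rule`` is ``"mean"`` (scores above the mean score, the default),
    ``("top_k", k)``, or ``"positive"`` (scores strictly above zero).
    """
    if method not in SELECTION_METHODS:
        raise ValueError(f"unknown selection method {method!r}; options: {SELECTION_METHODS}")
    if hasattr(X, "frame"):
        frame = X.frame
    elif isinstance(X, pd.DataFrame):
        frame = X
    else:
        frame = pd.DataFrame(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    scores = _scores(method, frame.to_numpy(dtype=float), y, seed)

    if keep_rule == "mean":
        mask = scores > scores.mean()
    elif keep_rule == "positive":
        mask = scores > 0
    elif isinstance(keep_rule, tuple) and keep_rule[0] == "top_k":
        k = int(keep_rule[1])
        order = np.argsort(scores)[::-1][:k]
        mask = np.zeros_like(scores, dtype=bool)
        mask[order] = True
    else:
        raise ValueError(f"unsupported keep_rule {keep_rule!r}")
    selected = [c for c, m in zip(frame.columns, mask) if m]
    if not selected:
        raise ValueError(
            f"selection method {method} kept no features; loosen the keep rule"
        )
    return selected


def evaluate_selection(
    method: str,
    X: pd.DataFrame,
    y,
    learner_specs: list,
    scheme: CvScheme | None = None,
    keep_rule: str | tuple = "mean",
    seed: int = 0,
    baseline_scores: dict | None = None,
) -> SelectionOutcome:
    """Score one selector: per-regressor repeated-CV R^2 before and after.

    The verdict per regressor is ``degraded``/``improved`` when the
    Bonferroni-adjusted (across regressors) paired Wilcoxon p is below 0.05
    and the mean R^2 moved down/up, else ``unchanged``.  Precomputed
    ``baseline_scores`` (learner name -> CvScores on the full design) are
    reused across selectors.
    """
    scheme = scheme or CvScheme()
    if hasattr(X, "frame"):
        X = X.frame
    selected = select_features(method, X, y, keep_rule=keep_rule, seed=seed)
    reduced = X[selected]
    rows = []
    n_comp = len(learner_specs)
    for spec in learner_specs:
        before = (
            baseline_scores[spec.name]
            if baseline_scores and spec.name in baseline_scores
            else repeated_cv(spec, X, y, scheme)
        )
        after = repeated_cv(spec, reduced, y, scheme)
        p_adj = paired_test(after, before, n_comparisons=n_comp)
        if p_adj < 0.05:
            verdict = "improved" if after.mean_r2 > before.mean_r2 else "degraded"
        else:
            verdict = "unchanged"
        rows.append(
            {
                "learner": spec.name,
                "r2_before": before.mean_r2,
                "r2_after": after.mean_r2,
                "p_adjusted": p_adj,
                "verdict": verdict,
            }
        )
    return SelectionOutcome(
        method=method,
        selected_feature_ids=selected,
        n_features=len(selected),
        deltas=pd.DataFrame(rows),
    )


def adjudicate(outcomes: list) -> SelectionOutcome:
    """Choose the best selector.

    Primary criterion: fewest regressors with significant performance
    degradation; ties broken by most significantly improved regressors,
    then by smallest retained feature dimension, then by method name for
    determinism.
    """
    if not outcomes:
        raise ValueError("no selection outcomes to adjudicate")
    return min(
        outcomes,
        key=lambda o: (o.n_degraded, -o.n_improved, o.n_features, o.method),
    )
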