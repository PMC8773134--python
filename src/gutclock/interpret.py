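"""Biomarker discovery by permutation feature importance (PFI) on a frozen
stacked model.

Each candidate feature's column is shuffled across evaluation samples
(50 shuffles by default) within its own view and the ensemble is re-scored;
the per-shuffle drop in R^2 relative to the intact model is that feature's
importance distribution.  A paired Wilcoxon signed-rank test against the
intact baseline, Bonferroni-corrected jointly across all tested features of
both views, flags significant biomarkers; features whose shuffling *helps*
(negative mean drop) are never called significant.  Each biomarker is
annotated with Spearman's rho against age.

PFI here operates on the model's input representation (post-CLR,
post-selection design columns), and is meant to run on samples held out
from generalizer training so the deltas are not optimistic.  Indicator
covariate columns (origin ``onehot:*``) are excluded by default — they are
covariates, not biomarkers.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bench import score_predictions, wilcoxon_signed_rank
from .containers import DesignMatrix
from .stacking import StackModel, _apply_generalizer, _as_frame, _view_oof_predict

__all__ = [
    "BiomarkerRecord",
    "permutation_importance",
    "test_biomarkers",
    "spearman_age_association",
    "biomarker_table",
    "interpret_model",
]


@dataclass
class BiomarkerRecord:
    """PFI result for one feature."""

    feature_id: str
    view: str
    delta_r2: list
    mean_delta_r2: float
    baseline_r2: float
    p_value: float = float("nan")
    p_adjusted: float = float("nan")
    significant: bool = False
    rank: int = 0
    spearman_rho: float = float("nan")
    spearman_p_adjusted: float = float("nan")
    values: np.ndarray | None = field(default=None, repr=False)


def _feature_rng(seed: int, view: str, feature_id: str) -> np.random.Generator:
    # per-feature stream keyed by (seed, view, feature); independent of the
    # order in which features are visited
    key = zlib.crc32(f"{view}:{feature_id}".encode())
    return np.random.default_rng([seed, key])


def permutation_importance(
    model: StackModel,
    views,
    y,
    n_shuffles: int = 50,
    seed: int = 0,
    include_covariates: bool = False,
) -> list[BiomarkerRecord]:
    """Per-feature PFI delta distributions for a frozen stack.

    ``views`` is a design (or dict of per-view designs) covering the
    evaluation samples; ``y`` their true ages.  For every candidate
    feature, the feature's column is shuffled ``n_shuffles`` times and the
    whole frozen pipeline re-run; the record stores baseline R^2 minus each
    shuffle's R^2.  Constant columns yield deltas of exactly zero.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be at least 2 for any downstream test")
    if not isinstance(views, dict):
        views = {next(iter(model.views)): views}
    origins = {}
    frames = {}
    for name, X in views.items():
        if isinstance(X, DesignMatrix):
            origins[name] = X.origins
        frames[name] = _as_frame(X)

    y = np.asarray(y, dtype=float)
    n = len(y)

    # intact OOF blocks per view, reused for every other view's shuffles
    base_blocks = {}
    for name, vs in model.views.items():
        frame = (
            frames[name]
            if name in frames
            else pd.concat(list(frames.values()), axis=1, join="inner")
        )
        block = _view_oof_predict(vs, frame)
        block.columns = [f"{name}|{c}" for c in block.columns]
        base_blocks[name] = block
    base_oof = pd.concat(base_blocks.values(), axis=1)
    baseline_pred = _apply_generalizer(model, base_oof)
    baseline_r2, _ = score_predictions(y, baseline_pred)

    records = []
    for name, vs in model.views.items():
        frame = (
            frames[name]
            if name in frames
            else pd.concat(list(frames.values()), axis=1, join="inner")
        )
        view_origins = origins.get(name, {})
        candidates = []
        for fid in vs.feature_ids:
            origin = view_origins.get(fid, "")
            if not include_covariates and origin.startswith("onehot:"):
                continue
            candidates.append(fid)

        Xv = frame[vs.feature_ids].to_numpy(dtype=float)
        other_oof = pd.concat(
            [b for nm, b in base_blocks.items() if nm != name], axis=1
        ) if len(base_blocks) > 1 else None

        for fid in candidates:
            j = vs.feature_ids.index(fid)
            col = Xv[:, j]
            if np.ptp(col) == 0:
                records.append(
                    BiomarkerRecord(
                        feature_id=fid,
                        view=name,
                        delta_r2=[0.0] * n_shuffles,
                        mean_delta_r2=0.0,
                        baseline_r2=baseline_r2,
                        values=col.copy(),
                    )
                )
                continue
            rng = _feature_rng(seed, name, fid)
            tiled = np.tile(Xv, (n_shuffles, 1))
            for s in range(n_shuffles):
                tiled[s * n : (s + 1) * n, j] = col[rng.permutation(n)]
            # one prediction pass per fold model over all shuffles at once
            cols = {}
            for spec in vs.specs:
                preds = [m.predict(tiled) for m in vs.fold_models[spec.name]]
                cols[f"{name}|{spec.name}"] = np.mean(preds, axis=0)
            oof_shuffled = pd.DataFrame(cols)
            if other_oof is not None:
                tiled_other = pd.concat(
                    [other_oof] * n_shuffles, ignore_index=True
                )
                oof_shuffled = pd.concat([oof_shuffled, tiled_other], axis=1)
            pred = _apply_generalizer(model, oof_shuffled)
            deltas = []
            for s in range(n_shuffles):
                r2_s, _ = score_predictions(y, pred[s * n : (s + 1) * n])
                deltas.append(baseline_r2 - r2_s)
            records.append(
                BiomarkerRecord(
                    feature_id=fid,
                    view=name,
                    delta_r2=deltas,
                    mean_delta_r2=float(np.mean(deltas)),
                    baseline_r2=baseline_r2,
                    values=col.copy(),
                )
            )
    return records


def test_biomarkers(records: list, alpha: float = 0.05) -> list:
    """Significance-test and rank PFI records in place.

    Paired Wilcoxon signed-rank of the permuted scores against the intact
    baseline (equivalently a one-sample test on the deltas), Bonferroni
    across all tested features of both views jointly.  A feature is a
    significant biomarker when its adjusted p is below ``alpha`` *and* its
    mean delta is positive.  Ranking is by mean delta, descending.
    """
    n_tests = len(records)
    for rec in records:
        rec.p_value = wilcoxon_signed_rank(np.asarray(rec.delta_r2))
        rec.p_adjusted = min(1.0, rec.p_value * n_tests)
        rec.significant = bool(rec.p_adjusted < alpha and rec.mean_delta_r2 > 0)
    order = np.argsort([-r.mean_delta_r2 for r in records], kind="stable")
    for pos, i in enumerate(order, start=1):
        records[i].rank = pos
    return records


def spearman_age_association(
    feature_values, ages, n_comparisons: int = 1
) -> tuple[float, float]:
    """Tie-corrected Spearman rho between a feature and age, with a
    Bonferroni-adjusted p-value.  Constant features give (nan, nan)."""
    x = np.asarray(feature_values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 samples for a Spearman association")
    if np.ptp(x) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, a)
    return float(rho), float(min(1.0, p * max(1, n_comparisons)))


def biomarker_table(records: list) -> pd.DataFrame:
    """Flat report of PFI records, ordered by rank."""
    rows = [
        {
            "feature_id": r.feature_id,
            "view": r.view,
            "mean_delta_r2": r.mean_delta_r2,
            "p_adjusted": r.p_adjusted,
            "significant": r.significant,
            "rank": r.rank,
            "spearman_rho": r.spearman_rho,
            "spearman_p_adjusted": r.spearman_p_adjusted,
        }
        for r in sorted(records, key=lambda r: r.rank)
    ]
    return pd.DataFrame(rows)


def interpret_model(
    model: StackModel,
    views,
    y,
    n_shuffles: int = 50,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[BiomarkerRecord]:
    """Full interpretation pass: PFI, significance testing, and Spearman
    age-association annotation of the significant biomarkers."""
    records = permutation_importance(model, views, y, n_shuffles=n_shuffles, seed=seed)
    test_biomarkers(records, alpha=alpha)
    significant = [r for r in records if r.significant]
    for rec in significant:
        rho, p_adj = spearman_age_association(
            rec.values, y, n_comparisons=len(significant)
        )
        rec.spearman_rho = rho
        rec.spearman_p_adjusted = p_adj
    return records
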