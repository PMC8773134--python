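"""Two-stage stacking ensemble and multi-view fusion.

Stage 1 splits the training set into k folds (k=5 by default); each base
learner is fit k times on k-1 folds, and its held-out predictions assemble
the "predicted training set" — an out-of-fold (OOF) age prediction per
training sample that never saw that sample's label.  The k fold models'
mean prediction on new samples is the "predicted test set".  Stage 2 fits a
generalizer (ordinary linear regression by default) on the OOF columns to
learn base-learner weights; the simple average (SA) is the no-fit baseline.

Two multi-view fusion strategies are provided:

* **EM1** — concatenate the views' design matrices first, then run
  single-view stacking on the combined matrix.  Requires the sample
  intersection up front.
* **EM2** — run stage 1 independently per view (each view may use all of
  its own samples), then fuse by fitting the generalizer on the
  concatenated OOF columns over the sample intersection.  This is the
  higher-data-utilization route when views only partially overlap.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .bench import (
    STACK_BASE_LEARNERS,
    CvScheme,
    CvScores,
    LearnerSpec,
    make_learner,
    score_predictions,
)

__all__ = [
    "OofMatrix",
    "ViewStack",
    "StackModel",
    "GENERALIZERS",
    "default_base_specs",
    "stage1_oof",
    "fit_generalizer",
    "predict_ensemble",
    "multiview_stack",
    "outer_cv_evaluate",
    "save_model",
    "load_model",
]

GENERALIZERS = ("SA", "LR", "Lasso", "BR", "LSVM", "SVM", "DT")


def default_base_specs(seed: int = 0) -> list[LearnerSpec]:
    """The nine pre-verified stage-1 base learners."""
    return [LearnerSpec(name, seed=seed) for name in STACK_BASE_LEARNERS]


@dataclass
class OofMatrix:
    """Per-sample, per-(view, learner) age predictions.

    ``role`` is ``"predicted-training-set"`` (strict OOF values) or
    ``"predicted-test-set"`` (mean over the k fold models).
    ``fold_assignment`` records, for the training role, which stage-1 fold
    held out each sample — the bookkeeping behind the no-leakage audit.
    """

    frame: pd.DataFrame
    role: str
    fold_assignment: pd.Series | None = None

    @property
    def sample_ids(self) -> list:
        return list(self.frame.index)


@dataclass
class ViewStack:
    """Frozen stage-1 state for one view: feature ids, base specs and the
    k fitted models per spec."""

    feature_ids: list
    specs: list
    fold_models: dict  # spec name -> list of k fitted estimators


@dataclass
class StackModel:
    """A deployable stacked aging clock."""

    views: dict  # view name -> ViewStack
    generalizer_method: str
    generalizer: object | None  # None for SA
    oof_columns: list  # column order the generalizer expects
    stage1_k: int = 5
    strategy: str = "single"


def _as_frame(X, name: str = "X") -> pd.DataFrame:
    if hasattr(X, "frame"):
        return X.frame
    if isinstance(X, pd.DataFrame):
        return X
    arr = np.asarray(X, dtype=float)
    return pd.DataFrame(arr)


def stage1_oof(
    specs: list,
    X_train,
    y_train,
    X_test=None,
    k: int = 5,
    seed: int = 0,
) -> tuple[OofMatrix, OofMatrix | None, dict]:
    """Stage-1 out-of-fold predictions and frozen fold models.

    One k-fold partition (shuffled, seeded) is shared by all specs so the
    OOF columns are comparable and downstream pairing is valid.  Returns
    the predicted training set, the predicted test set (or ``None`` when
    ``X_test`` is not given), and ``{spec name: [k fitted models]}``.
    """
    X_train = _as_frame(X_train)
    y = np.asarray(y_train, dtype=float)
    if len(X_train) != y.size:
        raise ValueError("X_train and y_train are not aligned")
    if k < 2:
        raise ValueError("stage-1 requires k >= 2")
    X_te = _as_frame(X_test) if X_test is not None else None

    Xv = X_train.to_numpy(dtype=float)
    kf = KFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**31 - 1))
    folds = list(kf.split(Xv))
    for _, held in folds:
        if held.size == 0:
            raise ValueError("empty stage-1 fold")
    assignment = np.empty(len(X_train), dtype=int)
    for f, (_, held) in enumerate(folds):
        assignment[held] = f

    oof_train = pd.DataFrame(
        np.nan, index=X_train.index, columns=[s.name for s in specs]
    )
    oof_test = (
        pd.DataFrame(0.0, index=X_te.index, columns=[s.name for s in specs])
        if X_te is not None
        else None
    )
    models: dict[str, list] = {}
    for spec in specs:
        fitted = []
        for f, (tr, held) in enumerate(folds):
            model = make_learner(spec.with_seed(spec.seed + f))
            model.fit(Xv[tr], y[tr])
            oof_train.iloc[held, oof_train.columns.get_loc(spec.name)] = model.predict(
                Xv[held]
            )
            if oof_test is not None:
                oof_test[spec.name] += model.predict(X_te.to_numpy(dtype=float)) / k
            fitted.append(model)
        models[spec.name] = fitted

    train = OofMatrix(
        oof_train,
        role="predicted-training-set",
        fold_assignment=pd.Series(assignment, index=X_train.index),
    )
    test = OofMatrix(oof_test, role="predicted-test-set") if oof_test is not None else None
    return train, test, models


def fit_generalizer(oof_train: OofMatrix | pd.DataFrame, y_train, method: str = "LR"):
    """Fit the stage-2 generalizer on OOF columns.

    ``SA`` returns ``None`` (equal weights, no fit).  ``DT`` is permitted
    but warns: a tree generalizer tends to overfit the OOF columns badly.
    """
    if method not in GENERALIZERS:
        raise ValueError(f"unknown generalizer {method!r}; options: {GENERALIZERS}")
    if method == "SA":
        return None
    if method == "DT":
        warnings.warn(
            "DT generalizer is prone to severe overfitting of OOF columns",
            UserWarning,
            stacklevel=2,
        )
    frame = oof_train.frame if isinstance(oof_train, OofMatrix) else oof_train
    model = make_learner(LearnerSpec(method))
    model.fit(frame.to_numpy(dtype=float), np.asarray(y_train, dtype=float))
    return model


def _apply_generalizer(model: StackModel, oof: pd.DataFrame) -> np.ndarray:
    cols = oof[model.oof_columns].to_numpy(dtype=float)
    if model.generalizer is None:  # simple average
        return cols.mean(axis=1)
    return np.asarray(model.generalizer.predict(cols), dtype=float)


def _view_oof_predict(view_stack: ViewStack, X: pd.DataFrame) -> pd.DataFrame:
    missing = [f for f in view_stack.feature_ids if f not in X.columns]
    if missing:
        raise ValueError(f"design lacks trained feature ids (first few: {missing[:5]})")
    Xv = X[view_stack.feature_ids].to_numpy(dtype=float)
    out = {}
    for spec in view_stack.specs:
        preds = [m.predict(Xv) for m in view_stack.fold_models[spec.name]]
        out[spec.name] = np.mean(preds, axis=0)
    return pd.DataFrame(out, index=X.index)


def predict_ensemble(model: StackModel, views) -> pd.Series:
    """Predict ages with a frozen stack.

    ``views`` is a design matrix (single-view models) or a dict of view
    name -> design.  Each (view, learner) OOF column is the mean of the k
    frozen fold models' predictions; the generalizer then combines them.
    """
    if not isinstance(views, dict):
        if len(model.views) != 1:
            raise ValueError("multi-view model needs a dict of per-view designs")
        views = {next(iter(model.views)): views}
    frames = {name: _as_frame(X) for name, X in views.items()}

    oof_blocks = []
    for name, view_stack in model.views.items():
        if name in frames:
            frame = frames[name]
        elif name == "concat":
            frame = pd.concat(list(frames.values()), axis=1, join="inner")
        else:
            raise ValueError(f"model requires view {name!r} which was not provided")
        block = _view_oof_predict(view_stack, frame)
        block.columns = [f"{name}|{c}" for c in block.columns]
        oof_blocks.append(block)
    oof = pd.concat(oof_blocks, axis=1, join="inner")
    if oof.empty:
        raise ValueError("no samples shared by all required views")
    return pd.Series(_apply_generalizer(model, oof), index=oof.index, name="predicted_age")


def multiview_stack(
    views: dict,
    y,
    generalizer: str = "LR",
    k: int = 5,
    seed: int = 0,
    strategy: str = "EM2",
    specs: list | None = None,
) -> StackModel:
    """Train a stacked model over one or more views.

    ``views`` maps view name -> design matrix (samples x features; a
    DataFrame index carries sample ids).  ``y`` is a Series of ages indexed
    by sample id (or an array aligned with every view).  With ``EM2`` each
    view's stage 1 uses all samples available for that view and only the
    generalizer needs the intersection; ``EM1`` concatenates the views over
    the intersection first and stacks the combined design.
    """
    if strategy not in ("EM1", "EM2", "single"):
        raise ValueError("strategy must be 'EM1', 'EM2' or 'single'")
    specs = specs if specs is not None else default_base_specs(seed)
    frames = {name: _as_frame(X) for name, X in views.items()}
    if not isinstance(y, pd.Series):
        first = next(iter(frames.values()))
        y = pd.Series(np.asarray(y, dtype=float), index=first.index)

    if strategy in ("EM1", "single"):
        if strategy == "EM1":
            combined = pd.concat(list(frames.values()), axis=1, join="inner")
            name = "concat"
        else:
            (name, combined), = frames.items()
        combined = combined.loc[combined.index.intersection(y.index)]
        if combined.empty:
            raise ValueError("empty sample intersection across views and labels")
        yv = y.loc[combined.index]
        oof_train, _, models = stage1_oof(specs, combined, yv, k=k, seed=seed)
        oof_train.frame.columns = [f"{name}|{c}" for c in oof_train.frame.columns]
        gen = fit_generalizer(oof_train.frame, yv, generalizer)
        return StackModel(
            views={
                name: ViewStack(
                    feature_ids=list(combined.columns), specs=specs, fold_models=models
                )
            },
            generalizer_method=generalizer,
            generalizer=gen,
            oof_columns=list(oof_train.frame.columns),
            stage1_k=k,
            strategy=strategy,
        )

    # EM2: stage 1 per view on all that view's labelled samples
    view_stacks, oof_blocks = {}, []
    for i, (name, frame) in enumerate(frames.items()):
        avail = frame.index.intersection(y.index)
        oof_train, _, models = stage1_oof(
            specs, frame.loc[avail], y.loc[avail], k=k, seed=seed + i
        )
        block = oof_train.frame.copy()
        block.columns = [f"{name}|{c}" for c in block.columns]
        oof_blocks.append(block)
        view_stacks[name] = ViewStack(
            feature_ids=list(frame.columns), specs=specs, fold_models=models
        )
    oof = pd.concat(oof_blocks, axis=1, join="inner")
    if oof.empty:
        raise ValueError("empty sample intersection across views")
    gen = fit_generalizer(oof, y.loc[oof.index], generalizer)
    return StackModel(
        views=view_stacks,
        generalizer_method=generalizer,
        generalizer=gen,
        oof_columns=list(oof.columns),
        stage1_k=k,
        strategy="EM2",
    )


def outer_cv_evaluate(
    views: dict,
    y,
    scheme: CvScheme | None = None,
    specs: list | None = None,
    k: int = 5,
    generalizers: tuple = ("LR",),
    view_subsets: list | None = None,
    base_singles: bool = False,
    include_em1: bool = False,
    seed: int = 0,
) -> dict:
    """Evaluate stacking variants under one outer repeated-CV scheme.

    The entire stacking procedure (stage-1 k-fold included) is re-run
    inside each outer training set, so every reported score is leakage
    free.  Stage-1 OOF matrices are computed once per view per outer split
    and shared across generalizers and view subsets, which makes the
    family of comparisons (ensemble vs single learners, single- vs
    multi-view, generalizer choices) paired on identical splits.

    Returns a dict of label -> :class:`CvScores` with labels
    ``"stack:<generalizer>:<subset>"``, ``"single:<view>:<learner>"`` and
    ``"stack:EM1:<generalizer>"``.
    """
    scheme = scheme or CvScheme(n_repeats=2, n_folds=5)
    specs = specs if specs is not None else default_base_specs(seed)
    frames = {name: _as_frame(X) for name, X in views.items()}
    first = next(iter(frames.values()))
    if not isinstance(y, pd.Series):
        y = pd.Series(np.asarray(y, dtype=float), index=first.index)
    common = first.index
    for frame in frames.values():
        common = common.intersection(frame.index)
    common = common.intersection(y.index)
    frames = {n: f.loc[common] for n, f in frames.items()}
    yv = y.loc[common]

    if view_subsets is None:
        names = list(frames)
        view_subsets = [tuple([n]) for n in names] + ([tuple(names)] if len(names) > 1 else [])

    results: dict[str, dict] = {}

    def _add(label: str, r2: float, mae: float) -> None:
        slot = results.setdefault(label, {"r2": [], "mae": []})
        slot["r2"].append(r2)
        slot["mae"].append(mae)

    n = len(common)
    for rep, fold, tr, te in scheme.splits(n):
        split_seed = (seed * 1_000_003 + rep * 31 + fold) % (2**31 - 1)
        y_tr, y_te = yv.iloc[tr], yv.iloc[te]
        oof_tr_blocks, oof_te_blocks = {}, {}
        for name, frame in frames.items():
            oof_tr, oof_te, _ = stage1_oof(
                specs, frame.iloc[tr], y_tr, frame.iloc[te], k=k, seed=split_seed
            )
            oof_tr_blocks[name] = oof_tr.frame.add_prefix(f"{name}|")
            oof_te_blocks[name] = oof_te.frame.add_prefix(f"{name}|")

        for subset in view_subsets:
            tr_mat = pd.concat([oof_tr_blocks[n_] for n_ in subset], axis=1)
            te_mat = pd.concat([oof_te_blocks[n_] for n_ in subset], axis=1)
            for gen_name in generalizers:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    gen = fit_generalizer(tr_mat, y_tr, gen_name)
                if gen is None:
                    pred = te_mat.to_numpy(dtype=float).mean(axis=1)
                else:
                    pred = gen.predict(te_mat.to_numpy(dtype=float))
                r2, mae = score_predictions(y_te, pred)
                _add(f"stack:{gen_name}:{'+'.join(subset)}", r2, mae)

        if base_singles:
            for name, frame in frames.items():
                Xtr = frame.iloc[tr].to_numpy(dtype=float)
                Xte = frame.iloc[te].to_numpy(dtype=float)
                for spec in specs:
                    model = make_learner(spec.with_seed(spec.seed + rep))
                    model.fit(Xtr, y_tr.to_numpy())
                    r2, mae = score_predictions(y_te, model.predict(Xte))
                    _add(f"single:{name}:{spec.name}", r2, mae)

        if include_em1 and len(frames) > 1:
            combined = pd.concat(list(frames.values()), axis=1)
            oof_tr, oof_te, _ = stage1_oof(
                specs, combined.iloc[tr], y_tr, combined.iloc[te], k=k, seed=split_seed
            )
            for gen_name in generalizers:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    gen = fit_generalizer(oof_tr.frame, y_tr, gen_name)
                if gen is None:
                    pred = oof_te.frame.to_numpy(dtype=float).mean(axis=1)
                else:
                    pred = gen.predict(oof_te.frame.to_numpy(dtype=float))
                r2, mae = score_predictions(y_te, pred)
                _add(f"stack:EM1:{gen_name}", r2, mae)

    return {
        label: CvScores(r2=v["r2"], mae=v["mae"], scheme=scheme, learner=label)
        for label, v in results.items()
    }


# ---------------------------------------------------------------------------
# serialization: JSON manifest + joblib blobs


def save_model(model: StackModel, directory) -> Path:
    """Serialize a stack to ``directory`` (JSON manifest + joblib blobs)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": 1,
        "strategy": model.strategy,
        "generalizer_method": model.generalizer_method,
        "oof_columns": model.oof_columns,
        "stage1_k": model.stage1_k,
        "views": {
            name: {
                "feature_ids": vs.feature_ids,
                "specs": [
                    {"name": s.name, "hyperparameters": s.hyperparameters, "seed": s.seed}
                    for s in vs.specs
                ],
            }
            for name, vs in model.views.items()
        },
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    blobs = {
        "generalizer": model.generalizer,
        "fold_models": {n: vs.fold_models for n, vs in model.views.items()},
    }
    joblib.dump(blobs, directory / "models.joblib")
    return directory


def load_model(directory) -> StackModel:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    blobs = joblib.load(directory / "models.joblib")
    views = {
        name: ViewStack(
            feature_ids=info["feature_ids"],
            specs=[
                LearnerSpec(s["name"], s["hyperparameters"], s["seed"])
                for s in info["specs"]
            ],
            fold_models=blobs["fold_models"][name],
        )
        for name, info in manifest["views"].items()
    }
    return StackModel(
        views=views,
        generalizer_method=manifest["generalizer_method"],
        generalizer=blobs["generalizer"],
        oof_columns=manifest["oof_columns"],
        stage1_k=manifest["stage1_k"],
        strategy=manifest["strategy"],
    )
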