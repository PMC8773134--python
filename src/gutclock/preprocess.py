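"""Compositional preprocessing: zero replacement, CLR, design assembly.

Relative-abundance profiles live on the simplex, so Euclidean models cannot
be applied to them directly.  The standard route taken here is multiplicative
zero replacement followed by the centered log-ratio (CLR) transform
``clr(x)_i = ln(x_i) - mean_j ln(x_j)``, which maps each composition to
unconstrained coordinates with row sum zero.  Indicator covariates such as
geographic subregion are *not* compositional parts and are appended to the
design after the CLR step.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from skbio.stats.composition import clr as _skbio_clr
from skbio.stats.composition import multi_replace as _skbio_multi_replace

from .containers import AbundanceView, ClrMatrix, CohortMetadata, DesignMatrix

__all__ = [
    "multiplicative_replacement",
    "clr_transform",
    "encode_subregion",
    "assemble_design",
]


def _auto_delta(values: np.ndarray) -> float:
    """Default replacement value: 1/D^2, capped below half the smallest
    observed positive entry so replacement never dominates a real part."""
    d = values.shape[1]
    delta = 1.0 / (d * d)
    positive = values[values > 0]
    if positive.size:
        delta = min(delta, 0.5 * float(positive.min()))
    return delta


def multiplicative_replacement(
    view: AbundanceView, delta: float | None = None
) -> AbundanceView:
    """Replace zeros with ``delta`` and rescale nonzero parts to preserve
    closure.

    For a row with ``z`` zeros, each zero becomes ``delta`` and each nonzero
    entry ``x_i`` becomes ``x_i * (1 - z * delta)``, so the row still sums
    to one.  Rows without zeros are returned unchanged.

    Parameters
    ----------
    view
        Relative abundances with rows summing to ~1.
    delta
        Replacement value; ``None`` selects ``1/D^2`` capped at half the
        minimum positive entry.

    Raises
    ------
    ValueError
        If a row is entirely zero (the composition is undefined) or the row
        sums are not ~1.
    """
    values = view.values
    sums = values.sum(axis=1)
    zero_rows = np.flatnonzero(sums == 0)
    if zero_rows.size:
        raise ValueError(
            f"multiplicative_replacement: all-zero row(s) at sample(s) "
            f"{[view.sample_ids[i] for i in zero_rows[:5]]} — composition undefined"
        )
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError(
            "multiplicative_replacement: rows must sum to 1 within 1e-6 "
            f"(max deviation {np.abs(sums - 1.0).max():.3g})"
        )
    if delta is None:
        delta = _auto_delta(values)
    if delta <= 0:
        raise ValueError("delta must be positive")
    positive = values[values > 0]
    if positive.size and delta >= float(positive.min()):
        raise ValueError(
            f"delta={delta:.3g} is not smaller than the minimum positive "
            f"entry {float(positive.min()):.3g}"
        )
    if not np.any(values == 0):
        return view

    n_zero = (values == 0).sum(axis=1)
    if np.any(1.0 - n_zero * delta <= 0):
        raise ValueError("delta too large: a row would lose all its mass")
    out = np.asarray(_skbio_multi_replace(values, delta=delta)).reshape(values.shape)
    return AbundanceView(
        pd.DataFrame(out, index=view.frame.index, columns=view.frame.columns),
        name=view.name,
    )


def clr_transform(view: AbundanceView) -> ClrMatrix:
    """Centered log-ratio transform of a strictly positive composition.

    Delegates to :func:`skbio.stats.composition.clr`; rows of the result sum
    to zero and the transform is invariant to per-row rescaling.
    """
    values = view.values
    if np.any(values <= 0):
        raise ValueError(
            "clr_transform requires strictly positive values; run "
            "multiplicative_replacement first"
        )
    coords = _skbio_clr(values)
    # re-center exactly: skbio leaves row sums at ~1e-15, we promise 1e-10
    coords = coords - coords.mean(axis=1, keepdims=True)
    return ClrMatrix(
        pd.DataFrame(coords, index=view.frame.index, columns=view.frame.columns),
        name=view.name,
    )


def encode_subregion(
    metadata: CohortMetadata, column: str = "subregion"
) -> DesignMatrix:
    """One-hot indicator block for the geographic subregion covariate.

    One column per observed level, in lexicographic order, named
    ``subregion=<level>``.  A single observed level yields one all-ones
    column and a warning (uninformative for any model).
    """
    if column not in metadata.frame.columns:
        raise ValueError(f"metadata has no {column!r} column")
    labels = metadata.frame[column]
    if labels.isna().any():
        bad = labels.index[labels.isna()].tolist()
        raise ValueError(f"missing {column} label for sample(s) {bad[:5]}")
    levels = sorted(labels.unique())
    if len(levels) == 1:
        warnings.warn(
            f"encode_subregion: single level {levels[0]!r} observed; the "
            "indicator block is uninformative",
            UserWarning,
            stacklevel=2,
        )
    block = pd.DataFrame(
        {f"{column}={lv}": (labels == lv).astype(float) for lv in levels},
        index=labels.index,
    )
    origins = {c: f"onehot:{column}" for c in block.columns}
    return DesignMatrix(block, origins=origins)


def assemble_design(primary: ClrMatrix, extras: list | None = None) -> DesignMatrix:
    """Concatenate a CLR matrix with extra blocks (one-hot covariates or a
    second view's CLR matrix) into one design.

    All blocks must share identical sample ids in identical order; one-hot
    blocks are appended as-is, never log-ratio transformed.
    """
    blocks: list[pd.DataFrame] = [primary.frame]
    origins = {c: f"clr:{primary.name}" for c in primary.frame.columns}
    for extra in extras or []:
        if isinstance(extra, ClrMatrix):
            frame = extra.frame
            tag = {c: f"clr:{extra.name}" for c in frame.columns}
        elif isinstance(extra, DesignMatrix):
            frame = extra.frame
            tag = dict(extra.origins)
        else:
            raise TypeError(f"unsupported design block type {type(extra)!r}")
        if list(frame.index) != list(primary.frame.index):
            missing = set(primary.frame.index).symmetric_difference(frame.index)
            raise ValueError(
                f"sample mismatch between design blocks; symmetric difference: "
                f"{sorted(missing)[:10]}"
            )
        blocks.append(frame)
        origins.update(tag)
    combined = pd.concat(blocks, axis=1)
    if combined.columns.has_duplicates:
        raise ValueError("duplicate column ids across design blocks")
    return DesignMatrix(combined, origins=origins)
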