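"""Core data containers shared across the pipeline.

All tabular containers are thin, validated wrappers around
:class:`pandas.DataFrame` with samples on the rows.  Sample identifiers are
carried on the index and are required to be unique; feature identifiers are
the column labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceView",
    "ClrMatrix",
    "DesignMatrix",
    "CohortMetadata",
]


def _check_frame(frame: pd.DataFrame, name: str) -> None:
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"{name}: duplicate sample ids {dup}")
    if frame.columns.has_duplicates:
        dup = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise ValueError(f"{name}: duplicate feature ids {dup}")


@dataclass
class AbundanceView:
    """One compositional samples x features table (e.g. species or pathways).

    Values are relative abundances: non-negative, each row summing to ~1.
    Rows on a percent scale (summing to ~100) are renormalized to 1 on
    construction.
    """

    frame: pd.DataFrame
    name: str = "view"

    def __post_init__(self) -> None:
        _check_frame(self.frame, f"AbundanceView({self.name})")
        values = self.frame.to_numpy(dtype=float)
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"AbundanceView({self.name}): negative value at sample "
                f"{self.frame.index[i]!r}, feature {self.frame.columns[j]!r}"
            )
        sums = values.sum(axis=1)
        if np.any(np.abs(sums - 100.0) < 1.0):
            # percent-scale input; close to 1
            with np.errstate(invalid="ignore"):
                values = values / sums[:, None]
            self.frame = pd.DataFrame(
                values, index=self.frame.index, columns=self.frame.columns
            )

    @property
    def sample_ids(self) -> list:
        return list(self.frame.index)

    @property
    def feature_ids(self) -> list:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.frame.shape[0]

    @property
    def n_features(self) -> int:
        return self.frame.shape[1]

    def subset_samples(self, sample_ids) -> "AbundanceView":
        return AbundanceView(self.frame.loc[list(sample_ids)].copy(), name=self.name)


@dataclass
class ClrMatrix:
    """Centered log-ratio coordinates: each row sums to zero."""

    frame: pd.DataFrame
    name: str = "clr"

    def __post_init__(self) -> None:
        _check_frame(self.frame, f"ClrMatrix({self.name})")
        sums = self.frame.to_numpy(dtype=float).sum(axis=1)
        if np.any(np.abs(sums) > 1e-8):
            raise ValueError(
                f"ClrMatrix({self.name}): row sums deviate from zero "
                f"(max |sum| = {np.abs(sums).max():.3g})"
            )

    @property
    def sample_ids(self) -> list:
        return list(self.frame.index)

    @property
    def feature_ids(self) -> list:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)


@dataclass
class DesignMatrix:
    """Model-ready design: CLR blocks and/or one-hot covariate blocks.

    ``origins`` maps each column to the block it came from, one of
    ``"clr:<view name>"`` or ``"onehot:<covariate>"``.
    """

    frame: pd.DataFrame
    origins: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_frame(self.frame, "DesignMatrix")
        missing = [c for c in self.frame.columns if c not in self.origins]
        if missing:
            self.origins = {**{c: "clr:unknown" for c in missing}, **self.origins}

    @property
    def sample_ids(self) -> list:
        return list(self.frame.index)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def columns_from(self, prefix: str) -> list:
        return [c for c, o in self.origins.items() if o.startswith(prefix)]


@dataclass
class CohortMetadata:
    """Per-sample host and technical covariates, indexed by sample id.

    The ``age`` column (years) is mandatory.  Other recognised columns:
    ``country``, ``subregion``, ``westernized``, ``sex``, ``bmi``,
    ``platform``, ``extraction_kit``; extra columns are carried through and
    their missing fractions tracked.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if "age" not in self.frame.columns:
            raise ValueError("CohortMetadata: mandatory 'age' column is missing")
        if self.frame.index.has_duplicates:
            raise ValueError("CohortMetadata: duplicate sample ids")

    @property
    def sample_ids(self) -> list:
        return list(self.frame.index)

    @property
    def ages(self) -> np.ndarray:
        return self.frame["age"].to_numpy(dtype=float)

    def missing_fractions(self) -> pd.Series:
        return self.frame.isna().mean()

    def subset_samples(self, sample_ids) -> "CohortMetadata":
        return CohortMetadata(self.frame.loc[list(sample_ids)].copy())
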