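"""Host-factor effect sizes and geography/age decoupling.

Two jobs live here.  First, covariate-adjusted PERMANOVA: a sequential
(Type-I) partitioning of a Bray-Curtis distance matrix's sum of squares
across an ordered list of metadata terms, with free permutation of sample
labels for inference — the semantics of ``vegan::adonis`` with a
``dissimilarities ~ covariate + platform + extraction kit`` formula.  Both
categorical and continuous terms are supported.

Second, decoupling geography from age: countries are regrouped to United
Nations M49 subregions, small subregion bins are dropped, and subregions are
then removed iteratively — most age-informative first, as ranked by random
forest feature importance on the one-hot subregion design — until a random
forest can no longer predict age from geography (cross-validated R^2 below a
threshold) or a single subregion remains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.ensemble import RandomForestRegressor

from .bench import CvScheme, LearnerSpec, repeated_cv
from .containers import AbundanceView, CohortMetadata, DesignMatrix
from .preprocess import encode_subregion

__all__ = [
    "PermanovaResult",
    "ScreenResult",
    "filter_metadata_columns",
    "load_m49_mapping",
    "regroup_to_subregion",
    "add_subregion_column",
    "SUBREGION_ABBREVIATIONS",
    "bray_curtis",
    "adonis_permanova",
    "covariate_effects",
    "assoc_region_age",
    "screen_subregions",
]

SUBREGION_ABBREVIATIONS = {
    "EA": "Eastern Asia",
    "NA": "Northern America",
    "NE": "Northern Europe",
    "SE": "Southern Europe",
    "WE": "Western Europe",
    "CE": "Central Europe",
    "EE": "Eastern Europe",
    "SA": "Southern Asia",
    "SEA": "South-eastern Asia",
    "WA": "Western Asia",
    "CA": "Central Asia",
    "SSA": "Sub-Saharan Africa",
    "NAF": "Northern Africa",
    "SAM": "South America",
    "CAM": "Central America",
    "ANZ": "Australia and New Zealand",
}


@dataclass
class PermanovaResult:
    term: str
    pseudo_F: float
    r2: float
    p_value: float
    p_adjusted: float
    n_permutations: int
    df: int = 1


@dataclass
class ScreenResult:
    """Record of the iterative subregion screen.

    ``epochs`` is an ordered list of ``(removed_subregion, importance,
    assoc_r2_before_removal)``; ``final_assoc_r2`` is the geography-age
    association of the retained subset.
    """

    epochs: list
    retained_subregions: list
    final_assoc_r2: float
    retained_sample_ids: list
    dropped_small_bins: list = field(default_factory=list)
    threshold: float = 0.01


# ---------------------------------------------------------------------------
# metadata filtering and M49 regrouping


def filter_metadata_columns(
    metadata: CohortMetadata,
    missing_threshold: float = 0.4,
    redundancy_map: dict | None = None,
) -> CohortMetadata:
    """Drop unreliable and redundant metadata columns.

    Columns whose missing fraction is >= ``missing_threshold`` are removed,
    as are columns declared redundant to a kept column via
    ``redundancy_map`` (e.g. ``{"age_category": "age"}``).
    """
    frame = metadata.frame.copy()
    fractions = frame.isna().mean()
    drop = [c for c in frame.columns if fractions[c] >= missing_threshold]
    if "age" in drop:
        raise ValueError(
            f"age column has {fractions['age']:.0%} missing values; cannot proceed"
        )
    for redundant, kept in (redundancy_map or {}).items():
        if redundant in frame.columns and kept in frame.columns and kept not in drop:
            drop.append(redundant)
    return CohortMetadata(frame.drop(columns=sorted(set(drop))))


def load_m49_mapping() -> dict:
    """Country -> M49 subregion abbreviation, from the shipped TSV."""
    path = resources.files("gutclock.data").joinpath("m49_subregions.tsv")
    # keep_default_na: the Northern America abbreviation is literally "NA"
    table = pd.read_csv(path, sep="\t", keep_default_na=False)
    return dict(zip(table["country"], table["subregion"]))


def regroup_to_subregion(country: str, mapping: dict | None = None) -> str:
    """Map one country label to its M49 subregion abbreviation."""
    mapping = mapping if mapping is not None else load_m49_mapping()
    if country not in mapping:
        raise KeyError(f"country {country!r} has no M49 subregion mapping")
    return mapping[country]


def add_subregion_column(
    metadata: CohortMetadata, mapping: dict | None = None
) -> CohortMetadata:
    """Regroup the ``country`` column into a ``subregion`` column."""
    mapping = mapping if mapping is not None else load_m49_mapping()
    frame = metadata.frame.copy()
    frame["subregion"] = [
        regroup_to_subregion(c, mapping) for c in frame["country"]
    ]
    return CohortMetadata(frame)


# ---------------------------------------------------------------------------
# Bray-Curtis + PERMANOVA


def bray_curtis(view: AbundanceView) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix, d(i,j) = sum|x-y| / sum(x+y)."""
    values = view.values
    zero_rows = np.flatnonzero(values.sum(axis=1) == 0)
    if zero_rows.size >= 2:
        raise ValueError(
            "Bray-Curtis undefined between all-zero samples: "
            f"{[view.sample_ids[i] for i in zero_rows]}"
        )
    dmat = squareform(pdist(values, metric="braycurtis"))
    return pd.DataFrame(dmat, index=view.sample_ids, columns=view.sample_ids)


def _gower_center(dmat: np.ndarray) -> np.ndarray:
    a = -0.5 * dmat**2
    n = a.shape[0]
    row = a.mean(axis=0, keepdims=True)
    col = a.mean(axis=1, keepdims=True)
    return a - row - col + a.mean()


def _term_basis(values: pd.Series) -> tuple[np.ndarray, bool]:
    """Raw design columns for one term (categorical dummies or a centered
    numeric column)."""
    if values.dtype.kind in "fiu" and values.nunique() > 2:
        x = values.to_numpy(dtype=float)[:, None]
        return x - x.mean(), False
    levels = pd.unique(values)
    if len(levels) < 2:
        raise ValueError(
            f"term {values.name!r} has a single level; no variance to partition"
        )
    dummies = pd.get_dummies(values.astype(str)).to_numpy(dtype=float)
    return dummies - dummies.mean(axis=0), True


def adonis_permanova(
    dmat,
    metadata,
    terms: list,
    n_permutations: int = 9999,
    seed: int = 0,
) -> list[PermanovaResult]:
    """Sequential PERMANOVA of a distance matrix over ordered model terms.

    The Gower-centered matrix ``G`` of squared distances is partitioned by
    projecting onto the terms' design columns in the given order; each
    term's pseudo-F is its mean square over the residual mean square, and
    p-values come from free permutation of sample labels.  Per-term
    p-values are Bonferroni-adjusted across the tested terms.

    Returns one :class:`PermanovaResult` per term plus a ``Residual`` row;
    the ``r2`` values over terms and residual sum to 1.
    """
    if isinstance(metadata, CohortMetadata):
        meta = metadata.frame
    else:
        meta = metadata
    if isinstance(dmat, pd.DataFrame):
        dvals = dmat.to_numpy(dtype=float)
    else:
        dvals = np.asarray(dmat, dtype=float)
    n = dvals.shape[0]
    if len(meta) != n:
        raise ValueError("distance matrix and metadata are not aligned")
    if n_permutations < 99:
        warnings.warn(
            f"n_permutations={n_permutations} gives coarse p-values",
            UserWarning,
            stacklevel=2,
        )

    keep = meta[list(terms)].notna().all(axis=1).to_numpy()
    if not keep.all():
        meta = meta.loc[keep]
        dvals = dvals[np.ix_(keep, keep)]
        n = dvals.shape[0]

    g = _gower_center(dvals)
    ss_total = float(np.trace(g))

    # orthonormal incremental bases per term (intercept direction excluded
    # implicitly: all design columns are centered)
    bases: list[np.ndarray] = []
    accumulated = np.zeros((n, 0))
    dfs = []
    for term in terms:
        cols, _ = _term_basis(meta[term])
        stacked = np.hstack([accumulated, cols])
        q, r = np.linalg.qr(stacked)
        rank = int(np.sum(np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(r).max())))
        q = q[:, :rank]
        prev = accumulated.shape[1]
        bases.append(q[:, prev:])
        dfs.append(rank - prev)
        accumulated = q
    df_model = sum(dfs)
    df_res = n - 1 - df_model
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def partition(q_blocks: list[np.ndarray]) -> np.ndarray:
        return np.array(
            [float(np.sum(qb * (g @ qb))) for qb in q_blocks]
        )

    ss_terms = partition(bases)
    ss_res = ss_total - ss_terms.sum()
    ms_res = ss_res / df_res
    f_obs = (ss_terms / np.array(dfs)) / ms_res

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    chunk = max(1, min(n_permutations, int(2e7 / (n * max(1, df_model)))))
    done = 0
    while done < n_permutations:
        c = min(chunk, n_permutations - done)
        idx = np.argsort(rng.random((c, n)), axis=1)  # c random permutations
        ss_p = np.zeros((c, len(terms)))
        for j, qb in enumerate(bases):
            if qb.shape[1] == 0:
                continue
            vp = qb[idx].transpose(1, 0, 2).reshape(n, -1)  # n x (c*df_j)
            gv = g @ vp
            ss_p[:, j] = (vp * gv).sum(axis=0).reshape(c, qb.shape[1]).sum(axis=1)
        ss_res_p = ss_total - ss_p.sum(axis=1)
        f_p = (ss_p / np.array(dfs)) / (ss_res_p / df_res)[:, None]
        # count ties as exceedances: label permutations that reproduce the
        # observed grouping (e.g. swapped group names) have identical F up
        # to floating-point noise and must not be dropped
        tol = 1e-8 * np.maximum(1.0, np.abs(f_obs))
        exceed += (f_p >= f_obs - tol).sum(axis=0)
        done += c
    p_values = (1.0 + exceed) / (1.0 + n_permutations)

    results = [
        PermanovaResult(
            term=t,
            pseudo_F=float(f_obs[j]),
            r2=float(ss_terms[j] / ss_total),
            p_value=float(p_values[j]),
            p_adjusted=float(min(1.0, p_values[j] * len(terms))),
            n_permutations=n_permutations,
            df=dfs[j],
        )
        for j, t in enumerate(terms)
    ]
    results.append(
        PermanovaResult(
            term="Residual",
            pseudo_F=float("nan"),
            r2=float(ss_res / ss_total),
            p_value=float("nan"),
            p_adjusted=float("nan"),
            n_permutations=n_permutations,
            df=df_res,
        )
    )
    return results


def covariate_effects(
    dmat,
    metadata,
    covariates: list,
    confounders: list = ("platform", "extraction_kit"),
    n_permutations: int = 9999,
    seed: int = 0,
    confounders_first: bool = False,
) -> pd.DataFrame:
    """One adjusted PERMANOVA per covariate, Bonferroni across covariates.

    Each covariate is tested with the formula ``distance ~ covariate +
    confounders`` (or confounders first when ``confounders_first``), and the
    covariate's p-value is multiplied by the number of covariates tested.
    """
    rows = []
    for i, cov in enumerate(covariates):
        terms = (
            list(confounders) + [cov] if confounders_first else [cov] + list(confounders)
        )
        res = adonis_permanova(
            dmat, metadata, terms, n_permutations=n_permutations, seed=seed + i
        )
        entry = next(r for r in res if r.term == cov)
        rows.append(
            {
                "covariate": cov,
                "pseudo_F": entry.pseudo_F,
                "r2": entry.r2,
                "p_value": entry.p_value,
                "p_adjusted": min(1.0, entry.p_value * len(covariates)),
            }
        )
    return pd.DataFrame(rows).set_index("covariate")


# ---------------------------------------------------------------------------
# geography-age association and the iterative subregion screen


def assoc_region_age(
    onehot,
    ages,
    learner: str = "random-forest",
    cv: CvScheme | None = None,
) -> float:
    """Mean cross-validated R^2 of predicting age from geography indicators.

    ``learner`` is ``"linear"`` or ``"random-forest"``.  The raw mean is
    returned (it may be negative under no association).
    """
    cv = cv or CvScheme()
    if isinstance(onehot, DesignMatrix):
        X = onehot.values
    else:
        X = np.asarray(onehot, dtype=float)
    if X.shape[1] < 2:
        warnings.warn(
            "fewer than two indicator columns; association is degenerate",
            UserWarning,
            stacklevel=2,
        )
    name = {"linear": "LR", "random-forest": "RF"}.get(learner)
    if name is None:
        raise ValueError("learner must be 'linear' or 'random-forest'")
    scores = repeated_cv(LearnerSpec(name, seed=cv.base_seed), X, ages, cv)
    return scores.mean_r2


def _subregion_importances(
    metadata: CohortMetadata, seed: int
) -> pd.Series:
    """Random-forest impurity importance of each subregion's indicator
    columns (summed per subregion) for predicting age."""
    design = encode_subregion(metadata)
    rf = RandomForestRegressor(random_state=seed)
    rf.fit(design.values, metadata.ages)
    scores = pd.Series(rf.feature_importances_, index=design.frame.columns)
    out = {}
    for col, score in scores.items():
        region = col.split("=", 1)[1]
        out[region] = out.get(region, 0.0) + float(score)
    return pd.Series(out)


def screen_subregions(
    metadata: CohortMetadata,
    min_bin_size: int = 200,
    threshold: float = 0.01,
    cv: CvScheme | None = None,
    seed: int = 0,
    views: dict | None = None,
) -> ScreenResult:
    """Iteratively remove age-confounded subregions.

    Subregion bins with at most ``min_bin_size`` samples are dropped up
    front.  Then, while a random forest predicts age from the one-hot
    subregion design with cross-validated R^2 >= ``threshold`` and more
    than one bin remains, the subregion with the largest summed feature
    importance is removed together with its samples.

    ``views`` is unused by the screen itself (the decision is metadata
    driven) but accepted so callers can pass the full cohort through.
    """
    cv = cv or CvScheme()
    if "subregion" not in metadata.frame.columns:
        raise ValueError("metadata lacks a subregion column; regroup countries first")
    counts = metadata.frame["subregion"].value_counts()
    small = sorted(counts.index[counts <= min_bin_size])
    if len(small) == len(counts):
        raise ValueError(
            f"all subregion bins have <= {min_bin_size} samples; nothing to screen"
        )
    current = metadata.frame[~metadata.frame["subregion"].isin(small)]

    epochs = []
    epoch_seed = seed
    while True:
        sub = CohortMetadata(current)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            design = encode_subregion(sub)
            r2 = assoc_region_age(
                design,
                sub.ages,
                learner="random-forest",
                cv=CvScheme(cv.n_repeats, cv.n_folds, cv.base_seed + epoch_seed),
            )
        remaining = sorted(current["subregion"].unique())
        if r2 < threshold or len(remaining) == 1:
            return ScreenResult(
                epochs=epochs,
                retained_subregions=remaining,
                final_assoc_r2=float(r2),
                retained_sample_ids=list(current.index),
                dropped_small_bins=small,
                threshold=threshold,
            )
        importances = _subregion_importances(sub, seed=seed + epoch_seed)
        worst = importances.idxmax()
        epochs.append((worst, float(importances[worst]), float(r2)))
        current = current[current["subregion"] != worst]
        epoch_seed += 1
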