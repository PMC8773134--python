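"""Synthetic two-view compositional cohorts with controllable age signal.

The generator emulates the structure of a pooled multi-cohort stool
metagenome resource: a species-level relative-abundance view and a
metabolic-pathway view over the same samples, adult ages on [18, 107] with a
median near 52 years, geographic subregion labels whose sampling can be
deliberately confounded with age, and a planted set of features whose
log-abundance trends monotonically with age.  Ground truth (which features
carry signal, and with what sign) is recorded so recovery can be scored.

Model
-----
Ages are drawn from a scaled Beta distribution calibrated to the requested
median.  For each view, feature ``j`` of sample ``i`` has log-abundance

    log a_ij = mu_j + s_j * g_j(age_i) + delta_{r(i), j} + eps_ij

with per-feature baseline ``mu_j ~ Normal(0, 2)`` (heavy-tailed abundances
after exponentiation), planted trend ``g_j`` (linear or a monotone step in
age, slope ``signal_effect`` per year, sign ``s_j``), a subregion shift
``delta`` on a random subset of features (geography structure), and noise
``eps ~ Normal(0, noise_dispersion)``.  Rows are exponentiated, entries
below a sparsity floor are zeroed, and each row is closed to sum 1.

Confounding between subregion and age is produced by a mixture assignment:
with probability ``m`` a sample's subregion is its age-quantile block, with
probability ``1 - m`` it is drawn from the nominal sampling weights.  ``m``
is calibrated by bisection on a large pre-run so that the fraction of age
variance explained by subregion matches ``confound_strength``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AbundanceView, CohortMetadata

__all__ = ["SyntheticConfig", "SyntheticCohort", "generate_cohort"]

_AGE_MIN, _AGE_MAX = 18.0, 107.0

#: default subregion labels (M49 abbreviations) and sampling weights,
#: mirroring the regions that dominate public stool-metagenome collections
_DEFAULT_SUBREGIONS = {
    "EA": 0.25,
    "NA": 0.20,
    "NE": 0.15,
    "SE": 0.15,
    "WE": 0.15,
    "CE": 0.10,
}

_COUNTRIES = {
    "EA": ["CHN", "JPN"],
    "NA": ["USA", "CAN"],
    "NE": ["SWE", "DNK"],
    "SE": ["ITA", "ESP"],
    "WE": ["FRA", "DEU"],
    "CE": ["HUN", "POL"],
}


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic cohort.

    Attributes
    ----------
    n_samples, n_species, n_pathways
        Cohort and view dimensions.  Defaults mirror a large pooled
        metagenome collection (904 species, 468 pathways).
    age_range, age_median_target
        Support and target median of the age distribution, in years.
    subregions
        Mapping of subregion label -> sampling weight.
    confound_strength
        Target fraction of age variance explained by subregion, in [0, 1).
    confounded_subregions
        Optional subset of subregions that carry the age enrichment; the
        rest are sampled independently of age.  ``None`` lets every
        subregion participate in the age-banded assignment.
    n_signal_features_per_view
        Number of planted age-associated features in each view.
    signal_effect
        Log-abundance slope per year of age for planted features.
    noise_dispersion
        Standard deviation of per-sample log-abundance noise.
    threshold_fraction
        Fraction of planted features whose trend is a monotone step at a
        random age cut instead of a linear ramp.
    species_signal_window, pathway_signal_window
        Optional age interval (years) outside which a view's planted trends
        are flat; lets the two views carry complementary age information.
    region_effect_sd, region_effect_fraction
        Scale and prevalence of subregion-specific log-abundance shifts.
    sparsity_floor
        Relative abundances below this value are zeroed before closure.
    """

    n_samples: int = 4478
    n_species: int = 904
    n_pathways: int = 468
    age_range: tuple = (_AGE_MIN, _AGE_MAX)
    age_median_target: float = 52.0
    subregions: dict = field(default_factory=lambda: dict(_DEFAULT_SUBREGIONS))
    confound_strength: float = 0.1
    n_signal_features_per_view: int = 40
    signal_effect: float = 0.01
    noise_dispersion: float = 1.0
    seed: int = 0
    threshold_fraction: float = 0.0
    species_signal_window: tuple | None = None
    pathway_signal_window: tuple | None = None
    region_effect_sd: float = 0.5
    region_effect_fraction: float = 0.2
    sparsity_floor: float = 1e-5
    confounded_subregions: tuple | None = None

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        if not (_AGE_MIN <= lo < hi <= _AGE_MAX):
            raise ValueError(f"age_range must lie within [{_AGE_MIN}, {_AGE_MAX}]")
        if not (lo < self.age_median_target < hi):
            raise ValueError("age_median_target outside age_range")
        if not (0.0 <= self.confound_strength < 1.0):
            raise ValueError("confound_strength must be in [0, 1)")
        if self.noise_dispersion <= 0:
            raise ValueError("noise_dispersion must be positive")
        if self.n_signal_features_per_view > min(self.n_species, self.n_pathways):
            raise ValueError("n_signal_features_per_view exceeds a view dimension")
        if len(self.subregions) < 1:
            raise ValueError("at least one subregion is required")
        total = sum(self.subregions.values())
        if total <= 0:
            raise ValueError("subregion weights must have positive sum")
        self.subregions = {k: v / total for k, v in self.subregions.items()}
        if self.confounded_subregions is not None:
            unknown = set(self.confounded_subregions) - set(self.subregions)
            if unknown:
                raise ValueError(f"confounded_subregions not in subregions: {unknown}")


@dataclass
class SyntheticCohort:
    """A generated cohort: two abundance views, metadata and ground truth.

    ``truth`` maps view name ("species" | "pathway") to a list of
    ``(feature_id, sign)`` pairs for the planted age-trend features.
    """

    species_view: AbundanceView
    pathway_view: AbundanceView
    metadata: CohortMetadata
    truth: dict
    config: SyntheticConfig

    @property
    def ages(self) -> np.ndarray:
        return self.metadata.ages


def _draw_ages(
    n: int, age_range: tuple, median_target: float, rng: np.random.Generator
) -> np.ndarray:
    lo, hi = age_range
    span = hi - lo
    # Beta(a, b) with a=2; b solved from the median approximation
    # median(Beta) ~ (a - 1/3) / (a + b - 2/3)
    med_t = (median_target - lo) / span
    a = 2.0
    b = (a - 1.0 / 3.0) / med_t - a + 2.0 / 3.0
    b = max(b, 0.2)
    return lo + span * rng.beta(a, b, size=n)


def _quantile_blocks(ages: np.ndarray, labels: list, weights: np.ndarray) -> np.ndarray:
    """Assign each sample the subregion whose cumulative-weight interval
    contains the sample's age-quantile rank."""
    n = len(ages)
    ranks = np.empty(n)
    ranks[np.argsort(ages, kind="stable")] = np.arange(n) / max(n - 1, 1)
    edges = np.cumsum(weights)
    idx = np.minimum(np.searchsorted(edges, ranks, side="right"), len(labels) - 1)
    return np.asarray(labels, dtype=object)[idx]


def _assign_regions(
    ages: np.ndarray,
    labels: list,
    weights: np.ndarray,
    m: float,
    confounded: tuple | None,
    u_mix: np.ndarray,
    random_regions: np.ndarray,
) -> np.ndarray:
    blocks = _quantile_blocks(ages, labels, weights)
    use_block = u_mix < m
    if confounded is not None:
        use_block &= np.isin(blocks, list(confounded))
    return np.where(use_block, blocks, random_regions)


def _group_r2(ages: np.ndarray, groups: np.ndarray) -> float:
    """Fraction of age variance explained by group means (eta squared)."""
    total = np.var(ages)
    if total == 0:
        return 0.0
    resid = 0.0
    for g in np.unique(groups):
        sub = ages[groups == g]
        resid += np.sum((sub - sub.mean()) ** 2)
    return 1.0 - resid / (len(ages) * total)


def _calibrate_mixture(
    cfg: SyntheticConfig,
    ages: np.ndarray,
    labels: list,
    weights: np.ndarray,
    u_mix: np.ndarray,
    random_regions: np.ndarray,
) -> float:
    """Find the mixture weight m whose subregion assignment explains
    ``confound_strength`` of age variance.

    Bisection runs on the cohort's own age and assignment draws (common
    random numbers), so the achieved between-subregion variance fraction
    matches the target up to the cross-validation penalty of whatever model
    later measures it, without realization noise from a separate pre-run.
    """
    if cfg.confound_strength == 0.0:
        return 0.0

    def achieved(m: float) -> float:
        assigned = _assign_regions(
            ages, labels, weights, m, cfg.confounded_subregions, u_mix, random_regions
        )
        return _group_r2(ages, assigned)

    r2_max = achieved(1.0)
    if cfg.confound_strength > r2_max - 0.01:
        raise ValueError(
            f"confound_strength={cfg.confound_strength} infeasible with "
            f"{len(labels)} subregions (maximum achievable ~{r2_max:.3f})"
        )
    lo_m, hi_m = 0.0, 1.0
    for _ in range(40):
        mid = 0.5 * (lo_m + hi_m)
        if achieved(mid) < cfg.confound_strength:
            lo_m = mid
        else:
            hi_m = mid
    return 0.5 * (lo_m + hi_m)


def _view_table(
    n_features: int,
    prefix: str,
    ages: np.ndarray,
    regions: np.ndarray,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    window: tuple | None,
) -> tuple[pd.DataFrame, list]:
    n = len(ages)
    feature_ids = [f"{prefix}{j:04d}" for j in range(n_features)]
    mu = rng.normal(0.0, 2.0, size=n_features)
    log_abund = np.tile(mu, (n, 1)) + rng.normal(
        0.0, cfg.noise_dispersion, size=(n, n_features)
    )

    # subregion-specific shifts on a random feature subset (geography signal)
    labels = sorted(set(regions))
    n_geo = int(round(cfg.region_effect_fraction * n_features))
    geo_idx = rng.choice(n_features, size=n_geo, replace=False)
    delta = rng.normal(0.0, cfg.region_effect_sd, size=(len(labels), n_geo))
    region_row = np.searchsorted(labels, regions)
    log_abund[:, geo_idx] += delta[region_row]

    # planted monotone age trends
    lo, hi = cfg.age_range
    w_lo, w_hi = window if window is not None else (lo, hi)
    eff_age = np.clip(ages, w_lo, w_hi)
    signal_idx = rng.choice(n_features, size=cfg.n_signal_features_per_view, replace=False)
    truth = []
    n_step = int(round(cfg.threshold_fraction * cfg.n_signal_features_per_view))
    for rank, j in enumerate(signal_idx):
        sign = 1.0 if rank % 2 == 0 else -1.0
        if rank < n_step:
            cut = rng.uniform(w_lo + 0.2 * (w_hi - w_lo), w_hi - 0.2 * (w_hi - w_lo))
            trend = cfg.signal_effect * 0.5 * (w_hi - w_lo) * (eff_age > cut)
        else:
            trend = cfg.signal_effect * (eff_age - 0.5 * (w_lo + w_hi))
        log_abund[:, j] += sign * trend
        truth.append((feature_ids[j], int(sign)))

    abund = np.exp(log_abund)
    abund /= abund.sum(axis=1, keepdims=True)
    abund[abund < cfg.sparsity_floor] = 0.0
    abund /= abund.sum(axis=1, keepdims=True)
    return pd.DataFrame(abund, columns=feature_ids), truth


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a deterministic synthetic cohort from ``config``.

    Returns a :class:`SyntheticCohort` whose views are closed compositions
    (rows sum to 1), whose metadata includes age, country, subregion and
    plausible technical covariates, and whose ``truth`` lists the planted
    signal features per view with their trend signs.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    ages = _draw_ages(cfg.n_samples, cfg.age_range, cfg.age_median_target, rng)

    labels = sorted(cfg.subregions)
    weights = np.array([cfg.subregions[k] for k in labels])
    u_mix = rng.uniform(size=cfg.n_samples)
    random_regions = rng.choice(labels, size=cfg.n_samples, p=weights)
    m = _calibrate_mixture(cfg, ages, labels, weights, u_mix, random_regions)
    regions = _assign_regions(
        ages, labels, weights, m, cfg.confounded_subregions, u_mix, random_regions
    )

    countries = np.array(
        [
            rng.choice(_COUNTRIES.get(r, [f"{r}-1", f"{r}-2"]))
            for r in regions
        ],
        dtype=object,
    )

    sample_ids = [f"S{i:05d}" for i in range(cfg.n_samples)]
    species, truth_sp = _view_table(
        cfg.n_species, "sp_", ages, regions, cfg, rng, cfg.species_signal_window
    )
    pathway, truth_pw = _view_table(
        cfg.n_pathways, "pw_", ages, regions, cfg, rng, cfg.pathway_signal_window
    )
    species.index = sample_ids
    pathway.index = sample_ids

    meta = pd.DataFrame(
        {
            "age": np.round(ages, 2),
            "country": countries,
            "subregion": regions,
            "westernized": rng.choice(["yes", "no"], size=cfg.n_samples, p=[0.8, 0.2]),
            "sex": rng.choice(["female", "male"], size=cfg.n_samples),
            "bmi": np.round(rng.normal(25.0, 4.0, size=cfg.n_samples), 1),
            "platform": rng.choice(
                ["IlluminaHiSeq", "IlluminaNovaSeq"], size=cfg.n_samples, p=[0.7, 0.3]
            ),
            "extraction_kit": rng.choice(
                ["Qiagen", "MoBio", "Gnome"], size=cfg.n_samples, p=[0.5, 0.3, 0.2]
            ),
        },
        index=sample_ids,
    )

    return SyntheticCohort(
        species_view=AbundanceView(species, name="species"),
        pathway_view=AbundanceView(pathway, name="pathway"),
        metadata=CohortMetadata(meta),
        truth={"species": truth_sp, "pathway": truth_pw},
        config=cfg,
    )
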