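"""Pre-registered simulation experiments exercising the whole pipeline.

Each function generates its own synthetic cohort at fixed study conditions,
runs one pipeline stage end to end, and returns the measured quantities.
They are shared by the acceptance test suite and the reproduction script so
both always measure the same procedure.  Problem sizes are chosen so the
full set runs on a single CPU in well under an hour; docs/methods.md
records them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bench import CvScheme, LearnerSpec, paired_test
from .containers import AbundanceView
from .interpret import interpret_model, spearman_age_association
from .preprocess import clr_transform, encode_subregion, multiplicative_replacement
from .screen import adonis_permanova, assoc_region_age, bray_curtis, screen_subregions
from .stacking import multiview_stack, outer_cv_evaluate
from .synthetic import SyntheticConfig, generate_cohort

__all__ = [
    "decoupling_experiment",
    "permanova_null_calibration",
    "stacking_experiment",
    "pfi_recovery_experiment",
    "spearman_trend_experiment",
]


def _clr(view):
    return clr_transform(multiplicative_replacement(view)).frame


def decoupling_experiment(seed: int = 0, n_samples: int = 1500) -> dict:
    """Screen a geographically confounded cohort and re-measure the
    geography-age association of the retained subset independently.

    The cohort plants an age enrichment (target R^2 = 0.10, about what
    country-level geography explains in pooled stool-metagenome cohorts) in
    two of six subregions.  The screen uses the 0.01 decoupling threshold
    under 10x5 CV; the final association is then recomputed with a fresh
    10x5 scheme and an independently seeded random forest.
    """
    cohort = generate_cohort(
        SyntheticConfig(
            n_samples=n_samples,
            n_species=10,
            n_pathways=10,
            n_signal_features_per_view=2,
            confound_strength=0.10,
            confounded_subregions=("CE", "WE"),
            seed=seed,
        )
    )
    result = screen_subregions(
        cohort.metadata,
        min_bin_size=100,
        threshold=0.01,
        cv=CvScheme(10, 5, seed),
        seed=seed,
    )
    retained = cohort.metadata.subset_samples(result.retained_sample_ids)
    independent_r2 = assoc_region_age(
        encode_subregion(retained),
        retained.ages,
        learner="random-forest",
        cv=CvScheme(10, 5, seed + 7919),
    )
    before = assoc_region_age(
        encode_subregion(cohort.metadata),
        cohort.ages,
        learner="random-forest",
        cv=CvScheme(10, 5, seed + 104729),
    )
    return {
        "screen": result,
        "assoc_r2_before": float(before),
        "independent_assoc_r2": float(independent_r2),
        "n_retained": len(result.retained_sample_ids),
        "threshold": 0.01,
    }


def permanova_null_calibration(
    seed: int = 0, n_sims: int = 500, n: int = 24, n_permutations: int = 199
) -> dict:
    """Type-I error of the PERMANOVA under a true null.

    ``n_sims`` datasets of ``n`` compositions with a random two-level group
    label independent of the data; returns the fraction rejected at 0.05.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for i in range(n_sims):
        data = rng.dirichlet(np.ones(8), size=n)
        labels = rng.permutation([("A" if j < n // 2 else "B") for j in range(n)])
        meta = pd.DataFrame(
            {"group": labels}, index=[f"s{k}" for k in range(n)]
        )
        dmat = bray_curtis(
            AbundanceView(pd.DataFrame(data, index=meta.index))
        )
        res = adonis_permanova(
            dmat, meta, ["group"], n_permutations=n_permutations, seed=int(rng.integers(2**31 - 1))
        )
        if res[0].p_value <= 0.05:
            rejections += 1
    return {"rejection_rate": rejections / n_sims, "n_sims": n_sims, "alpha": 0.05}


def heterogeneous_cohort(seed: int = 0, n_samples: int = 800):
    """Two-view cohort with disjoint, complementary planted signals:
    species features track age below the median, pathway features above,
    half linear ramps and half monotone steps."""
    return generate_cohort(
        SyntheticConfig(
            n_samples=n_samples,
            n_species=40,
            n_pathways=30,
            n_signal_features_per_view=12,
            confound_strength=0.0,
            signal_effect=0.03,
            threshold_fraction=0.5,
            species_signal_window=(18, 52),
            pathway_signal_window=(52, 107),
            seed=seed,
        )
    )


def stacking_experiment(seed: int = 0, n_samples: int = 800, n_repeats: int = 2) -> dict:
    """Ensemble vs single learners, single- vs multi-view, and the
    generalizer family, all under one shared outer CV.

    Returns the per-label :class:`CvScores` plus the headline comparisons.
    """
    cohort = heterogeneous_cohort(seed, n_samples)
    views = {
        "species": _clr(cohort.species_view),
        "pathway": _clr(cohort.pathway_view),
    }
    y = pd.Series(cohort.ages, index=cohort.metadata.sample_ids)
    scores = outer_cv_evaluate(
        views,
        y,
        scheme=CvScheme(n_repeats, 5, seed),
        generalizers=("SA", "LR", "Lasso", "BR", "LSVM", "SVM", "DT"),
        base_singles=True,
        seed=seed,
    )
    singles = {k: v for k, v in scores.items() if k.startswith("single:")}
    best_single = max(singles.values(), key=lambda s: s.mean_r2)
    ensemble = scores["stack:LR:species+pathway"]
    sv_best = max(
        (scores["stack:LR:species"], scores["stack:LR:pathway"]),
        key=lambda s: s.mean_r2,
    )
    return {
        "scores": scores,
        "best_single": best_single,
        "ensemble": ensemble,
        "best_single_view_ensemble": sv_best,
        "multiview_gain_p": paired_test(ensemble, sv_best),
    }


def pfi_recovery_experiment(seed: int = 0, n_runs: int = 20) -> dict:
    """Planted-biomarker recovery by PFI over independently seeded runs.

    Each run trains a compact stack (Lasso/GBRT/LGB bases) on 70% of a
    fresh cohort and interprets it on the held-out 30%; a run counts as a
    full recovery when every planted feature is Bonferroni-significant and
    out-ranks every non-planted feature.
    """
    full, details = 0, []
    for r in range(n_runs):
        run_seed = (seed * 1000 + r) % (2**31 - 1)
        cohort = generate_cohort(
            SyntheticConfig(
                n_samples=400,
                n_species=40,
                n_pathways=25,
                n_signal_features_per_view=4,
                confound_strength=0.0,
                signal_effect=0.05,
                seed=run_seed,
            )
        )
        clr_s, clr_p = _clr(cohort.species_view), _clr(cohort.pathway_view)
        y = pd.Series(cohort.ages, index=cohort.metadata.sample_ids)
        tr, te = y.index[:280], y.index[280:]
        model = multiview_stack(
            {"species": clr_s.loc[tr], "pathway": clr_p.loc[tr]},
            y.loc[tr],
            specs=[LearnerSpec(n, seed=r) for n in ("Lasso", "GBRT", "LGB")],
            seed=run_seed,
        )
        records = interpret_model(
            model,
            {"species": clr_s.loc[te], "pathway": clr_p.loc[te]},
            y.loc[te],
            n_shuffles=50,
            seed=run_seed,
        )
        planted = {f for f, _ in cohort.truth["species"]} | {
            f for f, _ in cohort.truth["pathway"]
        }
        by_id = {rec.feature_id: rec for rec in records}
        all_significant = all(by_id[f].significant for f in planted)
        worst_rank = max(by_id[f].rank for f in planted)
        ranked_on_top = worst_rank <= len(planted)
        ok = all_significant and ranked_on_top
        full += ok
        details.append(
            {"run": r, "all_significant": all_significant, "worst_rank": worst_rank}
        )
    return {"recovery_rate": full / n_runs, "n_runs": n_runs, "details": details}


def spearman_trend_experiment(seed: int = 0, n_samples: int = 500) -> dict:
    """Sign and significance of Spearman age associations for planted
    increasing/decreasing features at moderate cohort size."""
    cohort = generate_cohort(
        SyntheticConfig(
            n_samples=n_samples,
            n_species=120,
            n_pathways=80,
            n_signal_features_per_view=10,
            confound_strength=0.0,
            signal_effect=0.02,
            seed=seed,
        )
    )
    truth = cohort.truth["species"] + cohort.truth["pathway"]
    frames = {"sp": cohort.species_view.frame, "pw": cohort.pathway_view.frame}
    correct, sig = 0, 0
    rows = []
    for fid, sign in truth:
        frame = frames["sp"] if fid.startswith("sp_") else frames["pw"]
        rho, p_adj = spearman_age_association(
            frame[fid], cohort.ages, n_comparisons=len(truth)
        )
        correct += int(np.sign(rho) == sign)
        sig += int(p_adj < 0.05)
        rows.append({"feature": fid, "sign": sign, "rho": rho, "p_adjusted": p_adj})
    return {
        "n_planted": len(truth),
        "sign_correct": correct,
        "significant": sig,
        "records": rows,
    }
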