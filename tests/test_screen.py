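"""Metadata filtering, M49 regrouping, Bray-Curtis, sequential PERMANOVA
and the iterative subregion screen."""

import json
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from gutclock import (
    AbundanceView,
    CohortMetadata,
    adonis_permanova,
    assoc_region_age,
    bray_curtis,
    filter_metadata_columns,
    regroup_to_subregion,
    screen_subregions,
)
from gutclock.bench import CvScheme
from gutclock.screen import SUBREGION_ABBREVIATIONS, covariate_effects, load_m49_mapping


def view_of(rows):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return AbundanceView(
        pd.DataFrame(
            rows,
            index=[f"s{i}" for i in range(rows.shape[0])],
            columns=[f"f{j}" for j in range(rows.shape[1])],
        )
    )


class TestMetadataFilter:
    def metadata(self):
        n = 10
        return CohortMetadata(
            pd.DataFrame(
                {
                    "age": np.linspace(20, 80, n),
                    "age_category": ["adult"] * n,
                    "half_missing": [1.0] * 5 + [np.nan] * 5,
                    "complete": range(n),
                },
                index=[f"s{i}" for i in range(n)],
            )
        )

    def test_half_missing_dropped_at_40pct_threshold(self):
        out = filter_metadata_columns(self.metadata(), missing_threshold=0.4)
        assert "half_missing" not in out.frame.columns

    def test_redundant_column_dropped_kept_target_stays(self):
        out = filter_metadata_columns(
            self.metadata(), redundancy_map={"age_category": "age"}
        )
        assert "age_category" not in out.frame.columns
        assert "age" in out.frame.columns

    def test_fully_observed_column_retained(self):
        out = filter_metadata_columns(self.metadata())
        assert "complete" in out.frame.columns


class TestRegrouping:
    def test_known_countries_map_to_subregions(self):
        assert regroup_to_subregion("CHN") == "EA"
        assert regroup_to_subregion("FRA") == "WE"

    def test_abbreviations_expand_for_reports(self):
        assert SUBREGION_ABBREVIATIONS["EA"] == "Eastern Asia"
        assert SUBREGION_ABBREVIATIONS["WE"] == "Western Europe"

    def test_unmapped_country_raises_with_label(self):
        with pytest.raises(KeyError, match="Atlantis"):
            regroup_to_subregion("Atlantis")

    def test_shipped_mapping_targets_known_subregions(self):
        mapping = load_m49_mapping()
        assert set(mapping.values()) <= set(SUBREGION_ABBREVIATIONS)


class TestBrayCurtis:
    def test_identical_rows_distance_zero(self):
        d = bray_curtis(view_of([[0.2, 0.8], [0.2, 0.8]]))
        assert d.iloc[0, 1] == 0.0

    def test_disjoint_support_distance_one(self):
        d = bray_curtis(view_of([[1.0, 0.0], [0.0, 1.0]]))
        assert d.iloc[0, 1] == pytest.approx(1.0)

    def test_hand_worked_pair(self):
        # sum|x-y| = 4, sum(x+y) = 8
        d = bray_curtis(view_of([[2, 2, 0], [0, 2, 2]]))
        assert d.iloc[0, 1] == pytest.approx(0.5)

    def test_two_all_zero_rows_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(view_of([[0, 0], [0, 0], [1, 0]]))


def toy_distance_cohort(rng, n=24, groups=("A", "B", "C"), shift=0.0):
    """Small composition + metadata set for PERMANOVA tests."""
    labels = np.repeat(groups, n // len(groups))
    base = rng.dirichlet(np.ones(8), size=n)
    group_feature = {g: j % 8 for j, g in enumerate(groups)}
    for i, g in enumerate(labels):
        base[i, group_feature[g]] += shift
    base /= base.sum(axis=1, keepdims=True)
    view = view_of(base)
    meta = CohortMetadata(
        pd.DataFrame(
            {
                "age": rng.uniform(20, 80, n),
                "group": labels,
                "platform": rng.choice(["P1", "P2"], n),
            },
            index=view.sample_ids,
        )
    )
    return view, meta


class TestAdonis:
    def test_r2_partition_sums_to_one(self, rng):
        view, meta = toy_distance_cohort(rng, shift=0.3)
        res = adonis_permanova(
            bray_curtis(view), meta, ["group", "platform", "age"], 99, seed=0
        )
        assert sum(r.r2 for r in res) == pytest.approx(1.0, abs=1e-9)

    def test_joint_row_permutation_invariance(self, rng):
        view, meta = toy_distance_cohort(rng, shift=0.3)
        d = bray_curtis(view)
        res = adonis_permanova(d, meta, ["group", "age"], 999, seed=5)
        perm = rng.permutation(len(meta.frame))
        d2 = d.iloc[perm, perm]
        meta2 = CohortMetadata(meta.frame.iloc[perm])
        res2 = adonis_permanova(d2, meta2, ["group", "age"], 999, seed=5)
        for a, b in zip(res, res2):
            assert a.pseudo_F == pytest.approx(b.pseudo_F, abs=1e-10, nan_ok=True)
            assert a.r2 == pytest.approx(b.r2, abs=1e-10)
            # p is Monte-Carlo: allow 3-4 sigma of permutation noise
            assert a.p_value == pytest.approx(b.p_value, abs=0.06, nan_ok=True)

    def test_perfect_separation(self):
        # two blocks, within-distance 0, between-distance 1
        d = np.ones((8, 8))
        d[:4, :4] = 0.0
        d[4:, 4:] = 0.0
        np.fill_diagonal(d, 0.0)
        meta = CohortMetadata(
            pd.DataFrame(
                {"age": np.arange(8, dtype=float) + 20, "group": ["x"] * 4 + ["y"] * 4}
            )
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            res = adonis_permanova(d, meta, ["group"], 999, seed=0)
        group = res[0]
        assert group.r2 == pytest.approx(1.0, abs=1e-12)
        # permutations preserving the blocks also separate perfectly, so the
        # exact p is 4!4!2/8! = 0.0286, not the 1/(B+1) floor
        assert group.p_value == pytest.approx(1152 / 40320, abs=0.02)

    def test_single_level_term_rejected(self, rng):
        view, meta = toy_distance_cohort(rng)
        meta.frame["platform"] = "P1"
        with pytest.raises(ValueError, match="single level"):
            adonis_permanova(bray_curtis(view), meta, ["platform"], 99)

    def test_few_permutations_warn(self, rng):
        view, meta = toy_distance_cohort(rng)
        with pytest.warns(UserWarning, match="coarse"):
            adonis_permanova(bray_curtis(view), meta, ["group"], 49)

    def test_default_permutation_count_is_9999(self):
        import inspect

        sig = inspect.signature(adonis_permanova)
        assert sig.parameters["n_permutations"].default == 9999

    def test_matches_skbio_one_way_pseudo_f(self, rng):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        view, meta = toy_distance_cohort(rng, shift=0.2)
        d = bray_curtis(view)
        ours = adonis_permanova(d, meta, ["group"], 99, seed=0)[0]
        theirs = skbio_permanova(
            DistanceMatrix(d.to_numpy(), ids=list(d.index)),
            meta.frame["group"].to_numpy(),
            permutations=99,
        )
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-10)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_vegan_adonis2_sequential(self, rng, tmp_path):
        """Multi-term sequential partition agrees with vegan::adonis2."""
        view, meta = toy_distance_cohort(rng, shift=0.25)
        d = bray_curtis(view)
        d.to_csv(tmp_path / "d.tsv", sep="\t")
        meta.frame.to_csv(tmp_path / "meta.tsv", sep="\t")
        script = textwrap.dedent(
            """
            suppressMessages(library(vegan))
            d <- as.dist(as.matrix(read.table("d.tsv", sep="\t", header=TRUE, row.names=1)))
            m <- read.table("meta.tsv", sep="\t", header=TRUE, row.names=1)
            fit <- adonis2(d ~ group + platform + age, data=m, permutations=99, by="terms")
            out <- data.frame(term=rownames(fit), F=fit$F, R2=fit$R2)
            write.table(out, "vegan.tsv", sep="\t", row.names=FALSE, quote=FALSE)
            """
        )
        (tmp_path / "run.R").write_text(script)
        subprocess.run(
            ["Rscript", "run.R"], cwd=tmp_path, check=True, capture_output=True
        )
        vegan = pd.read_csv(tmp_path / "vegan.tsv", sep="\t").set_index("term")
        ours = adonis_permanova(d, meta, ["group", "platform", "age"], 99, seed=0)
        for rec in ours:
            key = rec.term if rec.term != "Residual" else "Residual"
            assert rec.r2 == pytest.approx(vegan.loc[key, "R2"], abs=1e-8)
            if rec.term != "Residual":
                assert rec.pseudo_F == pytest.approx(vegan.loc[key, "F"], abs=1e-8)

    def test_covariate_effects_bonferroni(self, rng):
        view, meta = toy_distance_cohort(rng, shift=0.3)
        table = covariate_effects(
            bray_curtis(view),
            meta,
            covariates=["group", "age"],
            confounders=["platform"],
            n_permutations=99,
            seed=0,
        )
        assert (table["p_adjusted"] >= table["p_value"]).all()
        assert (table["p_adjusted"] <= 1.0).all()


def enriched_metadata(rng, n_per=80):
    """Three subregions; region NE is strongly enriched for the elderly."""
    ages, regions = [], []
    for region, (lo, hi) in {"EA": (20, 75), "NA": (20, 75), "NE": (60, 90)}.items():
        ages.extend(rng.uniform(lo, hi, n_per))
        regions.extend([region] * n_per)
    return CohortMetadata(
        pd.DataFrame(
            {"age": ages, "subregion": regions},
            index=[f"s{i}" for i in range(len(ages))],
        )
    )


class TestScreenSubregions:
    def test_small_bins_dropped_before_loop(self, rng):
        meta = enriched_metadata(rng).frame
        extra = pd.DataFrame(
            {"age": rng.uniform(20, 80, 30), "subregion": ["SE"] * 30},
            index=[f"t{i}" for i in range(30)],
        )
        merged = CohortMetadata(pd.concat([meta, extra]))
        result = screen_subregions(
            merged, min_bin_size=50, threshold=0.01, cv=CvScheme(2, 5, 0), seed=0
        )
        assert result.dropped_small_bins == ["SE"]
        assert "SE" not in result.retained_subregions

    def test_age_enriched_subregion_removed_first(self, rng):
        result = screen_subregions(
            enriched_metadata(rng),
            min_bin_size=10,
            threshold=0.01,
            cv=CvScheme(2, 5, 0),
            seed=0,
        )
        assert result.epochs, "expected at least one removal epoch"
        assert result.epochs[0][0] == "NE"
        assert result.final_assoc_r2 < 0.01 or len(result.retained_subregions) == 1

    def test_unconfounded_cohort_exits_immediately(self, rng):
        ages = rng.uniform(20, 80, 240)
        meta = CohortMetadata(
            pd.DataFrame(
                {"age": ages, "subregion": rng.choice(["EA", "NA", "NE"], 240)},
                index=[f"s{i}" for i in range(240)],
            )
        )
        result = screen_subregions(
            meta, min_bin_size=10, threshold=0.01, cv=CvScheme(2, 5, 0), seed=0
        )
        assert result.epochs == []
        assert sorted(result.retained_subregions) == ["EA", "NA", "NE"]

    def test_retained_sets_are_nested(self, rng):
        # rerun the enriched case and confirm monotone shrinkage via epochs
        result = screen_subregions(
            enriched_metadata(rng),
            min_bin_size=10,
            threshold=0.001,
            cv=CvScheme(2, 5, 0),
            seed=0,
        )
        removed = [e[0] for e in result.epochs]
        assert len(set(removed)) == len(removed)
        assert not set(removed) & set(result.retained_subregions)


def test_assoc_region_age_warns_single_column(rng):
    X = np.ones((40, 1))
    with pytest.warns(UserWarning, match="indicator"):
        assoc_region_age(X, rng.uniform(20, 80, 40), learner="linear", cv=CvScheme(1, 4, 0))
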