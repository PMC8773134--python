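"""Two-stage stacking: OOF construction, generalizers, multi-view fusion."""

import numpy as np
import pandas as pd
import pytest
from sklearn.dummy import DummyRegressor

from gutclock import (
    CvScheme,
    LearnerSpec,
    fit_generalizer,
    load_model,
    multiview_stack,
    predict_ensemble,
    save_model,
    stage1_oof,
)
from gutclock.bench import LEARNER_REGISTRY, paired_test
from gutclock.stacking import outer_cv_evaluate
from tests.conftest import clr_frame


@pytest.fixture
def mean_toy_learner():
    """A 'predict the mean of my training labels' learner, registered
    temporarily so the OOF bookkeeping can be checked by hand."""
    LEARNER_REGISTRY["MeanToy"] = lambda seed, params: DummyRegressor(strategy="mean")
    yield LearnerSpec("MeanToy")
    del LEARNER_REGISTRY["MeanToy"]


class TestStage1Oof:
    def test_fold_mean_oracle(self, mean_toy_learner):
        # 10 samples, k=2: each OOF value must equal the mean age of the
        # complementary fold, recomputed here by hand from the bookkeeping
        y = pd.Series(
            [20.0, 30, 40, 50, 60, 25, 35, 45, 55, 65],
            index=[f"s{i}" for i in range(10)],
        )
        X = pd.DataFrame({"x": np.arange(10.0)}, index=y.index)
        oof_train, oof_test, models = stage1_oof(
            [mean_toy_learner], X, y, X_test=X.iloc[:3], k=2, seed=0
        )
        folds = oof_train.fold_assignment
        for sid in y.index:
            other = y[folds != folds[sid]]
            assert oof_train.frame.loc[sid, "MeanToy"] == pytest.approx(other.mean())
        # predicted test set = mean of the two fold models' predictions
        expected = np.mean(
            [y[folds != f].mean() for f in sorted(folds.unique())]
        )
        np.testing.assert_allclose(oof_test.frame["MeanToy"], expected)

    def test_no_leakage_of_own_label(self):
        # perturbing sample i's label must not change the OOF entries of
        # i's own fold (their models were fit without i)
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(30, 3)))
        y = pd.Series(rng.uniform(20, 80, 30))
        spec = LearnerSpec("LR")
        base_train, _, _ = stage1_oof([spec], X, y, k=5, seed=1)
        folds = base_train.fold_assignment
        i = 7
        y2 = y.copy()
        y2.iloc[i] += 1000.0
        perturbed, _, _ = stage1_oof([spec], X, y2, k=5, seed=1)
        same_fold = folds[folds == folds.iloc[i]].index
        np.testing.assert_allclose(
            base_train.frame.loc[same_fold, "LR"],
            perturbed.frame.loc[same_fold, "LR"],
        )

    def test_default_k_is_five(self):
        import inspect

        assert inspect.signature(stage1_oof).parameters["k"].default == 5

    def test_shared_partition_across_learners(self, mean_toy_learner):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(20, 2)))
        y = pd.Series(rng.uniform(20, 80, 20))
        oof_train, _, _ = stage1_oof(
            [mean_toy_learner.with_seed(0), LearnerSpec("LR")], X, y, k=4, seed=3
        )
        assert oof_train.fold_assignment.nunique() == 4


class TestGeneralizer:
    def test_exact_linear_solution_recovered(self, rng):
        y = rng.uniform(20, 80, 50)
        oof = pd.DataFrame({"a": y, "b": rng.normal(size=50)})
        gen = fit_generalizer(oof, y, "LR")
        np.testing.assert_allclose(gen.predict(oof.to_numpy()), y, atol=1e-8)

    def test_simple_average_has_no_fit(self):
        assert fit_generalizer(pd.DataFrame({"a": [30.0], "b": [50.0]}), [40.0], "SA") is None

    def test_dt_generalizer_warns_about_overfitting(self, rng):
        oof = pd.DataFrame(rng.normal(size=(30, 2)))
        with pytest.warns(UserWarning, match="overfit"):
            fit_generalizer(oof, rng.uniform(20, 80, 30), "DT")

    def test_unknown_generalizer_rejected(self):
        with pytest.raises(ValueError, match="generalizer"):
            fit_generalizer(pd.DataFrame({"a": [1.0]}), [1.0], "RF")


@pytest.fixture(scope="module")
def trained_em2(small_views_module):
    clr_s, clr_p, y = small_views_module
    specs = [LearnerSpec(n) for n in ("Lasso", "LGB")]
    model = multiview_stack(
        {"species": clr_s, "pathway": clr_p}, y, specs=specs, seed=4, strategy="EM2"
    )
    return model, clr_s, clr_p, y


@pytest.fixture(scope="module")
def small_views_module():
    from gutclock import SyntheticConfig, generate_cohort

    cohort = generate_cohort(
        SyntheticConfig(
            n_samples=200,
            n_species=25,
            n_pathways=15,
            n_signal_features_per_view=5,
            confound_strength=0.0,
            signal_effect=0.03,
            seed=21,
        )
    )
    y = pd.Series(cohort.ages, index=cohort.metadata.sample_ids)
    return clr_frame(cohort.species_view), clr_frame(cohort.pathway_view), y


class TestPredictEnsemble:
    def test_simple_average_of_two_columns(self):
        # SA over OOF columns [30, 50] must give 40
        from gutclock.stacking import StackModel, ViewStack

        class Const:
            def __init__(self, v):
                self.v = v

            def predict(self, X):
                return np.full(len(X), self.v)

        specs = [LearnerSpec("LR"), LearnerSpec("Lasso")]
        vs = ViewStack(
            feature_ids=["f0"],
            specs=specs,
            fold_models={"LR": [Const(30.0)], "Lasso": [Const(50.0)]},
        )
        model = StackModel(
            views={"v": vs},
            generalizer_method="SA",
            generalizer=None,
            oof_columns=["v|LR", "v|Lasso"],
            stage1_k=1,
        )
        pred = predict_ensemble(model, pd.DataFrame({"f0": [0.0, 1.0]}))
        np.testing.assert_allclose(pred, 40.0)

    def test_deterministic_repeat_predictions(self, trained_em2):
        model, clr_s, clr_p, _ = trained_em2
        views = {"species": clr_s, "pathway": clr_p}
        a = predict_ensemble(model, views)
        b = predict_ensemble(model, views)
        pd.testing.assert_series_equal(a, b)

    def test_missing_required_view_rejected(self, trained_em2):
        model, clr_s, *_ = trained_em2
        with pytest.raises(ValueError, match="pathway"):
            predict_ensemble(model, {"species": clr_s})


class TestMultiviewStack:
    def test_partial_overlap_em2_completes(self, small_views_module):
        clr_s, clr_p, y = small_views_module
        partial = clr_p.iloc[: int(0.8 * len(clr_p))]  # view B for 80% of samples
        specs = [LearnerSpec("Lasso")]
        model = multiview_stack(
            {"species": clr_s, "pathway": partial}, y, specs=specs, seed=0
        )
        pred = predict_ensemble(model, {"species": clr_s, "pathway": partial})
        assert len(pred) == len(partial)

    def test_em1_empty_intersection_rejected(self, small_views_module):
        clr_s, clr_p, y = small_views_module
        disjoint = clr_p.copy()
        disjoint.index = [f"z{i}" for i in range(len(disjoint))]
        with pytest.raises(ValueError, match="intersection"):
            multiview_stack(
                {"species": clr_s, "pathway": disjoint},
                y,
                specs=[LearnerSpec("Lasso")],
                strategy="EM1",
            )

    def test_em1_vs_em2_not_significantly_different(self, small_views_module):
        clr_s, clr_p, y = small_views_module
        specs = [LearnerSpec(n) for n in ("Lasso", "LGB")]
        res = outer_cv_evaluate(
            {"species": clr_s, "pathway": clr_p},
            y,
            scheme=CvScheme(2, 5, 17),
            specs=specs,
            generalizers=("LR",),
            view_subsets=[("species", "pathway")],
            include_em1=True,
            seed=17,
        )
        p = paired_test(res["stack:LR:species+pathway"], res["stack:EM1:LR"])
        assert p > 0.05

    def test_duplicated_views_match_single_view_performance(self, small_views_module):
        clr_s, _, y = small_views_module
        specs = [LearnerSpec("Lasso")]
        res = outer_cv_evaluate(
            {"a": clr_s, "b": clr_s.copy().add_prefix("dup_")},
            y,
            scheme=CvScheme(2, 5, 3),
            specs=specs,
            generalizers=("LR",),
            view_subsets=[("a",), ("a", "b")],
            seed=3,
        )
        p = paired_test(res["stack:LR:a+b"], res["stack:LR:a"])
        assert p > 0.05  # duplicated signal adds nothing


def test_save_load_round_trip(trained_em2, tmp_path):
    model, clr_s, clr_p, _ = trained_em2
    save_model(model, tmp_path / "m")
    loaded = load_model(tmp_path / "m")
    views = {"species": clr_s, "pathway": clr_p}
    pd.testing.assert_series_equal(
        predict_ensemble(model, views), predict_ensemble(loaded, views)
    )
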