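import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from disnet.dataset_builder import LabeledDataset
from disnet.evaluation import (
    ablation_study,
    confusion_counts,
    cross_validate,
    roc_curve,
    sensitivity_at_zero,
    threshold_series,
)

from oracles import mann_whitney_auc


class TestRocCurve:
    def test_perfect_separation(self):
        r = roc_curve([2.0, 1.0, 0.0, -1.0], ["positive", "positive", "negative", "negative"])
        assert r.auc == 1.0

    def test_all_scores_tied_is_diagonal(self):
        r = roc_curve([0.5] * 6, ["positive"] * 3 + ["negative"] * 3)
        assert r.auc == 0.5
        assert len(r.points) == 2  # (0,0) and (1,1) only

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        r = roc_curve(rng.normal(size=60), rng.choice(["positive", "negative"], 60))
        assert tuple(r.points[0]) == (0.0, 0.0)
        assert tuple(r.points[-1]) == (1.0, 1.0)
        assert (np.diff(r.points[:, 0]) >= 0).all()
        assert (np.diff(r.points[:, 1]) >= 0).all()

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], ["positive", "positive"])

    @pytest.mark.parametrize("seed", range(20))
    def test_auc_equals_rank_statistic(self, seed):
        """Trapezoid AUC is the tie-corrected Mann-Whitney statistic."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 80))
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = rng.choice(["positive", "negative"], n)
        if len(set(labels)) < 2:
            labels[0] = "positive"
            labels[1] = "negative"
        assert math.isclose(
            roc_curve(scores, labels).auc, mann_whitney_auc(scores, labels), abs_tol=1e-12
        )

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=40)
        labels = rng.choice(["positive", "negative"], 40)
        if len(set(labels)) < 2:
            labels[0], labels[1] = "positive", "negative"
        base = roc_curve(scores, labels)
        warped = roc_curve(np.exp(3 * scores) + 7, labels)
        assert math.isclose(base.auc, warped.auc, abs_tol=1e-12)
        np.testing.assert_allclose(base.points, warped.points)


class TestConfusionCounts:
    def test_partition(self):
        c = confusion_counts([1.0, -1.0, 0.5, -0.2], ["positive", "positive", "negative", "negative"])
        assert c.total == 4
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)

    def test_zero_threshold_is_strict(self):
        c = confusion_counts([0.0], ["positive"])
        assert c.fn == 1  # score 0 is not > 0


def make_dataset(n=60, informative=True, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([1, -1] * (n // 2))
    x1 = y * informative + rng.normal(scale=1.0, size=n)
    X = pd.DataFrame(
        {"a": x1, "b": rng.normal(size=n)},
        index=pd.Index([f"P{i:03d}" for i in range(n)], name="protein"),
    )
    labels = pd.Series(np.where(y > 0, "positive", "negative"), index=X.index)
    return LabeledDataset(X, labels, k_min=1)


class TestCrossValidate:
    def test_folds_partition_instances(self):
        ds = make_dataset()
        cv = cross_validate(ds, folds=10, n_iterations=2, seed=0)
        assert len(cv) == 60
        assert sorted(cv.index) == sorted(ds.features.index)
        sizes = cv.groupby("fold").size()
        assert len(sizes) == 10 and sizes.min() >= 5

    def test_stratification_balances_classes(self):
        ds = make_dataset(n=20)
        cv = cross_validate(ds, folds=10, n_iterations=1, seed=1)
        per_fold = cv.groupby("fold")["label"].apply(lambda s: (s == "positive").sum())
        assert per_fold.between(0, 2).all()

    def test_same_seed_reproduces_scores(self):
        ds = make_dataset()
        cv1 = cross_validate(ds, folds=5, n_iterations=3, seed=7)
        cv2 = cross_validate(ds, folds=5, n_iterations=3, seed=7)
        pd.testing.assert_frame_equal(cv1, cv2)

    def test_too_few_class_members_suggests_fewer_folds(self):
        ds = make_dataset(n=10)
        with pytest.raises(ValueError, match="folds"):
            cross_validate(ds, folds=8)

    def test_null_scores_have_chance_auc(self):
        aucs = []
        for seed in range(10):
            ds = make_dataset(n=80, informative=False, seed=seed)
            cv = cross_validate(ds, folds=5, n_iterations=3, seed=seed)
            aucs.append(roc_curve(cv["score"], cv["label"]).auc)
        assert 0.4 < np.mean(aucs) < 0.6


class TestThresholdSeries:
    def test_tiny_scenario_runs_all_thresholds(self, tiny_scenario):
        table = threshold_series(
            tiny_scenario.net, tiny_scenario.annotation,
            k_values=(1, 2), folds=5, n_iterations=5, seed=0,
        )
        assert list(table["k_min"]) == [1, 2]
        assert table["n_pos"].iloc[0] > table["n_pos"].iloc[1]
        assert ((0 <= table["auc"]) & (table["auc"] <= 1)).all()


class TestAblation:
    def test_dropping_constant_feature_changes_nothing(self):
        ds = make_dataset(n=60, seed=3)
        ds.features["const"] = 1.0
        table = ablation_study(ds, features_to_drop=["const"], folds=5, n_iterations=3)
        row = table.set_index("dropped_feature").loc["const"]
        assert row["delta_sensitivity"] == 0.0
        assert row["delta_auc"] == 0.0

    def test_dropping_signal_feature_hurts(self):
        ds = make_dataset(n=100, seed=4)
        table = ablation_study(ds, features_to_drop=["a", "b"], folds=5, n_iterations=5)
        t = table.set_index("dropped_feature")
        assert t.loc["a", "delta_auc"] < t.loc["b", "delta_auc"]

    def test_dropping_everything_is_an_error(self):
        ds = make_dataset()
        with pytest.raises(ValueError):
            cross_validate(ds, folds=5, drop_features=["a", "b"])
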