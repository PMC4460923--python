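import json
import math

import numpy as np
import pandas as pd
import pytest

from disnet.adtree import (
    ADTreeModel,
    DecisionRule,
    deserialize_model,
    score,
    score_frame,
    serialize_model,
    train_adtree,
)

from oracles import exhaustive_best_split


def frame(values, name="x"):
    if isinstance(values, dict):
        return pd.DataFrame(values)
    return pd.DataFrame({name: values})


def toy_fixture(seed=0, n=8, n_features=1):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, n_features)),
        columns=[f"f{i}" for i in range(n_features)],
    )
    y = np.where(X.sum(axis=1) + rng.normal(scale=0.5, size=n) > 0, 1, -1)
    if len(set(y)) == 1:
        y[0] = -y[0]
    return X, y


class TestTraining:
    def test_zero_iterations_balanced(self):
        X = frame([1.0, 2.0, 3.0, 4.0])
        y = np.array([1, 1, -1, -1])
        model = train_adtree((X, y), n_iterations=0)
        assert model.root_value == 0.0
        assert model.rules == []
        assert score(model, {"x": 99.0}) == 0.0  # not > 0 -> negative class

    def test_root_value_closed_form(self):
        X = frame([1.0, 2.0, 3.0, 4.0])
        y = np.array([1, 1, 1, -1])
        model = train_adtree((X, y), n_iterations=0)
        assert math.isclose(model.root_value, 0.5 * math.log(3))

    def test_single_class_is_an_error(self):
        X = frame([1.0, 2.0])
        with pytest.raises(ValueError):
            train_adtree((X, np.array([1, 1])), n_iterations=1)

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("n_features", [1, 2])
    def test_each_iteration_matches_exhaustive_z_search(self, seed, n_features):
        """Chosen rule and prediction values equal the brute-force minimizer."""
        X, y = toy_fixture(seed=seed, n=12, n_features=n_features)
        n_iter = 3
        model = train_adtree((X, y), n_iterations=n_iter, epsilon=1.0)

        # replay training with the oracle
        w = np.ones(len(y), dtype=float)
        w = w * np.exp(-y * model.root_value)
        preconds = [np.ones(len(y), dtype=bool)]
        for rule in model.rules:
            z, attr, pi, thr, a_true, a_false = exhaustive_best_split(
                X, y, w, preconds, epsilon=1.0
            )
            assert rule.attribute == attr
            assert math.isclose(rule.threshold, thr, abs_tol=1e-12)
            assert math.isclose(rule.a_true, a_true, abs_tol=1e-12)
            assert math.isclose(rule.a_false, a_false, abs_tol=1e-12)
            mask = preconds[pi]
            ge = mask & (X[attr].to_numpy() >= thr)
            lt = mask & ~(X[attr].to_numpy() >= thr)
            w[ge] *= np.exp(-y[ge] * a_true)
            w[lt] *= np.exp(-y[lt] * a_false)
            preconds.extend([ge, lt])

    @pytest.mark.parametrize("seed", range(4))
    def test_total_weight_non_increasing(self, seed):
        X, y = toy_fixture(seed=seed, n=20, n_features=2)
        model = train_adtree((X, y), n_iterations=8)
        totals = model.weight_totals
        assert all(b <= a + 1e-9 for a, b in zip(totals, totals[1:]))

    def test_training_error_non_increasing_on_toy_fixture(self):
        X, y = toy_fixture(seed=1, n=16, n_features=2)
        errors = []
        for n_iter in range(0, 9, 2):
            model = train_adtree((X, y), n_iterations=n_iter)
            s = score_frame(model, X)
            errors.append(int(np.sum((s > 0) != (y > 0))))
        assert all(b <= a for a, b in zip(errors, errors[1:]))

    def test_label_flip_negates_scores(self):
        X, y = toy_fixture(seed=2, n=14, n_features=2)
        m_pos = train_adtree((X, y), n_iterations=4)
        m_neg = train_adtree((X, -y), n_iterations=4)
        np.testing.assert_allclose(
            score_frame(m_pos, X), -score_frame(m_neg, X), atol=1e-9
        )


class TestScoring:
    def one_rule_model(self):
        rule = DecisionRule(
            index=0, parent=-1, parent_branch=None,
            attribute="attr", threshold=2.0, a_true=0.4, a_false=-0.2,
        )
        return ADTreeModel(
            root_value=0.1, rules=[rule], feature_names=["attr"],
            n_iterations=1, epsilon=1.0,
        )

    def test_root_only_model(self):
        model = ADTreeModel(0.7, [], ["x"], 0, 1.0)
        assert score(model, {"x": -5}) == 0.7

    def test_threshold_boundary_goes_left(self):
        model = self.one_rule_model()
        assert math.isclose(score(model, {"attr": 2.0}), 0.5)  # >= goes left
        assert math.isclose(score(model, {"attr": 1.999}), -0.1)

    def test_missing_attribute_named(self):
        with pytest.raises(KeyError, match="attr"):
            score(self.one_rule_model(), {"other": 1.0})

    def test_score_equals_independent_path_walk(self):
        """Vectorized scoring agrees with a per-instance tree traversal."""
        X, y = toy_fixture(seed=3, n=40, n_features=3)
        model = train_adtree((X, y), n_iterations=20)

        def walk(x):
            total = model.root_value
            satisfied = {}
            for rule in model.rules:
                if rule.parent == -1:
                    pre = True
                else:
                    pre = satisfied[(rule.parent, rule.parent_branch)]
                branch = x[rule.attribute] >= rule.threshold
                if pre:
                    total += rule.a_true if branch else rule.a_false
                satisfied[(rule.index, True)] = pre and branch
                satisfied[(rule.index, False)] = pre and not branch
            return total

        fast = score_frame(model, X)
        slow = [walk(row) for _, row in X.iterrows()]
        np.testing.assert_allclose(fast, slow, atol=1e-12)


class TestSerialization:
    def test_root_only_round_trip(self):
        model = ADTreeModel(0.3, [], ["x"], 0, 1.0, [4.0, 3.8])
        assert deserialize_model(serialize_model(model)) == model

    def test_trained_model_round_trips_identically(self):
        X, y = toy_fixture(seed=4, n=30, n_features=2)
        model = train_adtree((X, y), n_iterations=20)
        back = deserialize_model(serialize_model(model))
        assert back == model
        assert serialize_model(back) == serialize_model(model)

    def test_dangling_precondition_rejected(self):
        X, y = toy_fixture(seed=5, n=12)
        model = train_adtree((X, y), n_iterations=2)
        doc = json.loads(serialize_model(model))
        doc["rules"][0]["parent"] = 7  # forward/dangling reference
        with pytest.raises(ValueError, match="dangling|order"):
            deserialize_model(doc)
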