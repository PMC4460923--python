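import math

import numpy as np
import pandas as pd
import pytest

from disnet.adtree import train_adtree
from disnet.consensus import (
    bootstrap_trees,
    build_consensus,
    conservation_bin,
    rule_conservation,
    rule_signature,
    stability_check,
)
from disnet.dataset_builder import LabeledDataset


def strong_dataset(n=80, seed=0):
    """One dominant feature so bootstrap trees agree on the first rule."""
    rng = np.random.default_rng(seed)
    y = np.array([1, -1] * (n // 2))
    X = pd.DataFrame(
        {
            "signal": y * 2.0 + rng.normal(scale=0.3, size=n),
            "noise": rng.normal(size=n),
        },
        index=pd.Index([f"P{i:03d}" for i in range(n)], name="protein"),
    )
    labels = pd.Series(np.where(y > 0, "positive", "negative"), index=X.index)
    return LabeledDataset(X, labels, k_min=1)


class TestConservationBinning:
    @pytest.mark.parametrize(
        "fraction,expected",
        [(1.0, ">=0.9"), (0.9, ">=0.9"), (0.75, ">=0.7"), (0.5, ">=0.5"),
         (0.31, ">=0.3"), (0.1, ">=0.1"), (0.05, "<0.1"), (0.0, "<0.1")],
    )
    def test_bands(self, fraction, expected):
        assert conservation_bin(fraction) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            conservation_bin(1.2)


class TestRuleConservation:
    def test_identical_ensemble_fully_conserved(self):
        ds = strong_dataset()
        ref = train_adtree(ds, n_iterations=4)
        tree = rule_conservation(ref, [ref] * 10, feature_iqr=ds.feature_iqr())
        assert all(r.conservation == 1.0 for r in tree.rules)
        assert all(r.bin == ">=0.9" for r in tree.rules)

    def test_absent_feature_zero_conservation(self):
        ds = strong_dataset()
        ref = train_adtree(ds, n_iterations=3)
        other = train_adtree(ds, n_iterations=0)  # root only, no rules at all
        tree = rule_conservation(ref, [other] * 5)
        assert all(r.conservation == 0.0 for r in tree.rules)
        assert all(r.bin == "<0.1" for r in tree.rules)

    def test_conservation_invariant_to_ensemble_order(self):
        ds = strong_dataset()
        ref = train_adtree(ds, n_iterations=3)
        ensemble = bootstrap_trees(ds, B=6, n_iterations=3, seed=1)
        t1 = rule_conservation(ref, ensemble, feature_iqr=ds.feature_iqr())
        t2 = rule_conservation(ref, ensemble[::-1], feature_iqr=ds.feature_iqr())
        assert [r.conservation for r in t1.rules] == [r.conservation for r in t2.rules]

    def test_threshold_tolerance_uses_iqr(self):
        ds = strong_dataset()
        ref = train_adtree(ds, n_iterations=1)
        rule = ref.rules[0]
        shifted = ref.__class__(
            root_value=ref.root_value,
            rules=[rule.__class__(**{**rule.__dict__, "threshold": rule.threshold + 100.0})],
            feature_names=ref.feature_names,
            n_iterations=1,
            epsilon=ref.epsilon,
        )
        iqr = ds.feature_iqr()
        strict = rule_conservation(ref, [shifted], threshold_tolerance=0.25, feature_iqr=iqr)
        assert strict.rules[0].conservation == 0.0
        loose = rule_conservation(ref, [shifted], feature_iqr=None)  # signature-only
        assert loose.rules[0].conservation == 1.0

    def test_binned_fractions_match_hand_count(self):
        """Conservation equals a manual match count over a 10-tree ensemble."""
        ds = strong_dataset()
        ref = train_adtree(ds, n_iterations=3)
        ensemble = bootstrap_trees(ds, B=10, n_iterations=3, seed=3)
        tree = rule_conservation(ref, ensemble, feature_iqr=ds.feature_iqr())
        iqr = ds.feature_iqr()
        for annotated in tree.rules:
            sig = rule_signature(ref, annotated.rule)
            tol = 0.25 * iqr[annotated.rule.attribute]
            hand = sum(
                any(
                    rule_signature(t, r) == sig
                    and abs(r.threshold - annotated.rule.threshold) <= tol
                    for r in t.rules
                )
                for t in ensemble
            )
            assert math.isclose(annotated.conservation, hand / 10)
            assert annotated.bin == conservation_bin(hand / 10)


class TestBootstrap:
    def test_requires_at_least_two(self):
        with pytest.raises(ValueError):
            bootstrap_trees(strong_dataset(), B=1)

    def test_deterministic_given_seed(self):
        ds = strong_dataset()
        a = bootstrap_trees(ds, B=3, n_iterations=2, seed=5)
        b = bootstrap_trees(ds, B=3, n_iterations=2, seed=5)
        assert [m.rules for m in a] == [m.rules for m in b]

    def test_root_values_reflect_resample_class_ratio(self):
        """root = 1/2 ln(n+*/n-*) for each resample's class counts."""
        ds = strong_dataset(n=60)
        X, y = ds.training_frame()
        n = len(y)
        streams = np.random.SeedSequence(9).spawn(20)
        models = bootstrap_trees(ds, B=20, n_iterations=0, seed=9)
        for b, model in enumerate(models):
            rng = np.random.default_rng(streams[b])
            idx = rng.integers(0, n, size=n)
            n_pos = int((y[idx] > 0).sum())
            assert math.isclose(
                model.root_value, 0.5 * math.log(n_pos / (n - n_pos)), abs_tol=1e-12
            )

    def test_strong_signal_dominates_first_rule(self):
        ds = strong_dataset(n=100)
        models = bootstrap_trees(ds, B=50, n_iterations=1, seed=2)
        picked = sum(m.rules[0].attribute == "signal" for m in models)
        assert picked >= 45  # >= 90% of trees


class TestStability:
    def test_degenerate_zero_removal_is_identity(self):
        ds = strong_dataset()
        report = stability_check(ds, fraction_removed=0.0, seed=0, n_iterations=3, B=5)
        assert report["jaccard"] == 1.0
        assert report["top2_unchanged"]

    def test_noise_data_smoke(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            rng.normal(size=(60, 3)), columns=list("abc"),
            index=pd.Index([f"P{i}" for i in range(60)], name="protein"),
        )
        labels = pd.Series(["positive", "negative"] * 30, index=X.index)
        ds = LabeledDataset(X, labels, k_min=1)
        report = stability_check(ds, fraction_removed=0.15, seed=1, n_iterations=2, B=4)
        assert 0.0 <= report["jaccard"] <= 1.0

    def test_strong_signal_top_rules_survive_removal(self):
        ds = strong_dataset(n=120)
        report = stability_check(ds, fraction_removed=0.15, seed=2, n_iterations=3, B=5)
        assert report["top2_unchanged"]
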