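"""Bootstrap rule-conservation analysis and the consensus tree.

Many ADTrees are trained on bootstrap resamples of the training data; each
rule of a reference tree (the one trained on the full data) is then
annotated with the fraction of bootstrap trees containing a *matching* rule.
Two rules match when they test the same attribute under the same
precondition context — the same sequence of (ancestor attribute, branch)
pairs from the root — and their thresholds differ by at most a tolerance
expressed as a fraction of the attribute's interquartile range.  Exact
thresholds are deliberately not part of rule identity: bootstrap resampling
jitters thresholds while leaving the rule structure intact.

Conservation fractions are binned into the color bands used when the tree is
rendered: >=0.9, >=0.7, >=0.5, >=0.3, >=0.1 and <0.1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .adtree import ADTreeModel, DecisionRule, train_adtree
from .dataset_builder import LabeledDataset

logger = logging.getLogger(__name__)

CONSERVATION_BINS = [
    (0.9, ">=0.9", "red"),
    (0.7, ">=0.7", "orange"),
    (0.5, ">=0.5", "yellow"),
    (0.3, ">=0.3", "green"),
    (0.1, ">=0.1", "blue"),
]


def conservation_bin(fraction: float) -> str:
    """Highest band whose lower bound does not exceed ``fraction``."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"conservation must be in [0, 1], got {fraction}")
    for bound, name, _ in CONSERVATION_BINS:
        if fraction >= bound:
            return name
    return "<0.1"


def _bin_color(name: str) -> str:
    for _, band, color in CONSERVATION_BINS:
        if band == name:
            return color
    return "black"


@dataclass(frozen=True)
class AnnotatedRule:
    rule: DecisionRule
    conservation: float
    bin: str


@dataclass
class ConsensusTree:
    root_value: float
    rules: list[AnnotatedRule]
    n_bootstrap: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "root_value": self.root_value,
                "n_bootstrap": self.n_bootstrap,
                "rules": [
                    {
                        "index": r.rule.index,
                        "parent": r.rule.parent,
                        "parent_branch": r.rule.parent_branch,
                        "attribute": r.rule.attribute,
                        "threshold": r.rule.threshold,
                        "a_true": r.rule.a_true,
                        "a_false": r.rule.a_false,
                        "conservation": r.conservation,
                        "bin": r.bin,
                    }
                    for r in self.rules
                ],
            },
            indent=2,
        )

    def to_dot(self) -> str:
        """Graphviz rendering with the conservation color legend."""
        lines = [
            "digraph consensus {",
            "  node [fontname=Helvetica];",
            f'  root [shape=ellipse, label="{self.root_value:+.3f}"];',
        ]
        for r in self.rules:
            color = _bin_color(r.bin)
            lines.append(
                f'  rule{r.rule.index} [shape=box, color={color}, '
                f'label="{r.rule.attribute} ({r.rule.index})\\n'
                f'conserved {r.conservation:.0%}"];'
            )
            lines.append(
                f'  pred{r.rule.index}T [shape=ellipse, label="{r.rule.a_true:+.3f}"];'
            )
            lines.append(
                f'  pred{r.rule.index}F [shape=ellipse, label="{r.rule.a_false:+.3f}"];'
            )
            parent = (
                "root"
                if r.rule.parent == -1
                else f"pred{r.rule.parent}{'T' if r.rule.parent_branch else 'F'}"
            )
            lines.append(f"  {parent} -> rule{r.rule.index};")
            lines.append(
                f'  rule{r.rule.index} -> pred{r.rule.index}T [label=">= {r.rule.threshold:.4g}"];'
            )
            lines.append(
                f'  rule{r.rule.index} -> pred{r.rule.index}F [label="< {r.rule.threshold:.4g}"];'
            )
        lines.append(
            '  legend [shape=note, label="conservation: red >=90%, orange >=70%, '
            'yellow >=50%, green >=30%, blue >=10%, black <10%"];'
        )
        lines.append("}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# rule identity
# ---------------------------------------------------------------------------

def rule_signature(model: ADTreeModel, rule: DecisionRule) -> tuple:
    """(attribute, ((ancestor attribute, branch), ...)) identity of a rule."""
    path: list[tuple[str, bool]] = []
    parent, branch = rule.parent, rule.parent_branch
    while parent != -1:
        ancestor = model.rules[parent]
        path.append((ancestor.attribute, bool(branch)))
        parent, branch = ancestor.parent, ancestor.parent_branch
    return rule.attribute, tuple(reversed(path))


def signature_set(model: ADTreeModel) -> set[tuple]:
    return {rule_signature(model, r) for r in model.rules}


# ---------------------------------------------------------------------------
# bootstrap ensemble
# ---------------------------------------------------------------------------

def bootstrap_trees(
    dataset: LabeledDataset,
    B: int = 100,
    n_iterations: int = 20,
    seed: int = 0,
    epsilon: float = 1.0,
) -> list[ADTreeModel]:
    """Train ``B`` ADTrees on size-n resamples drawn with replacement.

    Per-tree RNG streams are spawned deterministically from the master seed.
    A resample containing a single class is redrawn (at most 100 attempts).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    X, y = dataset.training_frame()
    n = len(y)
    streams = np.random.SeedSequence(seed).spawn(B)
    models = []
    for b in range(B):
        rng = np.random.default_rng(streams[b])
        for attempt in range(100):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
        else:
            raise RuntimeError(f"bootstrap resample {b}: single class after 100 attempts")
        models.append(
            train_adtree((X.iloc[idx], y[idx]), n_iterations=n_iterations, epsilon=epsilon)
        )
    return models


def rule_conservation(
    reference: ADTreeModel,
    ensemble: Sequence[ADTreeModel],
    threshold_tolerance: float = 0.25,
    feature_iqr: Mapping[str, float] | None = None,
) -> ConsensusTree:
    """Annotate each reference rule with its bootstrap conservation fraction.

    A reference rule is present in an ensemble tree iff some rule there has
    the same signature (attribute + precondition attribute path) and a
    threshold within ``threshold_tolerance * IQR(attribute)``.  With no
    ``feature_iqr`` the threshold check is skipped (signature-only matching).
    """
    if not ensemble:
        raise ValueError("ensemble must be non-empty")
    annotated = []
    for rule in reference.rules:
        sig = rule_signature(reference, rule)
        if feature_iqr is not None:
            tol = threshold_tolerance * float(feature_iqr[rule.attribute])
        else:
            tol = np.inf
        hits = 0
        for tree in ensemble:
            for other in tree.rules:
                if rule_signature(tree, other) == sig and abs(other.threshold - rule.threshold) <= tol:
                    hits += 1
                    break
        fraction = hits / len(ensemble)
        annotated.append(AnnotatedRule(rule, fraction, conservation_bin(fraction)))
    return ConsensusTree(
        root_value=reference.root_value,
        rules=annotated,
        n_bootstrap=len(ensemble),
    )


def build_consensus(
    dataset: LabeledDataset,
    B: int = 100,
    n_iterations: int = 20,
    seed: int = 0,
    threshold_tolerance: float = 0.25,
) -> tuple[ADTreeModel, ConsensusTree]:
    """Full-data reference tree plus its bootstrap conservation annotation."""
    reference = train_adtree(dataset, n_iterations=n_iterations)
    ensemble = bootstrap_trees(dataset, B=B, n_iterations=n_iterations, seed=seed)
    tree = rule_conservation(
        reference, ensemble,
        threshold_tolerance=threshold_tolerance,
        feature_iqr=dataset.feature_iqr(),
    )
    return reference, tree


# ---------------------------------------------------------------------------
# stability under data removal
# ---------------------------------------------------------------------------

def stability_check(
    dataset: LabeledDataset,
    fraction_removed: float = 0.15,
    seed: int = 0,
    n_iterations: int = 20,
    B: int = 20,
    threshold_tolerance: float = 0.25,
) -> dict:
    """Retrain after removing a random fraction of instances and compare.

    Reports the Jaccard similarity of the (attribute, path) rule-signature
    sets of the full-data and reduced-data trees, whether the first two rules
    agree, and per-rule conservation deltas for the signatures shared by both
    consensus trees.  ``fraction_removed`` may be 0 (degenerate, for tests).
    """
    if not 0.0 <= fraction_removed < 1.0:
        raise ValueError("fraction_removed must be in [0, 1)")
    rng = np.random.default_rng(seed)
    full_ref, full_cons = build_consensus(
        dataset, B=B, n_iterations=n_iterations, seed=seed,
        threshold_tolerance=threshold_tolerance,
    )

    proteins = np.array(dataset.features.index)
    n_keep = len(proteins) - int(round(fraction_removed * len(proteins)))
    keep = np.sort(rng.permutation(len(proteins))[:n_keep])
    reduced = dataset.subset(proteins[keep])
    red_ref, red_cons = build_consensus(
        reduced, B=B, n_iterations=n_iterations, seed=seed + 1,
        threshold_tolerance=threshold_tolerance,
    )

    sig_full = signature_set(full_ref)
    sig_red = signature_set(red_ref)
    union = sig_full | sig_red
    jaccard = len(sig_full & sig_red) / len(union) if union else 1.0

    def top_sigs(model, k=2):
        return [rule_signature(model, r) for r in model.rules[:k]]

    cons_full = {rule_signature(full_ref, r.rule): r.conservation for r in full_cons.rules}
    cons_red = {rule_signature(red_ref, r.rule): r.conservation for r in red_cons.rules}
    deltas = {
        str(sig): cons_red[sig] - cons_full[sig]
        for sig in sorted(set(cons_full) & set(cons_red))
    }

    return {
        "fraction_removed": fraction_removed,
        "jaccard": jaccard,
        "top2_unchanged": top_sigs(full_ref) == top_sigs(red_ref),
        "n_rules_full": len(full_ref.rules),
        "n_rules_reduced": len(red_ref.rules),
        "conservation_deltas": deltas,
    }
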