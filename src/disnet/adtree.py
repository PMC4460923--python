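"""Alternating decision tree (ADTree) with confidence-rated boosting.

An ADTree alternates *prediction* nodes (real-valued contributions) and
*decision* nodes (threshold tests of one attribute).  The classification
margin of an instance is the sum of the root prediction value and the
prediction values of every branch the instance reaches: a rule contributes
only when the instance satisfies the rule's precondition (the chain of
ancestor decisions on the path from the root), and then contributes its
``a_true`` value when ``attribute >= threshold`` (the left branch) or its
``a_false`` value otherwise.  An instance is classified positive when its
total score is strictly greater than 0; the magnitude of the score is the
confidence of the classification.

Training follows the boosting formulation: instances carry weights
``w_i`` (initially 1).  The root value is ``1/2 ln(W+/W-)``.  Each iteration
exhaustively scores every (precondition c, attribute, candidate threshold)
combination with the loss criterion

    Z = 2 * ( sqrt(W+(c & r) W-(c & r)) + sqrt(W+(c & !r) W-(c & !r)) ) + W(!c)

where ``r`` is the test ``attribute >= threshold`` and ``W+`` / ``W-`` are
total weights of positive / negative instances in the given region.  The
minimizing rule is added with smoothed branch prediction values
``a = 1/2 ln((W+ + eps) / (W- + eps))`` and instance weights are updated as
``w <- w * exp(-y * a)`` for instances inside ``c``.  Candidate thresholds
are the midpoints between consecutive distinct sorted attribute values among
the instances satisfying the precondition.  Because the smoothed ``a`` lies
between 0 and the unsmoothed minimizer, the total instance weight never
increases from one iteration to the next.

Ties between candidates with equal Z are broken deterministically: lowest
attribute name lexicographically, then precondition creation order, then
smallest threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_Z_TOLERANCE = 1e-12
MODEL_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class DecisionRule:
    """One decision node with its two prediction values.

    ``parent`` is the index of the rule owning the precondition (-1 for the
    root precondition, which every instance satisfies) and ``parent_branch``
    records which branch of the parent must have been taken (``True`` for the
    left, ``attribute >= threshold`` branch).
    """

    index: int
    parent: int
    parent_branch: bool | None
    attribute: str
    threshold: float
    a_true: float
    a_false: float


@dataclass
class ADTreeModel:
    root_value: float
    rules: list[DecisionRule]
    feature_names: list[str]
    n_iterations: int
    epsilon: float
    weight_totals: list[float] = field(default_factory=list)

    def used_attributes(self) -> list[str]:
        return sorted({r.attribute for r in self.rules})


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _training_arrays(dataset, drop_features=()):
    # accept a LabeledDataset or an (X, y) pair
    if hasattr(dataset, "training_frame"):
        X, y = dataset.training_frame(drop_features=drop_features)
    else:
        X, y = dataset
        y = np.asarray(y)
        if set(np.unique(y)) <= {0, 1}:
            y = np.where(y > 0, 1, -1)
    return X, np.asarray(y, dtype=float)


def train_adtree(
    dataset,
    n_iterations: int = 20,
    epsilon: float = 1.0,
    seed: int = 0,
) -> ADTreeModel:
    """Train an ADTree by exhaustive Z-minimization boosting.

    ``dataset`` is a :class:`~disnet.dataset_builder.LabeledDataset` or an
    ``(X, y)`` pair with ``X`` a DataFrame and ``y`` in {+1, -1}.  Training
    is fully deterministic; ``seed`` is accepted for interface uniformity.
    Raises on single-class input; ``n_iterations=0`` yields a root-only model.
    """
    del seed
    X, y = _training_arrays(dataset)
    if n_iterations < 0:
        raise ValueError("n_iterations must be >= 0")
    n = len(y)
    if n == 0 or (y > 0).all() or (y < 0).all():
        raise ValueError("training data must contain both classes")

    columns = list(X.columns)
    order_of = {name: j for j, name in enumerate(columns)}
    values = X.to_numpy(dtype=float)
    sort_orders = {j: np.argsort(values[:, j], kind="stable") for j in range(len(columns))}

    w = np.ones(n)
    weight_totals = [float(n)]
    w_pos = w[y > 0].sum()
    w_neg = w[y < 0].sum()
    root_value = 0.5 * float(np.log(w_pos / w_neg))
    w = w * np.exp(-y * root_value)
    weight_totals.append(float(w.sum()))

    # preconditions: (parent rule index, branch, boolean mask), creation order
    preconditions: list[tuple[int, bool | None, np.ndarray]] = [
        (-1, None, np.ones(n, dtype=bool))
    ]
    rules: list[DecisionRule] = []

    for _ in range(n_iterations):
        total_w = float(w.sum())
        best = None  # (Z, attr_name, precond_idx, threshold, stats)
        for attr in sorted(columns):
            j = order_of[attr]
            order = sort_orders[j]
            col_sorted = values[order, j]
            w_sorted = w[order]
            y_sorted = y[order]
            for pi, (_, _, mask) in enumerate(preconditions):
                m = mask[order]
                v = col_sorted[m]
                if v.size < 2:
                    continue
                cuts = np.nonzero(v[1:] > v[:-1])[0]
                if cuts.size == 0:
                    continue
                ww = w_sorted[m]
                yy = y_sorted[m]
                wp = np.where(yy > 0, ww, 0.0)
                wm = ww - wp
                cp = np.cumsum(wp)
                cm = np.cumsum(wm)
                tot_p, tot_m = cp[-1], cm[-1]
                w_outside = total_w - (tot_p + tot_m)
                wp_lt, wm_lt = cp[cuts], cm[cuts]
                wp_ge, wm_ge = tot_p - wp_lt, tot_m - wm_lt
                z = 2.0 * (np.sqrt(wp_ge * wm_ge) + np.sqrt(wp_lt * wm_lt)) + w_outside
                k = int(np.argmin(z))  # first minimum -> smallest threshold
                if best is None or z[k] < best[0] - _Z_TOLERANCE:
                    threshold = 0.5 * (v[cuts[k]] + v[cuts[k] + 1])
                    best = (
                        float(z[k]), attr, pi, float(threshold),
                        (wp_ge[k], wm_ge[k], wp_lt[k], wm_lt[k]),
                    )
        if best is None:
            logger.info("no admissible split left after %d rules; stopping early", len(rules))
            break

        _, attr, pi, threshold, (wp_ge, wm_ge, wp_lt, wm_lt) = best
        a_true = 0.5 * float(np.log((wp_ge + epsilon) / (wm_ge + epsilon)))
        a_false = 0.5 * float(np.log((wp_lt + epsilon) / (wm_lt + epsilon)))
        parent, parent_branch, mask = preconditions[pi]
        satisfied_ge = mask & (values[:, order_of[attr]] >= threshold)
        satisfied_lt = mask & ~(values[:, order_of[attr]] >= threshold)
        w[satisfied_ge] *= np.exp(-y[satisfied_ge] * a_true)
        w[satisfied_lt] *= np.exp(-y[satisfied_lt] * a_false)

        rule = DecisionRule(
            index=len(rules),
            parent=parent,
            parent_branch=parent_branch,
            attribute=attr,
            threshold=threshold,
            a_true=a_true,
            a_false=a_false,
        )
        rules.append(rule)
        preconditions.append((rule.index, True, satisfied_ge))
        preconditions.append((rule.index, False, satisfied_lt))
        weight_totals.append(float(w.sum()))

    return ADTreeModel(
        root_value=root_value,
        rules=rules,
        feature_names=columns,
        n_iterations=n_iterations,
        epsilon=epsilon,
        weight_totals=weight_totals,
    )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_frame(model: ADTreeModel, X: pd.DataFrame) -> np.ndarray:
    """Additive confidence score for every row of ``X``."""
    missing = [a for a in model.used_attributes() if a not in X.columns]
    if missing:
        raise KeyError(f"missing attribute(s): {', '.join(missing)}")
    n = len(X)
    scores = np.full(n, model.root_value)
    branch_masks: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for rule in model.rules:
        if rule.parent == -1:
            pre = np.ones(n, dtype=bool)
        else:
            left, right = branch_masks[rule.parent]
            pre = left if rule.parent_branch else right
        ge = X[rule.attribute].to_numpy(dtype=float) >= rule.threshold
        mask_true = pre & ge
        mask_false = pre & ~ge
        scores += np.where(mask_true, rule.a_true, 0.0)
        scores += np.where(mask_false, rule.a_false, 0.0)
        branch_masks[rule.index] = (mask_true, mask_false)
    return scores


def score(model: ADTreeModel, x: Mapping[str, float]) -> float:
    """Score a single instance given as a mapping attribute -> value."""
    for attr in model.used_attributes():
        if attr not in x:
            raise KeyError(f"missing attribute: {attr}")
    frame = pd.DataFrame([dict(x)])
    return float(score_frame(model, frame)[0])


def classify(model: ADTreeModel, x: Mapping[str, float]) -> str:
    return "positive" if score(model, x) > 0 else "negative"


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def serialize_model(model: ADTreeModel) -> str:
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "root_value": model.root_value,
        "n_iterations": model.n_iterations,
        "epsilon": model.epsilon,
        "feature_names": model.feature_names,
        "weight_totals": model.weight_totals,
        "rules": [asdict(r) for r in model.rules],
    }
    return json.dumps(doc, indent=2)


def deserialize_model(doc: str | dict) -> ADTreeModel:
    data = json.loads(doc) if isinstance(doc, str) else doc
    if data.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema: {data.get('schema_version')!r}")
    rules = []
    seen: set[int] = set()
    for i, raw in enumerate(data["rules"]):
        rule = DecisionRule(**raw)
        if rule.index != i:
            raise ValueError(f"rule index {rule.index} out of order (expected {i})")
        if rule.parent == -1:
            if rule.parent_branch is not None:
                raise ValueError(f"rule {i}: root precondition must have null branch")
        else:
            if rule.parent not in seen:
                raise ValueError(f"rule {i}: dangling precondition reference {rule.parent}")
            if not isinstance(rule.parent_branch, bool):
                raise ValueError(f"rule {i}: parent_branch must be boolean")
        if not np.isfinite(rule.threshold):
            raise ValueError(f"rule {i}: non-finite threshold")
        seen.add(rule.index)
        rules.append(rule)
    return ADTreeModel(
        root_value=float(data["root_value"]),
        rules=rules,
        feature_names=list(data["feature_names"]),
        n_iterations=int(data["n_iterations"]),
        epsilon=float(data["epsilon"]),
        weight_totals=[float(t) for t in data.get("weight_totals", [])],
    )


def save_model(model: ADTreeModel, path: str | Path) -> None:
    Path(path).write_text(serialize_model(model), encoding="utf-8")


def load_model(path: str | Path) -> ADTreeModel:
    return deserialize_model(Path(path).read_text(encoding="utf-8"))
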