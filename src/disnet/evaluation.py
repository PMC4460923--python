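"""Cross-validated ROC/AUC evaluation, threshold-series and ablation studies.

The ROC curve sweeps a decision threshold over the distinct classifier
scores in descending order.  At each threshold the false positive rate is
FPR = FP / (FP + TN) and the true positive rate is TPR = TP / (TP + FN);
tied scores are grouped so the curve has one point per distinct score, and
the AUC is the trapezoid integral of the resulting curve.  Sensitivity, used
by the ablation study, is the TPR of the hard classification rule
"score > 0".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .adtree import score_frame, train_adtree
from .dataset_builder import LabeledDataset, assign_labels
from .graph_model import DiseaseAnnotation
from .topology import build_feature_table, disease_neighbor_ratio

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else 0.0

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0


@dataclass(frozen=True)
class ROCResult:
    points: np.ndarray       # (m, 2) array of (FPR, TPR), from (0,0) to (1,1)
    thresholds: np.ndarray   # score threshold producing each interior point
    auc: float


def _as_signs(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        return np.where(arr == "positive", 1, -1)
    return np.where(arr.astype(float) > 0, 1, -1)


def confusion_counts(scores, labels, threshold: float = 0.0) -> ConfusionCounts:
    """Counts for the hard rule 'positive iff score > threshold'."""
    s = np.asarray(scores, dtype=float)
    y = _as_signs(labels)
    pred = s > threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (y > 0))),
        fp=int(np.sum(pred & (y < 0))),
        tn=int(np.sum(~pred & (y < 0))),
        fn=int(np.sum(~pred & (y > 0))),
    )


def sensitivity_at_zero(scores, labels) -> float:
    return confusion_counts(scores, labels, threshold=0.0).tpr


def roc_curve(scores, labels) -> ROCResult:
    """ROC points and trapezoid AUC over the descending distinct-score sweep."""
    s = np.asarray(scores, dtype=float)
    y = _as_signs(labels)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    n_pos = int(np.sum(y > 0))
    n_neg = int(np.sum(y < 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    pos_sorted = (y[order] > 0).astype(float)
    cum_tp = np.cumsum(pos_sorted)
    cum_fp = np.cumsum(1.0 - pos_sorted)
    # last index of each tied group of scores
    last = np.nonzero(np.diff(s_sorted, append=np.nan) != 0)[0]
    tpr = np.concatenate([[0.0], cum_tp[last] / n_pos])
    fpr = np.concatenate([[0.0], cum_fp[last] / n_neg])
    thresholds = s_sorted[last]
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(points=points, thresholds=thresholds, auc=auc)


def write_roc_tsv(result: ROCResult, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for line in header_lines:
            handle.write(f"# {line}\n")
        handle.write("threshold\tfpr\ttpr\n")
        handle.write(f"\t{result.points[0, 0]:.6g}\t{result.points[0, 1]:.6g}\n")
        for t, (f, tp) in zip(result.thresholds, result.points[1:]):
            handle.write(f"{t:.10g}\t{f:.6g}\t{tp:.6g}\n")


def load_scores_tsv(path: str | Path) -> pd.DataFrame:
    """Read an external score file: columns ``protein``, ``score`` [, ``label``]."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    if "protein" not in frame.columns or "score" not in frame.columns:
        raise ValueError(f"{path}: expected at least columns 'protein' and 'score'")
    return frame.set_index("protein")


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def cross_validate(
    dataset: LabeledDataset,
    folds: int = 10,
    n_iterations: int = 20,
    seed: int = 0,
    epsilon: float = 1.0,
    drop_features: Iterable[str] = (),
    strict_dnr: bool = False,
    net: nx.Graph | None = None,
    annotation: DiseaseAnnotation | None = None,
) -> pd.DataFrame:
    """Out-of-fold ADTree scores via stratified K-fold cross-validation.

    Every non-excluded instance is scored exactly once by a model that did
    not train on it.  With ``strict_dnr=True`` (requires ``net`` and
    ``annotation``) the DNR column is recomputed per fold from the annotation
    restricted to training-fold proteins, so no label information about the
    held-out proteins reaches the feature.  Returns a DataFrame indexed by
    protein with columns ``score``, ``label`` and ``fold``.
    """
    X, y = dataset.training_frame(drop_features=drop_features)
    class_sizes = [int(np.sum(y > 0)), int(np.sum(y < 0))]
    if min(class_sizes) < folds:
        raise ValueError(
            f"smallest class has {min(class_sizes)} members; "
            f"use at most {min(class_sizes)} folds"
        )
    if strict_dnr and (net is None or annotation is None):
        raise ValueError("strict_dnr requires net and annotation")

    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.zeros(len(y))
    fold_of = np.zeros(len(y), dtype=int)
    for fold, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        X_fold = X
        if strict_dnr and "dnr" in X.columns:
            train_proteins = set(X.index[train_idx])
            disease = annotation.disease_genes() & train_proteins
            dnr = disease_neighbor_ratio(net, disease)
            X_fold = X.copy()
            X_fold["dnr"] = [dnr.get(p, 0.0) for p in X.index]
        model = train_adtree(
            (X_fold.iloc[train_idx], y[train_idx]),
            n_iterations=n_iterations,
            epsilon=epsilon,
            seed=seed * 1000 + fold,
        )
        scores[test_idx] = score_frame(model, X_fold.iloc[test_idx])
        fold_of[test_idx] = fold
    return pd.DataFrame(
        {
            "score": scores,
            "label": np.where(y > 0, "positive", "negative"),
            "fold": fold_of,
        },
        index=X.index,
    )


def cross_validated_auc(dataset: LabeledDataset, **kwargs) -> float:
    cv = cross_validate(dataset, **kwargs)
    return roc_curve(cv["score"], cv["label"]).auc


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def threshold_series(
    net: nx.Graph,
    annotation: DiseaseAnnotation,
    k_values: Sequence[int] = (1, 2, 3, 4, 5),
    folds: int = 10,
    n_iterations: int = 20,
    seed: int = 0,
    features: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cross-validated AUC for each minimum-disease threshold.

    The feature table is computed once (pass ``features`` to reuse one already
    computed) and relabeled at each threshold; pipeline settings are identical
    across thresholds.
    """
    if features is None:
        features = build_feature_table(net, annotation)
    rows = []
    for k in k_values:
        dataset = assign_labels(features, annotation, k_min=k)
        auc = cross_validated_auc(dataset, folds=folds, n_iterations=n_iterations, seed=seed)
        rows.append((k, auc, dataset.n_pos, dataset.n_neg, dataset.n_excluded))
        logger.info("threshold k_min=%d: AUC=%.4f (pos=%d neg=%d)", k, auc, *rows[-1][2:4])
    return pd.DataFrame(rows, columns=["k_min", "auc", "n_pos", "n_neg", "n_excluded"])


def ablation_study(
    dataset: LabeledDataset,
    features_to_drop: Sequence[str] | None = None,
    folds: int = 10,
    n_iterations: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Single-feature removal deltas against the all-features baseline.

    For every feature, the classifier is retrained and re-evaluated without
    it; the table reports the change in sensitivity (TPR at score threshold
    0) and AUC relative to the baseline.  Negative deltas mean the removal
    hurt.
    """
    names = dataset.feature_names
    if features_to_drop is None:
        features_to_drop = names
    unknown = [f for f in features_to_drop if f not in names]
    if unknown:
        raise KeyError(f"unknown features: {unknown}")

    base = cross_validate(dataset, folds=folds, n_iterations=n_iterations, seed=seed)
    base_auc = roc_curve(base["score"], base["label"]).auc
    base_sens = sensitivity_at_zero(base["score"], base["label"])

    rows = []
    for feature in features_to_drop:
        cv = cross_validate(
            dataset, folds=folds, n_iterations=n_iterations, seed=seed,
            drop_features=[feature],
        )
        auc = roc_curve(cv["score"], cv["label"]).auc
        sens = sensitivity_at_zero(cv["score"], cv["label"])
        rows.append((feature, sens - base_sens, auc - base_auc, sens, auc))
    table = pd.DataFrame(
        rows,
        columns=["dropped_feature", "delta_sensitivity", "delta_auc", "sensitivity", "auc"],
    )
    table.attrs["baseline_auc"] = base_auc
    table.attrs["baseline_sensitivity"] = base_sens
    return table
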