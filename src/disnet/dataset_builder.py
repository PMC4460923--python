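"""Labeled dataset construction and greedy correlation-based feature selection.

A protein is *positive* when it is annotated to at least ``k_min`` distinct
diseases, *negative* when it has no disease annotation at all, and *excluded*
(dropped from training, not relabeled) when its disease count is positive but
below the threshold — raising the threshold removes weak positives and leaves
the negative class untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .graph_model import DiseaseAnnotation
from .topology import FEATURE_COLUMNS, build_feature_table

logger = logging.getLogger(__name__)


@dataclass
class LabeledDataset:
    """Per-protein feature matrix plus positive/negative/excluded labels."""

    features: pd.DataFrame          # index: protein, columns: feature names
    labels: pd.Series               # 'positive' / 'negative' / 'excluded'
    k_min: int

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.labels.index):
            raise ValueError("features and labels must share one protein index")

    @property
    def n_pos(self) -> int:
        return int((self.labels == "positive").sum())

    @property
    def n_neg(self) -> int:
        return int((self.labels == "negative").sum())

    @property
    def n_excluded(self) -> int:
        return int((self.labels == "excluded").sum())

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def counts(self) -> dict[str, int]:
        return {
            "k_min": self.k_min,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "n_excluded": self.n_excluded,
            "n_total": len(self.labels),
        }

    def training_frame(
        self, drop_features: Iterable[str] = ()
    ) -> tuple[pd.DataFrame, np.ndarray]:
        """Feature matrix and +/-1 labels with excluded rows removed."""
        drop = list(drop_features)
        keep = self.labels != "excluded"
        X = self.features.loc[keep]
        if drop:
            missing = [f for f in drop if f not in X.columns]
            if missing:
                raise KeyError(f"unknown features: {missing}")
            if len(drop) >= len(X.columns):
                raise ValueError("cannot drop every feature")
            X = X.drop(columns=drop)
        y = np.where(self.labels.loc[keep] == "positive", 1, -1)
        return X, y

    def feature_iqr(self) -> pd.Series:
        q = self.features.quantile([0.25, 0.75])
        return q.loc[0.75] - q.loc[0.25]

    def subset(self, proteins: Sequence) -> "LabeledDataset":
        return LabeledDataset(
            self.features.loc[proteins], self.labels.loc[proteins], self.k_min
        )


def assign_labels(
    features: pd.DataFrame, annotation: DiseaseAnnotation, k_min: int
) -> LabeledDataset:
    """Label a feature table; only network proteins (table rows) are considered."""
    if k_min < 1:
        raise ValueError(f"k_min must be >= 1, got {k_min}")
    cols = [c for c in features.columns if c != "label"]
    counts = np.array([annotation.disease_count(p) for p in features.index])
    labels = pd.Series(
        np.where(counts >= k_min, "positive", np.where(counts == 0, "negative", "excluded")),
        index=features.index,
        name="label",
    )
    dataset = LabeledDataset(features[cols], labels, k_min)
    logger.info("labeled dataset (k_min=%d): %s", k_min, dataset.counts())
    return dataset


def build_dataset(
    net: nx.Graph, annotation: DiseaseAnnotation, k_min: int = 1
) -> LabeledDataset:
    """Convenience wrapper: compute the feature table, then label it."""
    table = build_feature_table(net, annotation, k_min=k_min)
    return assign_labels(table[FEATURE_COLUMNS], annotation, k_min)


# ---------------------------------------------------------------------------
# greedy correlation-based feature selection
# ---------------------------------------------------------------------------

def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize into at most ``n_bins`` equal-frequency bins (codes)."""
    if np.all(x == x[0]):
        return np.zeros(len(x), dtype=int)
    codes = pd.qcut(x, q=n_bins, labels=False, duplicates="drop")
    # a single surviving bin edge (heavily tied data) can yield all-NaN codes
    return np.nan_to_num(np.asarray(codes, dtype=float), nan=0.0).astype(int)


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def symmetric_uncertainty(a: np.ndarray, b: np.ndarray) -> float:
    """SU(A, B) = 2 I(A;B) / (H(A) + H(B)) on discretized vectors; 0 if degenerate."""
    joint = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy().astype(float)
    ha = _entropy(joint.sum(axis=1))
    hb = _entropy(joint.sum(axis=0))
    if ha + hb == 0:
        return 0.0
    hab = _entropy(joint.ravel())
    mi = ha + hb - hab
    return max(0.0, 2.0 * mi / (ha + hb))


def greedy_feature_selection(
    dataset: LabeledDataset, n_bins: int = 10
) -> list[str]:
    """Forward stepwise selection under a correlation-based subset merit.

    Merit(S) = k * mean SU(feature, class) / sqrt(k + k(k-1) * mean SU(f, f'))
    with features discretized into equal-frequency bins.  Features are
    returned in order of selection; once no candidate improves the merit, the
    remaining features are appended ranked by the merit they would achieve if
    added next (ties broken lexicographically).  Constant features contribute
    merit 0.
    """
    if len(dataset.feature_names) < 2:
        raise ValueError("need at least two features")
    X, y = dataset.training_frame()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    names = sorted(X.columns)
    binned = {f: _equal_frequency_bins(X[f].to_numpy(float), n_bins) for f in names}
    ycode = (y > 0).astype(int)

    su_fc = {f: symmetric_uncertainty(binned[f], ycode) for f in names}
    su_ff: dict[tuple[str, str], float] = {}

    def pair_su(f: str, g: str) -> float:
        key = (f, g) if f < g else (g, f)
        if key not in su_ff:
            su_ff[key] = symmetric_uncertainty(binned[f], binned[g])
        return su_ff[key]

    def merit(subset: list[str]) -> float:
        k = len(subset)
        if k == 0:
            return 0.0
        rcf = np.mean([su_fc[f] for f in subset])
        if k == 1:
            return float(rcf)
        rff = np.mean([pair_su(f, g) for i, f in enumerate(subset) for g in subset[i + 1:]])
        return float(k * rcf / np.sqrt(k + k * (k - 1) * rff))

    selected: list[str] = []
    current = 0.0
    remaining = list(names)
    while remaining:
        scored = sorted(
            ((merit(selected + [f]), f) for f in remaining),
            key=lambda t: (-t[0], t[1]),
        )
        best_merit, best_feature = scored[0]
        if best_merit <= current + 1e-12:
            break
        selected.append(best_feature)
        remaining.remove(best_feature)
        current = best_merit

    tail = sorted(remaining, key=lambda f: (-merit(selected + [f]), f))
    return selected + tail
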