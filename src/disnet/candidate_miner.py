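"""Mining high-confidence false positives as candidate disease proteins.

Negative-class proteins that the classifier nonetheless scores above a
confidence cutoff share network characteristics with known disease proteins
and are treated as candidate novel disease genes.  For each candidate the
disease annotations of its first-order neighbors (direct interaction
partners) and second-order neighbors (nodes at shortest-path distance
exactly 2 — direct neighbors and the protein itself are excluded to avoid
double counting) are profiled: a neighbor annotated to a disease counts once
per protein, regardless of how many supporting PMIDs it carries.
"""

from __future__ import annotations

import logging
from typing import Sequence

import networkx as nx
import pandas as pd

from .graph_model import DiseaseAnnotation

logger = logging.getLogger(__name__)


def rank_false_positives(
    scores: pd.Series,
    labels: pd.Series,
    min_confidence: float = 0.5,
    score_mode: str = "full-model",
) -> pd.DataFrame:
    """Negative-class proteins with confidence score >= ``min_confidence``.

    ``scores`` and ``labels`` are aligned series indexed by protein; labels
    are 'positive'/'negative'.  The result is sorted by confidence descending
    (ties broken lexicographically by protein id) with a 1-based ``rank``
    column; the scoring mode (full-model resubstitution vs out-of-fold) is
    recorded in ``attrs``.  An empty report is allowed.  The cutoff applies
    to the raw additive margin: rescaling scores requires rescaling the
    cutoff.
    """
    aligned = pd.DataFrame({"confidence": scores, "label": labels}).dropna()
    hits = aligned[(aligned["label"] == "negative") & (aligned["confidence"] >= min_confidence)]
    hits = hits.reset_index(names="protein")
    hits = hits.sort_values(
        by=["confidence", "protein"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    report = hits[["protein", "confidence"]].copy()
    report["rank"] = range(1, len(report) + 1)
    report.attrs["score_mode"] = score_mode
    report.attrs["min_confidence"] = min_confidence
    return report


def neighbor_disease_distribution(
    net: nx.Graph,
    annotation: DiseaseAnnotation,
    protein: str,
    order: int = 1,
    top_n: int = 5,
) -> list[tuple[str, str, int]]:
    """Top diseases among a protein's first- or second-order neighbors.

    Order 1 considers direct interaction partners; order 2 considers nodes at
    shortest-path distance exactly 2.  Counts are per neighbor protein; the
    ``top_n`` diseases are returned sorted by count descending, ties by
    disease id.
    """
    if protein not in net:
        raise KeyError(f"unknown protein: {protein}")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    direct = set(net.neighbors(protein))
    if order == 1:
        neighborhood = direct
    else:
        second = set()
        for nbr in direct:
            second.update(net.neighbors(nbr))
        neighborhood = second - direct - {protein}

    names = annotation.all_diseases()
    counts: dict[str, int] = {}
    for node in neighborhood:
        for disease_id in annotation.disease_ids(node):
            counts[disease_id] = counts.get(disease_id, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    return [(did, names.get(did, ""), count) for did, count in ranked]


def candidate_dossier(
    report: pd.DataFrame,
    net: nx.Graph,
    annotation: DiseaseAnnotation,
    top_k: int = 15,
    features: pd.DataFrame | None = None,
    top_n_diseases: int = 5,
) -> str:
    """Markdown dossier for the ``top_k`` highest-confidence candidates.

    Each block lists the candidate's confidence score, degree and DNR (when a
    feature table is supplied) and the top diseases of its first- and
    second-order neighborhoods.  Output is deterministic for identical
    inputs.
    """
    if report.empty:
        raise ValueError("candidate report is empty")
    blocks = [
        "# Candidate disease proteins",
        "",
        f"Score mode: {report.attrs.get('score_mode', 'unknown')}; "
        f"confidence cutoff: {report.attrs.get('min_confidence', 'n/a')}; "
        f"{len(report)} candidates, showing top {min(top_k, len(report))}.",
    ]
    for _, row in report.head(top_k).iterrows():
        protein = row["protein"]
        blocks.append("")
        blocks.append(f"## {row['rank']}. {protein} (confidence {row['confidence']:.4f})")
        if features is not None and protein in features.index:
            blocks.append(
                f"- degree: {features.loc[protein, 'degree']:.0f}, "
                f"DNR: {features.loc[protein, 'dnr']:.3f}"
            )
        for order, title in ((1, "First-order"), (2, "Second-order")):
            dist = neighbor_disease_distribution(
                net, annotation, protein, order=order, top_n=top_n_diseases
            )
            blocks.append(f"- {title} neighbor diseases:")
            if not dist:
                blocks.append("  - (none annotated)")
            for did, name, count in dist:
                label = f"{did} {name}".strip()
                blocks.append(f"  - {label}: {count} neighbors")
    blocks.append("")
    return "\n".join(blocks)
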