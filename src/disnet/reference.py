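"""Validation of externally supplied network/annotation files.

Users running the pipeline on a real interactome (e.g. a curated human PPI
release plus a Disease Ontology-based gene annotation, which are
registration-gated downloads and are not shipped here) can check their
parsed inputs against the summary statistics published for those releases
before trusting downstream results.
"""

from __future__ import annotations

from pathlib import Path

from .graph_model import network_summary, read_annotations, read_edge_list

#: Published summary statistics of the human PPI + disease-annotation release
#: the pipeline was designed around (HPRD Release 9 with DORIF annotation).
HPRD_DORIF_EXPECTED = {
    "node_count": 9616,
    "edge_count": 39240,
    "mean_neighbor_count": 7.7,
    "diameter": 14,
    "characteristic_path_length": 4.2,
    "annotation_gene_count": 5376,
    "positive_fraction": 0.32,
    "mean_diseases_per_positive": 4.3,
}


def summarize_inputs(edges_path: str | Path, annotations_path: str | Path) -> dict:
    """Parse an edge list + annotation file and compute their joint summary."""
    net = read_edge_list(edges_path)
    annotation = read_annotations(annotations_path)
    summary = network_summary(net)
    annotated_in_net = annotation.disease_genes() & set(net.nodes())
    pair_count = sum(annotation.disease_count(g) for g in annotated_in_net)
    return {
        "node_count": summary.node_count,
        "edge_count": summary.edge_count,
        "mean_neighbor_count": summary.mean_neighbor_count,
        "diameter": summary.diameter,
        "characteristic_path_length": summary.characteristic_path_length,
        "annotation_gene_count": len(annotation),
        "positive_fraction": len(annotated_in_net) / summary.node_count,
        "mean_diseases_per_positive": (
            pair_count / len(annotated_in_net) if annotated_in_net else 0.0
        ),
    }


def compare_statistics(
    observed: dict, expected: dict | None = None, rtol: float = 0.05
) -> dict[str, dict]:
    """Compare observed summary statistics against published values.

    Returns per-statistic records with the observed and expected values, the
    relative difference, and whether it falls within ``rtol``.  Statistics
    missing from ``observed`` are reported as unchecked.
    """
    if expected is None:
        expected = HPRD_DORIF_EXPECTED
    report: dict[str, dict] = {}
    for key, exp in expected.items():
        if key not in observed:
            report[key] = {"expected": exp, "observed": None, "within": None}
            continue
        obs = observed[key]
        rel = abs(obs - exp) / abs(exp) if exp else abs(obs)
        report[key] = {
            "expected": exp,
            "observed": obs,
            "relative_difference": rel,
            "within": bool(rel <= rtol),
        }
    return report
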