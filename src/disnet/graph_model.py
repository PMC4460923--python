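"""Protein-protein interaction network and disease annotation handling.

The interaction network is held as an undirected simple :class:`networkx.Graph`
whose nodes are gene symbols (case-preserved, whitespace-trimmed strings).
Self-loops and duplicate edges are dropped at parse time; the counts of both
are logged so that the simplification is auditable.

Disease annotations map a gene symbol to a set of disease records
(``disease_id``, ``disease_name``, supporting PMIDs).  A gene is annotated to
a disease at most once; PMID sets merge when the same (gene, disease) pair
appears on several input rows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised when an input file violates the expected tabular layout."""


# ---------------------------------------------------------------------------
# interaction network
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, self_loop_policy: str = "drop") -> nx.Graph:
    """Read a two-column tab-separated edge list into a simple graph.

    Lines starting with ``#`` are comments.  Self-loops are dropped (the node
    is kept) and duplicate edges are collapsed.  A malformed line (fewer than
    two non-empty tab-separated identifiers) raises :class:`ParseError` naming
    the line number, and an empty file is an error.
    """
    if self_loop_policy != "drop":
        raise ValueError(f"unsupported self_loop_policy: {self_loop_policy!r}")
    path = Path(path)
    graph: nx.Graph = nx.Graph()
    n_lines = n_self = n_dup = 0
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ParseError(
                    f"{path}:{lineno}: expected two tab-separated identifiers, "
                    f"got {raw.rstrip()!r}"
                )
            a, b = parts[0], parts[1]
            n_lines += 1
            if a == b:
                n_self += 1
                graph.add_node(a)
                continue
            if graph.has_edge(a, b):
                n_dup += 1
                continue
            graph.add_edge(a, b)
    if n_lines == 0:
        raise ParseError(f"{path}: no interactions found")
    logger.info(
        "read %d interaction lines from %s: %d nodes, %d edges "
        "(dropped %d self-loops, %d duplicate edges)",
        n_lines, path, graph.number_of_nodes(), graph.number_of_edges(),
        n_self, n_dup,
    )
    return graph


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    """Write the network as a two-column TSV (round-trips with the reader)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("# gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in net.edges()):
            handle.write(f"{a}\t{b}\n")
        for node in sorted(net.nodes()):
            if net.degree(node) == 0:
                handle.write(f"{node}\t{node}\n")  # re-read as isolated node


# ---------------------------------------------------------------------------
# disease annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiseaseRecord:
    disease_id: str
    disease_name: str
    pmids: frozenset[str]


class DiseaseAnnotation:
    """Mapping gene symbol -> set of disease records."""

    def __init__(self) -> None:
        # gene -> disease_id -> (disease_name, pmid set)
        self._genes: dict[str, dict[str, tuple[str, set[str]]]] = {}

    def add(
        self,
        gene: str,
        disease_id: str,
        disease_name: str = "",
        pmids: Iterable[str] = (),
    ) -> None:
        entry = self._genes.setdefault(gene, {})
        if disease_id in entry:
            name, pmid_set = entry[disease_id]
            pmid_set.update(pmids)
            if not name and disease_name:
                entry[disease_id] = (disease_name, pmid_set)
        else:
            entry[disease_id] = (disease_name, set(pmids))

    # -- queries ------------------------------------------------------------

    def genes(self) -> set[str]:
        return set(self._genes)

    def disease_count(self, gene: str) -> int:
        return len(self._genes.get(gene, {}))

    def diseases(self, gene: str) -> list[DiseaseRecord]:
        return [
            DiseaseRecord(did, name, frozenset(pmids))
            for did, (name, pmids) in sorted(self._genes.get(gene, {}).items())
        ]

    def disease_ids(self, gene: str) -> set[str]:
        return set(self._genes.get(gene, {}))

    def disease_genes(self, min_count: int = 1) -> set[str]:
        """Genes annotated to at least ``min_count`` distinct diseases."""
        return {g for g, d in self._genes.items() if len(d) >= min_count}

    def all_diseases(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for entry in self._genes.values():
            for did, (name, _) in entry.items():
                out.setdefault(did, name)
        return out

    def n_pairs(self) -> int:
        """Number of distinct (gene, disease) pairs."""
        return sum(len(d) for d in self._genes.values())

    def remove_gene(self, gene: str) -> None:
        self._genes.pop(gene, None)

    def copy(self) -> "DiseaseAnnotation":
        clone = DiseaseAnnotation()
        for gene, entry in self._genes.items():
            for did, (name, pmids) in entry.items():
                clone.add(gene, did, name, pmids)
        return clone

    def __contains__(self, gene: str) -> bool:
        return gene in self._genes

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._genes))


def read_annotations(path: str | Path) -> DiseaseAnnotation:
    """Read a 4-column TSV: gene, disease_id, disease_name, pmids (';'-sep).

    The pmids column is optional.  Genes absent from any network are retained;
    intersection with the network happens when datasets are built.
    """
    path = Path(path)
    annotation = DiseaseAnnotation()
    n_rows = 0
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) < 3 or not parts[0] or not parts[1]:
                raise ParseError(
                    f"{path}:{lineno}: expected columns gene, disease_id, "
                    f"disease_name[, pmids], got {line!r}"
                )
            pmids = [p for p in parts[3].split(";")] if len(parts) > 3 and parts[3] else []
            annotation.add(parts[0], parts[1], parts[2], [p for p in pmids if p])
            n_rows += 1
    if n_rows == 0:
        raise ParseError(f"{path}: no annotation rows found")
    logger.info(
        "read %d annotation rows from %s: %d genes, %d distinct gene-disease pairs",
        n_rows, path, len(annotation), annotation.n_pairs(),
    )
    return annotation


def write_annotations(annotation: DiseaseAnnotation, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("# gene\tdisease_id\tdisease_name\tpmids\n")
        for gene in annotation:
            for rec in annotation.diseases(gene):
                pmids = ";".join(sorted(rec.pmids))
                handle.write(f"{gene}\t{rec.disease_id}\t{rec.disease_name}\t{pmids}\n")


# ---------------------------------------------------------------------------
# global network statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkSummary:
    node_count: int
    edge_count: int
    mean_neighbor_count: float
    diameter: int
    characteristic_path_length: float
    component_count: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def network_summary(net: nx.Graph) -> NetworkSummary:
    """Global statistics of the (possibly disconnected) network.

    The diameter is the maximum eccentricity over the largest connected
    component; the characteristic path length is the mean shortest-path
    distance over all connected ordered pairs across the whole graph.  An
    edgeless graph reports both as 0 with a warning.
    """
    if net.number_of_nodes() < 1:
        raise ValueError("network must contain at least one node")
    n = net.number_of_nodes()
    e = net.number_of_edges()
    components = list(nx.connected_components(net))
    if e == 0:
        logger.warning("network has no edges; diameter and path length undefined, reporting 0")
        return NetworkSummary(n, 0, 0.0, 0, 0.0, len(components))

    from .topology import distance_matrix  # local import; topology is standalone

    nodes, dist = distance_matrix(net)
    finite = np.isfinite(dist) & (dist > 0)
    cpl = float(dist[finite].mean()) if finite.any() else 0.0

    largest = max(components, key=len)
    idx = [i for i, node in enumerate(nodes) if node in largest]
    sub = dist[np.ix_(idx, idx)]
    diameter = int(sub[np.isfinite(sub)].max()) if len(idx) > 1 else 0

    return NetworkSummary(
        node_count=n,
        edge_count=e,
        mean_neighbor_count=2.0 * e / n,
        diameter=diameter,
        characteristic_path_length=cpl,
        component_count=len(components),
    )
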