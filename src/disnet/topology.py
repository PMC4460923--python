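"""Per-protein topological features and the disease neighbor ratio (DNR).

Ten features are computed for every protein in the interaction network:

========================  ==================================================
degree                    number of interaction partners
closeness                 1 / mean shortest-path distance to reachable nodes
betweenness               Brandes pair-dependency sum, unnormalized, each
                          unordered (s, t) pair counted once
stress                    number of shortest paths between distinct s, t
                          (both != v) that pass through v
eccentricity              maximum distance from v within its component
radiality                 (component diameter + 1 - mean distance) /
                          component diameter
neighborhood_connectivity mean degree of v's neighbors
topological_coefficient   mean shared-neighbor overlap with partner nodes,
                          normalized by degree (NetworkAnalyzer variant)
clustering_coefficient    2 * (edges among neighbors) / k(k-1)
dnr                       fraction of direct neighbors that are
                          disease-annotated
========================  ==================================================

The shortest-path family is computed by a level-synchronous, matrix-form
variant of Brandes' algorithm: one BFS distance matrix from
:func:`scipy.sparse.csgraph.shortest_path`, then path counts ``sigma`` and
two backward dependency accumulations (one weighted by ``1/sigma`` for
betweenness, one unweighted for stress) propagated level by level with sparse
matrix products.  This is exact on unweighted graphs and fast enough for
networks with a few thousand proteins.

Isolated nodes get 0 for every distance-based metric, and the DNR of an
isolated node is defined as 0 (the ratio is 0/0 there: no disease neighbors
are observable).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse import csgraph

from .graph_model import DiseaseAnnotation

logger = logging.getLogger(__name__)

#: Fixed column order of the feature table.
FEATURE_COLUMNS = [
    "degree",
    "closeness",
    "betweenness",
    "stress",
    "eccentricity",
    "radiality",
    "neighborhood_connectivity",
    "topological_coefficient",
    "clustering_coefficient",
    "dnr",
]


class ShortestPathFeatures(NamedTuple):
    eccentricity: int
    closeness: float
    radiality: float
    betweenness: float
    stress: int


class LocalFeatures(NamedTuple):
    neighborhood_connectivity: float
    topological_coefficient: float
    clustering_coefficient: float


def _nodelist(net: nx.Graph, nodelist: Sequence | None) -> list:
    return sorted(net.nodes()) if nodelist is None else list(nodelist)


def adjacency(net: nx.Graph, nodelist: Sequence | None = None) -> sp.csr_array:
    nodes = _nodelist(net, nodelist)
    return sp.csr_array(nx.to_scipy_sparse_array(net, nodelist=nodes, dtype=float, format="csr"))


def distance_matrix(net: nx.Graph, nodelist: Sequence | None = None):
    """All-pairs BFS distances; unreachable pairs are ``inf``.

    Returns ``(nodes, D)`` with rows/columns ordered by ``nodes`` (sorted
    node ids by default).
    """
    nodes = _nodelist(net, nodelist)
    if not nodes:
        return nodes, np.zeros((0, 0))
    A = adjacency(net, nodes)
    dist = csgraph.shortest_path(A, method="D", unweighted=True, directed=False)
    return nodes, dist


def _sigma_matrix(A: sp.csr_array, dist: np.ndarray):
    """Shortest-path counts sigma[s, v], level-synchronous accumulation."""
    n = dist.shape[0]
    level = np.where(np.isfinite(dist), dist, -1.0).astype(np.int64)
    max_d = int(level.max()) if n else 0
    sigma = np.eye(n)
    for d in range(1, max_d + 1):
        cur = level == d
        if not cur.any():
            break
        prev = level == d - 1
        # sigma[s, v] = sum of sigma[s, u] over neighbors u of v one level up
        spread = (A @ (sigma * prev).T).T
        sigma[cur] = spread[cur]
    return sigma, level, max_d


def _dependencies(A: sp.csr_array, sigma: np.ndarray, level: np.ndarray, max_d: int):
    """Backward accumulation of betweenness (delta) and stress (phi) terms.

    ``delta[s, v]`` is Brandes' pair dependency of source s on v;
    ``phi[s, v]`` is the number of shortest-path continuations from v to
    nodes strictly downstream of v in the BFS dag of s, so that
    ``sigma[s, v] * phi[s, v]`` counts (s, t) shortest paths through v.
    """
    n = sigma.shape[0]
    delta = np.zeros((n, n))
    phi = np.zeros((n, n))
    for d in range(max_d, 0, -1):
        cur = level == d
        if not cur.any():
            continue
        up = level == d - 1
        ratio = np.zeros((n, n))
        np.divide(1.0 + delta, sigma, out=ratio, where=cur & (sigma > 0))
        delta = np.where(up, sigma * (A @ ratio.T).T, delta)
        phi = np.where(up, (A @ ((1.0 + phi) * cur).T).T, phi)
    return delta, phi


def shortest_path_features(
    net: nx.Graph, nodelist: Sequence | None = None
) -> dict[object, ShortestPathFeatures]:
    """Eccentricity, closeness, radiality, betweenness and stress per node."""
    nodes = _nodelist(net, nodelist)
    n = len(nodes)
    if n == 0:
        return {}
    A = adjacency(net, nodes)
    _, dist = distance_matrix(net, nodes)
    finite = np.isfinite(dist)
    reach = finite.sum(axis=1) - 1  # reachable nodes besides self
    dist_sum = np.where(finite, dist, 0.0).sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        closeness = np.where(reach > 0, reach / dist_sum, 0.0)
        mean_dist = np.where(reach > 0, dist_sum / reach, 0.0)
    ecc = np.where(reach > 0, np.where(finite, dist, -np.inf).max(axis=1), 0.0)

    # component diameter per node, for radiality
    n_comp, comp = csgraph.connected_components(A, directed=False)
    comp_diam = np.zeros(n_comp)
    for c in range(n_comp):
        members = comp == c
        if members.sum() > 1:
            comp_diam[c] = ecc[members].max()
    diam = comp_diam[comp]
    with np.errstate(divide="ignore", invalid="ignore"):
        radiality = np.where((reach > 0) & (diam > 0), (diam + 1.0 - mean_dist) / diam, 0.0)

    sigma, level, max_d = _sigma_matrix(A, dist)
    delta, phi = _dependencies(A, sigma, level, max_d)
    betweenness = (delta.sum(axis=0) - np.diag(delta)) / 2.0
    stress_paths = sigma * phi
    stress = (stress_paths.sum(axis=0) - np.diag(stress_paths)) / 2.0

    return {
        node: ShortestPathFeatures(
            eccentricity=int(round(ecc[i])),
            closeness=float(closeness[i]),
            radiality=float(radiality[i]),
            betweenness=float(betweenness[i]),
            stress=int(round(stress[i])),
        )
        for i, node in enumerate(nodes)
    }


def local_features(
    net: nx.Graph, nodelist: Sequence | None = None
) -> dict[object, LocalFeatures]:
    """Neighborhood connectivity, topological coefficient, clustering."""
    nodes = _nodelist(net, nodelist)
    n = len(nodes)
    if n == 0:
        return {}
    A = adjacency(net, nodes)
    deg = np.asarray(A.sum(axis=1)).ravel()

    with np.errstate(divide="ignore", invalid="ignore"):
        nbr_conn = np.where(deg > 0, (A @ deg) / deg, 0.0)

    clustering = nx.clustering(net)
    cc = np.array([clustering[node] for node in nodes])

    # topological coefficient: partners m share >= 1 neighbor with v or are
    # direct neighbors; J(v, m) = shared-neighbor count (+1 if adjacent)
    shared = (A @ A).tocsr()
    J = (shared + A).tolil()
    J.setdiag(0.0)
    J = J.tocsr()
    J.eliminate_zeros()
    partner_count = np.diff(J.indptr)
    j_sum = np.asarray(J.sum(axis=1)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        tc = np.where(
            (deg >= 2) & (partner_count > 0),
            j_sum / np.maximum(partner_count, 1) / np.maximum(deg, 1),
            0.0,
        )

    return {
        node: LocalFeatures(
            neighborhood_connectivity=float(nbr_conn[i]),
            topological_coefficient=float(tc[i]),
            clustering_coefficient=float(cc[i]),
        )
        for i, node in enumerate(nodes)
    }


def disease_neighbor_ratio(
    net: nx.Graph, disease_genes: Iterable, nodelist: Sequence | None = None
) -> dict[object, float]:
    """DNR_i = (number of disease-annotated neighbors of i) / degree(i).

    Non-network members of ``disease_genes`` are ignored; isolated nodes get
    DNR 0.
    """
    nodes = _nodelist(net, nodelist)
    disease = set(disease_genes)
    A = adjacency(net, nodes)
    indicator = np.array([1.0 if node in disease else 0.0 for node in nodes])
    deg = np.asarray(A.sum(axis=1)).ravel()
    counts = A @ indicator
    with np.errstate(divide="ignore", invalid="ignore"):
        dnr = np.where(deg > 0, counts / deg, 0.0)
    return {node: float(dnr[i]) for i, node in enumerate(nodes)}


def build_feature_table(
    net: nx.Graph,
    annotation: DiseaseAnnotation,
    k_min: int = 1,
    dnr_disease_genes: Iterable | None = None,
) -> pd.DataFrame:
    """Feature table for every network protein, plus a class label column.

    Features are computed on the full network before any labeling split.  The
    DNR is computed from the full annotation's gene set by default; pass
    ``dnr_disease_genes`` to restrict it (e.g. to training-fold genes only).
    Rows are ordered lexicographically by protein id; columns follow
    :data:`FEATURE_COLUMNS` with ``label`` last.
    """
    nodes = sorted(net.nodes())
    spf = shortest_path_features(net, nodes)
    loc = local_features(net, nodes)
    disease = set(dnr_disease_genes) if dnr_disease_genes is not None else annotation.disease_genes()
    dnr = disease_neighbor_ratio(net, disease, nodes)

    rows = []
    for node in nodes:
        s, l = spf[node], loc[node]
        count = annotation.disease_count(node)
        if count >= k_min:
            label = "positive"
        elif count == 0:
            label = "negative"
        else:
            label = "excluded"
        rows.append(
            (
                node, net.degree(node), s.closeness, s.betweenness, s.stress,
                s.eccentricity, s.radiality, l.neighborhood_connectivity,
                l.topological_coefficient, l.clustering_coefficient,
                dnr[node], label,
            )
        )
    table = pd.DataFrame(
        rows, columns=["protein", *FEATURE_COLUMNS, "label"]
    ).set_index("protein")
    return table
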