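"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: explicit enumeration of shortest
paths, O(n^3) scans, closed-form statistics.  These functions never share
code with the package.
"""

from __future__ import annotations

import itertools
from collections import deque

import networkx as nx
import numpy as np
from scipy.stats import rankdata


# ---------------------------------------------------------------------------
# shortest-path metrics by exhaustive enumeration
# ---------------------------------------------------------------------------

def bfs_distances(net: nx.Graph, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in net.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def all_shortest_paths_count(net: nx.Graph, s, t):
    if s == t:
        return 1, [[s]]
    try:
        paths = list(nx.all_shortest_paths(net, s, t))
    except nx.NetworkXNoPath:
        return 0, []
    return len(paths), paths


def brute_force_metrics(net: nx.Graph) -> dict:
    """Per-node eccentricity, closeness, radiality, betweenness, stress."""
    nodes = sorted(net.nodes())
    ecc, clo, rad, btw, stress = {}, {}, {}, {}, {}
    # component diameters
    comp_of, diam_of = {}, {}
    for comp in nx.connected_components(net):
        comp = set(comp)
        d = 0
        for s in comp:
            dist = bfs_distances(net, s)
            if len(dist) > 1:
                d = max(d, max(dist.values()))
        for v in comp:
            comp_of[v] = comp
            diam_of[v] = d

    for v in nodes:
        dist = bfs_distances(net, v)
        others = {u: d for u, d in dist.items() if u != v}
        if not others:
            ecc[v] = 0
            clo[v] = 0.0
            rad[v] = 0.0
        else:
            mean_d = sum(others.values()) / len(others)
            ecc[v] = max(others.values())
            clo[v] = 1.0 / mean_d
            diam = diam_of[v]
            rad[v] = (diam + 1.0 - mean_d) / diam if diam > 0 else 0.0
        btw[v] = 0.0
        stress[v] = 0

    for s, t in itertools.combinations(nodes, 2):
        count, paths = all_shortest_paths_count(net, s, t)
        if count == 0:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            stress[v] += through
            btw[v] += through / count
    return {
        "eccentricity": ecc,
        "closeness": clo,
        "radiality": rad,
        "betweenness": btw,
        "stress": stress,
    }


def brute_force_local(net: nx.Graph) -> dict:
    """Neighborhood connectivity, topological coefficient, clustering."""
    nc, tc, cc = {}, {}, {}
    for v in net.nodes():
        nbrs = set(net.neighbors(v))
        k = len(nbrs)
        nc[v] = sum(net.degree(u) for u in nbrs) / k if k else 0.0
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if net.has_edge(a, b))
        cc[v] = 2.0 * links / (k * (k - 1)) if k >= 2 else 0.0
        # partners: nodes (not v) sharing >= 1 neighbor with v, plus direct neighbors
        shares = []
        for m in net.nodes():
            if m == v:
                continue
            shared = len(nbrs & set(net.neighbors(m)))
            if shared > 0 or m in nbrs:
                j = shared + (1 if m in nbrs else 0)
                shares.append(j)
        tc[v] = (np.mean(shares) / k) if (k >= 2 and shares) else 0.0
    return {
        "neighborhood_connectivity": nc,
        "topological_coefficient": tc,
        "clustering_coefficient": cc,
    }


def brute_force_dnr(net: nx.Graph, disease_genes) -> dict:
    disease = set(disease_genes)
    out = {}
    for v in net.nodes():
        nbrs = list(net.neighbors(v))
        out[v] = sum(1 for u in nbrs if u in disease) / len(nbrs) if nbrs else 0.0
    return out


# ---------------------------------------------------------------------------
# AUC via the tie-corrected rank statistic
# ---------------------------------------------------------------------------

def mann_whitney_auc(scores, labels) -> float:
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    if y.dtype.kind in "UO":
        pos = y == "positive"
    else:
        pos = y.astype(float) > 0
    n_pos, n_neg = pos.sum(), (~pos).sum()
    ranks = rankdata(s)  # average ranks handle ties
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# one ADTree boosting step by exhaustive search
# ---------------------------------------------------------------------------

def exhaustive_best_split(X, y, w, preconditions, epsilon=1.0):
    """Reference search over (precondition, attribute, midpoint threshold).

    ``preconditions`` is a list of boolean masks in creation order; returns
    (z, attribute, precondition index, threshold, a_true, a_false) of the
    best candidate under the tie order: attribute name, precondition order,
    smallest threshold.
    """
    total_w = w.sum()
    best = None
    for attr in sorted(X.columns):
        col = X[attr].to_numpy(float)
        for pi, mask in enumerate(preconditions):
            vals = sorted(set(col[mask]))
            for lo, hi in zip(vals, vals[1:]):
                thr = (lo + hi) / 2.0
                r = mask & (col >= thr)
                nr = mask & ~(col >= thr)
                wp = lambda m: w[m & (y > 0)].sum()
                wm = lambda m: w[m & (y < 0)].sum()
                z = 2 * (np.sqrt(wp(r) * wm(r)) + np.sqrt(wp(nr) * wm(nr))) + (
                    total_w - w[mask].sum()
                )
                if best is None or z < best[0] - 1e-12:
                    a_true = 0.5 * np.log((wp(r) + epsilon) / (wm(r) + epsilon))
                    a_false = 0.5 * np.log((wp(nr) + epsilon) / (wm(nr) + epsilon))
                    best = (z, attr, pi, thr, a_true, a_false)
    return best
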