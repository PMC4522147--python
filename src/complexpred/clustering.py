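"""Clustering algorithms over weighted protein networks.

Four algorithms are implemented natively behind a common registry:

* **MCL** — Markov clustering: alternating expansion (matrix squaring) and
  inflation (entry-wise power + column renormalisation) of a column-stochastic
  flow matrix until convergence; clusters are the attractor basins.
* **CMC** — maximal-clique finding (via :func:`networkx.find_cliques`)
  followed by merge-or-remove resolution of highly-overlapping cliques.
* **ClusterONE-style** — greedy seed growth maximising a cohesiveness
  function ``f(C) = W_in / (W_in + W_bound + penalty·|C|)``.
* **Coach** — core-attachment detection: dense neighbourhood cores plus
  proteins attached to a sufficient fraction of each core.

External tools (e.g. RNSC, IPCA binaries) can be plugged in through
:func:`register_algorithm`.  All algorithms are deterministic: every
iteration order is sorted, never hash order.
"""

from __future__ import annotations

import inspect
import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .features import WeightedNetwork
from .netio import canon

logger = logging.getLogger("complexpred")

__all__ = [
    "Cluster",
    "weighted_density",
    "mcl",
    "cmc",
    "cluster_one",
    "coach",
    "register_algorithm",
    "run_algorithms",
    "ALGORITHMS",
]


@dataclass(frozen=True)
class Cluster:
    """A predicted protein set with a score and provenance label."""

    members: frozenset[str]
    score: float = 0.0
    provenance: str = ""

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("cluster needs ≥2 members")

    @property
    def size(self) -> int:
        return len(self.members)

    def with_score(self, score: float, provenance: str | None = None) -> "Cluster":
        return Cluster(self.members, score,
                       self.provenance if provenance is None else provenance)


ClusterSet = list  # list[Cluster] from one algorithm run, no duplicate member sets


def weighted_density(members: Iterable[str], net: WeightedNetwork) -> float:
    """Sum of internal edge weights over the number of possible internal
    edges; absent edges contribute 0."""
    ms = sorted(set(members))
    n = len(ms)
    if n < 2:
        raise ValueError("need ≥2 members")
    total = 0.0
    for u, v in itertools.combinations(ms, 2):
        if net.has_edge(u, v):
            total += net.edges[u, v]["weight"]
    return total / (n * (n - 1) / 2)


def _dedup(clusters: Iterable[Cluster]) -> list[Cluster]:
    seen: dict[frozenset, Cluster] = {}
    for c in clusters:
        prev = seen.get(c.members)
        if prev is None or c.score > prev.score:
            seen[c.members] = c
    return sorted(seen.values(), key=lambda c: (-c.score, sorted(c.members)))


# ---------------------------------------------------------------------------
# MCL


def mcl(
    net: WeightedNetwork,
    inflation: float = 2.0,
    max_iter: int = 200,
    tol: float = 1e-6,
    prune: float = 1e-7,
    provenance: str = "mcl",
) -> list[Cluster]:
    """Markov clustering of a weighted network.

    Self-loops are added with weight equal to each node's maximum incident
    edge weight (stabilises the flow), columns are normalised, and
    expansion (power 2) / inflation steps are iterated until the matrix
    changes by less than ``tol`` or ``max_iter`` is reached.  The final
    partition is read off the attractor structure (connected components of
    the thresholded limit matrix); clusters of size ≥2 are returned, scored
    by their weighted density in the input network.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(net.nodes)
    if not nodes:
        return []
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    for u, v, d in net.edges(data=True):
        i, j = index[u], index[v]
        rows += [i, j]
        cols += [j, i]
        vals += [d["weight"], d["weight"]]
    for v in nodes:
        wmax = max((d["weight"] for _, d in net.adj[v].items()), default=1.0)
        i = index[v]
        rows.append(i)
        cols.append(i)
        vals.append(wmax if wmax > 0 else 1.0)
    m = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    def normalise(mat: sp.csr_matrix) -> sp.csr_matrix:
        colsum = np.asarray(mat.sum(axis=0)).ravel()
        colsum[colsum == 0] = 1.0
        return (mat @ sp.diags(1.0 / colsum)).tocsr()

    m = normalise(m)
    converged = False
    for _ in range(max_iter):
        prev = m
        m = m @ m                      # expansion
        m = m.power(inflation)         # inflation
        m.data[m.data < prune] = 0.0
        m.eliminate_zeros()
        m = normalise(m)
        diff = abs(m - prev)
        if diff.nnz == 0 or diff.max() < tol:
            converged = True
            break
    if not converged:
        logger.warning("mcl: no convergence after %d iterations", max_iter)

    # attractor basins: connected components of the support of the limit
    support = m.tocoo()
    comp_graph = nx.Graph()
    comp_graph.add_nodes_from(range(n))
    thresh = 1e-5
    for i, j, v in zip(support.row, support.col, support.data):
        if v > thresh and i != j:
            comp_graph.add_edge(int(i), int(j))
    clusters = []
    for comp in nx.connected_components(comp_graph):
        members = frozenset(nodes[i] for i in comp)
        if len(members) >= 2:
            clusters.append(
                Cluster(members, weighted_density(members, net), provenance)
            )
    return _dedup(clusters)


# ---------------------------------------------------------------------------
# CMC


def max_cliques(net: WeightedNetwork) -> list[frozenset[str]]:
    """Maximal cliques of size ≥2."""
    return sorted(
        (frozenset(c) for c in nx.find_cliques(net) if len(c) >= 2),
        key=lambda c: sorted(c),
    )


def _cross_density(net: WeightedNetwork, left: set[str], right: set[str]) -> float:
    if not left or not right:
        return 0.0
    total = sum(
        net.edges[u, v]["weight"]
        for u in left for v in right
        if net.has_edge(u, v)
    )
    return total / (len(left) * len(right))


def cmc(
    net: WeightedNetwork,
    merge_overlap: float = 0.75,
    interconnect_min: float = 0.5,
    provenance: str = "cmc",
) -> list[Cluster]:
    """Clustering by maximal cliques with merge-or-remove resolution.

    Cliques are ranked by descending weighted density.  For each
    lower-ranked clique overlapping a kept cluster by at least
    ``merge_overlap`` (relative to the lower-ranked clique's size): if the
    density of cross edges between the exclusive parts, relative to the mean
    internal density of the two, reaches ``interconnect_min`` the cliques
    are merged; otherwise the lower-density clique is discarded.
    """
    cliques = max_cliques(net)
    ranked = sorted(
        cliques, key=lambda c: (-weighted_density(c, net), sorted(c))
    )
    kept: list[set[str]] = []
    for cl in ranked:
        cl = set(cl)
        merged_away = False
        for grp in kept:
            inter = len(grp & cl)
            if inter / len(cl) >= merge_overlap:
                only_grp = grp - cl
                only_cl = cl - grp
                if not only_cl:
                    merged_away = True  # fully contained
                    break
                within = 0.5 * (
                    weighted_density(grp, net) + weighted_density(cl, net)
                )
                cross = _cross_density(net, only_grp or grp, only_cl)
                if within > 0 and cross / within >= interconnect_min:
                    grp |= cl
                merged_away = True
                break
        if not merged_away:
            kept.append(cl)
    clusters = [
        Cluster(frozenset(c), weighted_density(c, net), provenance)
        for c in kept
        if len(c) >= 2
    ]
    return _dedup(clusters)


# ---------------------------------------------------------------------------
# ClusterONE-style greedy cohesiveness expansion


def _cohesiveness(w_in: float, w_bound: float, size: int, penalty: float) -> float:
    denom = w_in + w_bound + penalty * size
    return w_in / denom if denom > 0 else 0.0


def cluster_one(
    net: WeightedNetwork,
    overlap_merge: float = 0.8,
    penalty: float | None = None,
    provenance: str = "clusterone",
) -> list[Cluster]:
    """Greedy cohesiveness-based seed expansion.

    Every node seeds a candidate cluster, processed in descending
    weighted-degree order (nodes already absorbed by a previous cluster do
    not re-seed).  Clusters grow by the boundary node (or shrink by the
    member) whose move best increases ``f(C) = W_in/(W_in+W_bound+p·|C|)``.
    The per-node penalty ``p`` defaults to twice the mean edge weight,
    modelling unobserved edges.  Finally, clusters with overlap
    ``ω(A,B) = |A∩B|²/(|A||B|) ≥ overlap_merge`` are merged.
    """
    if net.number_of_edges() == 0:
        return []
    if penalty is None:
        mean_w = float(
            np.mean([d["weight"] for _, _, d in net.edges(data=True)])
        )
        penalty = 2.0 * mean_w
    strength = {
        v: sum(d["weight"] for d in net.adj[v].values()) for v in net.nodes
    }
    seeds = sorted(net.nodes, key=lambda v: (-strength[v], v))
    covered: set[str] = set()
    raw: list[set[str]] = []
    for seed in seeds:
        if seed in covered:
            continue
        members = {seed}
        w_in = 0.0
        w_bound = strength[seed]
        while True:
            best_gain, best_move = 0.0, None
            f_cur = _cohesiveness(w_in, w_bound, len(members), penalty)
            boundary: set[str] = set()
            for u in members:
                boundary.update(v for v in net.adj[u] if v not in members)
            for v in sorted(boundary):
                w_to = sum(
                    d["weight"] for u, d in net.adj[v].items() if u in members
                )
                nw_in = w_in + w_to
                nw_bound = w_bound - w_to + (strength[v] - w_to)
                f_new = _cohesiveness(nw_in, nw_bound, len(members) + 1, penalty)
                if f_new - f_cur > best_gain + 1e-12:
                    best_gain, best_move = f_new - f_cur, ("add", v, nw_in, nw_bound)
            if len(members) > 1:
                for v in sorted(members):
                    w_to = sum(
                        d["weight"]
                        for u, d in net.adj[v].items()
                        if u in members and u != v
                    )
                    nw_in = w_in - w_to
                    nw_bound = w_bound + w_to - (strength[v] - w_to)
                    f_new = _cohesiveness(nw_in, nw_bound, len(members) - 1, penalty)
                    if f_new - f_cur > best_gain + 1e-12:
                        best_gain, best_move = f_new - f_cur, ("rm", v, nw_in, nw_bound)
            if best_move is None:
                break
            op, v, w_in, w_bound = best_move
            if op == "add":
                members.add(v)
            else:
                members.remove(v)
        if len(members) >= 2:
            raw.append(members)
            covered.update(members)

    # merge highly-overlapping clusters (ω² measure) to a fixpoint
    changed = True
    while changed:
        changed = False
        raw = sorted(raw, key=lambda c: (-len(c), sorted(c)))
        out: list[set[str]] = []
        for c in raw:
            for o in out:
                inter = len(c & o)
                if inter and inter * inter / (len(c) * len(o)) >= overlap_merge:
                    o |= c
                    changed = True
                    break
            else:
                out.append(set(c))
        raw = out
    clusters = [
        Cluster(frozenset(c), weighted_density(c, net), provenance) for c in raw
    ]
    return _dedup(clusters)


# ---------------------------------------------------------------------------
# Coach (core-attachment)


def coach(
    net: WeightedNetwork,
    core_density_min: float = 0.7,
    attach_frac: float = 0.5,
    provenance: str = "coach",
) -> list[Cluster]:
    """Core-attachment complex detection.

    For each protein's neighbourhood subgraph, the core is the set of
    vertices with at-least-average local degree whose induced subgraph is
    dense (weighted density ≥ ``core_density_min``).  Outside proteins
    adjacent to at least ``attach_frac`` of the core's vertices join as
    attachments.  By design only complexes of size ≥4 are emitted (the
    algorithm does not generate small clusters).
    """
    clusters: list[Cluster] = []
    for v in sorted(net.nodes):
        nbhd = sorted(set(net.adj[v]) | {v})
        if len(nbhd) < 4:
            continue
        sub = net.subgraph(nbhd)
        degs = {u: sub.degree(u) for u in nbhd}
        avg = sum(degs.values()) / len(nbhd)
        core = {u for u in nbhd if degs[u] >= avg}
        if len(core) < 2:
            continue
        if weighted_density(core, net) < core_density_min:
            continue
        attachments = set()
        need = attach_frac * len(core)
        for u in sorted(net.nodes):
            if u in core:
                continue
            links = sum(1 for c in core if net.has_edge(u, c))
            if links >= need:
                attachments.add(u)
        members = frozenset(core | attachments)
        if len(members) >= 4:
            clusters.append(
                Cluster(members, weighted_density(members, net), provenance)
            )
    return _dedup(clusters)


# ---------------------------------------------------------------------------
# registry / driver

ALGORITHMS: dict[str, Callable[..., list[Cluster]]] = {
    "mcl": mcl,
    "cmc": cmc,
    "clusterone": cluster_one,
    "coach": coach,
}


def register_algorithm(name: str, fn: Callable[..., list[Cluster]]) -> None:
    """Register an external clustering adapter (e.g. an RNSC/IPCA binary
    wrapper).  The callable takes a network and returns clusters."""
    ALGORITHMS[name] = fn


def run_algorithms(
    net: WeightedNetwork,
    algorithms: list[str],
    params: dict[str, dict] | None = None,
) -> list[list[Cluster]]:
    """Run each named algorithm on the same network.

    A failing plugin is skipped with a warning; callers using voting still
    divide by the configured algorithm count, so results stay comparable.
    Clusters of size <2 and duplicate member sets are dropped per set.
    """
    if not algorithms:
        raise ValueError("need at least one algorithm")
    params = params or {}
    out: list[list[Cluster]] = []
    for name in algorithms:
        if name not in ALGORITHMS:
            raise KeyError(f"unknown algorithm {name!r}")
        fn = ALGORITHMS[name]
        kwargs = dict(params.get(name, {}))
        takes_prov = "provenance" in inspect.signature(fn).parameters
        if takes_prov:
            kwargs["provenance"] = name
        try:
            clusters = fn(net, **kwargs)
        except Exception as exc:  # plugin failure: skip, keep denominator
            logger.warning("algorithm %s failed (%s); skipped", name, exc)
            continue
        if not takes_prov:
            clusters = [c.with_score(c.score, name) for c in clusters]
        out.append(_dedup(c for c in clusters if c.size >= 2))
    return out
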