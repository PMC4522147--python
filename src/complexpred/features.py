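"""Per-pair data-source scores and topological features.

Three data sources each yield a weighted, undirected network over proteins:

* **PPI** — experimental interactions scored by a per-method reliability
  model: ``reliability(a,b) = 1 − ∏_e (1 − rel_e)^{n_e}``, where ``rel_e`` is
  the fraction of method *e*'s detected pairs whose proteins share a
  high-level cellular-component term, and ``n_e`` counts publication-distinct
  detections of the pair by *e*.
* **STRING** — functional-association scores, kept only when strictly > 0.5.
* **LIT** — literature co-occurrence, the Jaccard similarity of the sets of
  papers mentioning each protein.

From each source network three topological features are derived per pair —
degree (DEG), neighbourhood connectivity (NBC) and iterative-AdjustCD shared
neighbours (SHARED) — using that source's scores as edge weights.  The table
builder assembles the feature columns each prediction approach consumes.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter, defaultdict

import networkx as nx
import pandas as pd

from .netio import EvidenceRecord, OntologyAnnotation, ScoredPair, canon

logger = logging.getLogger("complexpred")

WeightedNetwork = nx.Graph  # undirected, edge attribute "weight"

#: feature columns consumed by each approach
APPROACH_COLUMNS = {
    "SWC": ["PPI", "STRING", "LIT", "SHARED_PPI"],
    "DECOMP": ["PPI"],
    "SSS": [
        "PPI", "STRING", "LIT",
        "DEG_PPI", "DEG_STRING", "DEG_LIT",
        "SHARED_PPI", "SHARED_STRING", "SHARED_LIT",
        "NBC_PPI", "NBC_STRING", "NBC_LIT",
        "ISO",
    ],
}

__all__ = [
    "WeightedNetwork",
    "APPROACH_COLUMNS",
    "network_from_weights",
    "method_reliability",
    "ppi_reliability",
    "string_filter",
    "lit_jaccard",
    "deg",
    "nbc",
    "shared_adjustcd",
    "build_feature_table",
]


def network_from_weights(weights: dict[tuple[str, str], float]) -> WeightedNetwork:
    g = nx.Graph()
    for (a, b), w in weights.items():
        g.add_edge(a, b, weight=float(w))
    return g


def method_reliability(
    evidence: list[EvidenceRecord],
    cc: OntologyAnnotation,
    high_level_terms: set[str],
) -> dict[str, float]:
    """Estimate each detection method's reliability.

    ``rel_e`` is the fraction of the distinct pairs detected by method *e*
    whose two proteins share at least one high-level cellular-component
    term.  Proteins without CC annotation count as not sharing.  Methods
    with no detected pairs are absent from the result.
    """
    if not high_level_terms:
        raise ValueError("high_level_terms must be nonempty")
    term_sets: dict[str, set[str]] = {}  # protein -> high-level terms

    def hl_terms(p: str) -> set[str]:
        if p not in term_sets:
            term_sets[p] = {t for t in high_level_terms if p in cc.ann(t)}
        return term_sets[p]

    pairs_by_method: dict[str, set[tuple[str, str]]] = defaultdict(set)
    for rec in evidence:
        pairs_by_method[rec.method].add(rec.pair)
    rel: dict[str, float] = {}
    for method, pairs in sorted(pairs_by_method.items()):
        share = sum(1 for a, b in pairs if hl_terms(a) & hl_terms(b))
        rel[method] = share / len(pairs)
    return rel


def ppi_reliability(
    evidence: list[EvidenceRecord], rel: dict[str, float]
) -> WeightedNetwork:
    """Score each pair by ``1 − ∏_e (1 − rel_e)^{n_e}``.

    Evidence is deduplicated by publication ID per (pair, method) before
    counting, so the same detection reported by several source files counts
    once.  Pairs whose weight is 0 (all contributing methods have rel 0)
    are still emitted as 0-weight edges.
    """
    counts: Counter[tuple[tuple[str, str], str]] = Counter()
    seen: set[tuple[str, str, str, str]] = set()
    for r in evidence:
        key = (r.a, r.b, r.method, r.pub)
        if key in seen:
            continue
        seen.add(key)
        counts[(r.pair, r.method)] += 1
    per_pair: dict[tuple[str, str], float] = defaultdict(lambda: 1.0)
    for (pair, method), n in counts.items():
        if method not in rel:
            raise KeyError(f"no reliability estimate for method {method!r}")
        per_pair[pair] *= (1.0 - rel[method]) ** n
    g = nx.Graph()
    for (a, b), prod in per_pair.items():
        g.add_edge(a, b, weight=1.0 - prod)
    return g


def string_filter(pairs: list[ScoredPair]) -> WeightedNetwork:
    """Keep functional-association edges with score strictly greater than 0.5."""
    g = nx.Graph()
    for p in pairs:
        if p.score > 0.5:
            g.add_edge(p.a, p.b, weight=p.score)
    return g


def lit_jaccard(paper_sets: dict[str, set[str]]) -> WeightedNetwork:
    """Literature co-occurrence network: Jaccard similarity of paper sets.

    Only pairs with a positive score are emitted; candidate pairs are those
    sharing at least one paper (all others score 0).
    """
    by_paper: dict[str, list[str]] = defaultdict(list)
    for prot in sorted(paper_sets):
        for paper in paper_sets[prot]:
            by_paper[paper].append(prot)
    g = nx.Graph()
    done: set[tuple[str, str]] = set()
    for prots in by_paper.values():
        for a, b in itertools.combinations(prots, 2):
            pair = canon(a, b)
            if pair in done:
                continue
            done.add(pair)
            inter = len(paper_sets[a] & paper_sets[b])
            union = len(paper_sets[a] | paper_sets[b])
            if inter:
                g.add_edge(*pair, weight=inter / union)
    return g


def _strength(g: WeightedNetwork, node: str, exclude: str | None = None) -> float:
    return sum(
        d["weight"] for nbr, d in g.adj[node].items() if nbr != exclude
    )


def deg(net: WeightedNetwork, pair: tuple[str, str]) -> float:
    """Summed weight of edges leaving the pair, excluding the (a,b) edge."""
    a, b = pair
    total = 0.0
    if a in net:
        total += _strength(net, a, exclude=b)
    if b in net:
        total += _strength(net, b, exclude=a)
    return total


def nbc(net: WeightedNetwork, pair: tuple[str, str], lambda_: int = 10) -> float:
    """Neighbourhood connectivity: weighted density among the pair's
    neighbours ``N_{a,b} = (N_a ∪ N_b) ∖ {a,b}``.

    The numerator sums over ordered neighbour pairs (each undirected edge
    counts twice) so a complete unit-weight neighbourhood of ≤ λ nodes
    scores exactly 1.  Neighbourhoods of fewer than two nodes score 0.
    """
    a, b = pair
    nbrs: set[str] = set()
    if a in net:
        nbrs.update(net.adj[a])
    if b in net:
        nbrs.update(net.adj[b])
    nbrs -= {a, b}
    n = len(nbrs)
    if n < 2:
        return 0.0
    total = 0.0
    for x in nbrs:
        if x not in net:
            continue
        for y, d in net.adj[x].items():
            if y in nbrs and y != x:
                total += d["weight"]  # ordered pairs: counted from both ends
    m = min(n, lambda_)
    return total / (m * (m - 1))


def shared_adjustcd(
    net: WeightedNetwork, iterations: int = 2
) -> dict[tuple[str, str], float]:
    """Iterative AdjustCD shared-neighbour scores.

    One iteration maps weights ``w_k`` to::

        w_{k+1}(u,v) = Σ_{x∈N_u∩N_v} (w_k(u,x)+w_k(v,x))
                       / (Σ_{x∈N_u} w_k(u,x) + λ_u + Σ_{x∈N_v} w_k(v,x) + λ_v)

    with ``λ_u = max(0, n̄ − Σ_{x∈N_u} w_k(u,x))`` and ``n̄`` the mean node
    strength, penalising poorly-connected proteins.  Scores are produced for
    every pair sharing at least one neighbour; the pair graph itself evolves
    across iterations.
    """
    if iterations < 1:
        raise ValueError("iterations must be ≥ 1")
    adj: dict[str, dict[str, float]] = {
        u: {v: d["weight"] for v, d in net.adj[u].items()} for u in net.nodes
    }
    result: dict[tuple[str, str], float] = {}
    for _ in range(iterations):
        strengths = {u: sum(nbrs.values()) for u, nbrs in adj.items()}
        nodes = list(adj)
        nbar = sum(strengths.values()) / len(nodes) if nodes else 0.0
        lam = {u: max(0.0, nbar - strengths[u]) for u in nodes}
        # candidate pairs: share >= 1 neighbour
        new: dict[tuple[str, str], float] = {}
        by_node = {u: set(nbrs) for u, nbrs in adj.items()}
        cand: set[tuple[str, str]] = set()
        for x, nbrs in adj.items():
            for u, v in itertools.combinations(sorted(nbrs), 2):
                cand.add((u, v))
        for u, v in cand:
            common = by_node[u] & by_node[v]
            num = sum(adj[u][x] + adj[v][x] for x in common)
            den = strengths[u] + lam[u] + strengths[v] + lam[v]
            if den > 0 and num > 0:
                new[(u, v)] = num / den
        result = new
        adj = defaultdict(dict)
        for (u, v), w in new.items():
            adj[u][v] = w
            adj[v][u] = w
        adj = dict(adj)
    return result


def build_feature_table(
    ppi: WeightedNetwork,
    string: WeightedNetwork | None = None,
    lit: WeightedNetwork | None = None,
    approach: str = "SSS",
    lambda_nbc: int = 10,
) -> pd.DataFrame:
    """Assemble the per-pair feature table for one approach.

    Rows are the union of edges over the source networks; topological
    features are computed in each source network with that source's weights.
    Missing values are 0.  The ISO column (SSS only) is initialised to 0 and
    filled by the small-complex stage.
    """
    if approach not in APPROACH_COLUMNS:
        raise ValueError(f"unknown approach {approach!r}")
    if ppi is None or ppi.number_of_edges() == 0:
        raise ValueError("PPI network must be nonempty")
    columns = APPROACH_COLUMNS[approach]
    string = string if string is not None else nx.Graph()
    lit = lit if lit is not None else nx.Graph()
    nets = {"PPI": ppi, "STRING": string, "LIT": lit}

    pairs: set[tuple[str, str]] = set()
    for name, net in nets.items():
        if name in columns:  # union of sources whose score column is used
            pairs.update(canon(u, v) for u, v in net.edges)
    pairs_sorted = sorted(pairs)

    data: dict[str, list[float]] = {c: [] for c in columns}
    shared_cache: dict[str, dict[tuple[str, str], float]] = {}
    for col in columns:
        if col.startswith("SHARED_"):
            src = col.split("_", 1)[1]
            shared_cache[src] = shared_adjustcd(nets[src], iterations=2)

    for pair in pairs_sorted:
        for col in columns:
            if col == "ISO":
                data[col].append(0.0)
            elif col in nets:
                net = nets[col]
                w = net.edges[pair]["weight"] if net.has_edge(*pair) else 0.0
                data[col].append(w)
            elif col.startswith("DEG_"):
                data[col].append(deg(nets[col.split("_", 1)[1]], pair))
            elif col.startswith("NBC_"):
                data[col].append(nbc(nets[col.split("_", 1)[1]], pair, lambda_nbc))
            elif col.startswith("SHARED_"):
                data[col].append(shared_cache[col.split("_", 1)[1]].get(pair, 0.0))
    index = pd.MultiIndex.from_tuples(pairs_sorted, names=["a", "b"])
    return pd.DataFrame(data, index=index, columns=columns)
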