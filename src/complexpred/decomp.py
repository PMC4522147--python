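"""GO-based decomposition branch (DECOMP).

Complexes embedded in highly-connected regions of the PPI network are hard
to delimit.  This branch (1) removes hub proteins (more than ``n_hub``
interaction partners, typically date hubs with non-simultaneous
interactions), (2) splits the network into spatially-coherent subnetworks
induced by cellular-component terms chosen at an annotation-size sweet spot
(at least ``n_go`` proteins, no descendant above ``n_go``), (3) clusters
each subnetwork, and (4) re-adds hubs to the clusters they are highly
connected to before majority voting across the clustering algorithms.
"""

from __future__ import annotations

import logging

from .clustering import Cluster, run_algorithms, weighted_density
from .combine import combine_votes
from .features import WeightedNetwork
from .netio import OntologyAnnotation, RunConfig
from .supervised_weighting import top_k_edges

logger = logging.getLogger("complexpred")

__all__ = [
    "remove_hubs",
    "select_terms",
    "decompose",
    "readd_hubs",
    "decomp_pipeline",
]


def remove_hubs(
    net: WeightedNetwork, n_hub: int
) -> tuple[WeightedNetwork, set[str]]:
    """Drop nodes with more than ``n_hub`` interaction partners.

    Degree is the unweighted partner count on the input network (strictly
    greater than the threshold removes).  Returns the reduced network and
    the hub set.
    """
    if n_hub < 1:
        raise ValueError("n_hub must be ≥ 1")
    hubs = {v for v in net.nodes if net.degree(v) > n_hub}
    reduced = net.copy()
    reduced.remove_nodes_from(hubs)
    return reduced, hubs


def select_terms(ann: OntologyAnnotation, n_go: int) -> list[str]:
    """Choose decomposition terms: annotated to ≥ ``n_go`` proteins while no
    descendant term is annotated to more than ``n_go`` proteins."""
    if n_go < 1:
        raise ValueError("n_go must be ≥ 1")
    selected = []
    for term in ann.terms():
        if len(ann.ann(term)) < n_go:
            continue
        if all(len(ann.ann(d)) <= n_go for d in ann.descendants(term)):
            selected.append(term)
    if not selected:
        raise ValueError(
            f"no ontology term annotated to ≥{n_go} proteins with all "
            f"descendants ≤{n_go}; try a smaller n_go"
        )
    return selected


def decompose(
    net: WeightedNetwork, terms: list[str], ann: OntologyAnnotation
) -> dict[str, WeightedNetwork]:
    """Induced subnetwork per selected term (proteins annotated to the term,
    post-propagation); empty subnetworks are dropped.  A protein annotated
    to several selected terms appears in each of their subnetworks."""
    out: dict[str, WeightedNetwork] = {}
    for term in terms:
        members = ann.ann(term) & set(net.nodes)
        sub = net.subgraph(sorted(members)).copy()
        if sub.number_of_edges() > 0:
            out[term] = sub
    return out


def readd_hubs(
    clusters: list[Cluster],
    hubs: set[str],
    net_full: WeightedNetwork,
    frac: float = 0.5,
) -> list[Cluster]:
    """Re-add each hub to every cluster it is adjacent to at least ``frac``
    of the members of (on the pre-hub-removal network); duplicates arising
    from the extension are re-deduplicated keeping the best score."""
    if not hubs:
        return clusters
    out: dict[frozenset, Cluster] = {}
    for c in clusters:
        members = set(c.members)
        for h in sorted(hubs):
            if h in members or h not in net_full:
                continue
            links = sum(1 for m in c.members if net_full.has_edge(h, m))
            if links >= frac * len(c.members):
                members.add(h)
        extended = frozenset(members)
        prev = out.get(extended)
        if prev is None or c.score > prev.score:
            out[extended] = Cluster(extended, c.score, c.provenance)
    return sorted(out.values(), key=lambda c: (-c.score, sorted(c.members)))


def decomp_pipeline(
    ppi_net: WeightedNetwork,
    ann: OntologyAnnotation,
    config: RunConfig,
    algorithms: list[str] | None = None,
    algo_params: dict | None = None,
) -> list[Cluster]:
    """Full DECOMP branch: top-k reliability edges → hub removal → GO
    decomposition → per-algorithm clustering of each subnetwork with hub
    re-addition → majority voting → size ≥4 filter.

    Scores are weighted density under the reliability weights times the
    vote fraction.
    """
    algorithms = algorithms or ["mcl", "cmc", "clusterone", "coach"]
    weights = {
        tuple(sorted((u, v))): d["weight"] for u, v, d in ppi_net.edges(data=True)
    }
    net = top_k_edges(weights, config.k_large)
    reduced, hubs = remove_hubs(net, config.n_hub)
    terms = select_terms(ann, config.n_go)
    subnets = decompose(reduced, terms, ann)
    logger.info(
        "decomp: %d hubs removed, %d terms, %d subnetworks",
        len(hubs), len(terms), len(subnets),
    )
    per_algorithm: list[list[Cluster]] = []
    for algo in algorithms:
        union: dict[frozenset, Cluster] = {}
        for term in sorted(subnets):
            sets = run_algorithms(subnets[term], [algo], algo_params)
            for cset in sets:
                for c in cset:
                    prev = union.get(c.members)
                    if prev is None or c.score > prev.score:
                        union[c.members] = c
        clusters = sorted(
            union.values(), key=lambda c: (-c.score, sorted(c.members))
        )
        clusters = readd_hubs(clusters, hubs, net, config.hub_readd_frac)
        per_algorithm.append(clusters)
    combined = combine_votes(
        per_algorithm, net, n_algorithms=len(algorithms),
        sim_threshold=config.sim_threshold, provenance="decomp",
    )
    return [c for c in combined if c.size >= 4]
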