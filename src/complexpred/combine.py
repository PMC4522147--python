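"""Majority-vote aggregation of cluster sets and final branch integration.

COMBINE takes the union of cluster sets produced by several clustering
algorithms on the same network.  Clusters that are mutually similar
(Jaccard ≥ 0.75 by default) are grouped; each group is represented by its
highest-weighted-density member, scored by that density times the number of
algorithms voting for the group, normalised by the number of algorithms
configured.

Integration merges the cluster sets of the three prediction branches after
scaling: DECOMP scores are multiplied by *d* and SSS scores by *s* (SWC is
the implicit 1.0 reference); similar clusters across branches have their
scaled scores summed.  Similarity grouping is not transitive, so both
operations use the same deterministic greedy representative scheme in
descending score order.
"""

from __future__ import annotations

from collections.abc import Iterable, Set

from .clustering import Cluster, weighted_density
from .features import WeightedNetwork

__all__ = ["jaccard", "combine_votes", "integrate"]


def jaccard(set_a: Set[str], set_b: Set[str]) -> float:
    """Jaccard similarity |A∩B| / |A∪B| of two nonempty protein sets."""
    if not set_a or not set_b:
        raise ValueError("sets must be nonempty")
    inter = len(set_a & set_b)
    if inter == 0:
        return 0.0
    return inter / len(set_a | set_b)


def _greedy_groups(
    ranked: list[tuple[float, Cluster]], sim_threshold: float
) -> list[tuple[Cluster, list[tuple[float, Cluster]]]]:
    """Group clusters greedily: in descending score order, each cluster
    joins the first group whose representative it matches, else starts one.
    Returns (representative, [(key_score, member), ...]) per group."""
    groups: list[tuple[Cluster, list[tuple[float, Cluster]]]] = []
    for key, cluster in ranked:
        for rep, members in groups:
            if jaccard(rep.members, cluster.members) >= sim_threshold:
                members.append((key, cluster))
                break
        else:
            groups.append((cluster, [(key, cluster)]))
    return groups


def combine_votes(
    cluster_sets: Iterable[list[Cluster]],
    net_for_density: WeightedNetwork,
    n_algorithms: int,
    sim_threshold: float = 0.75,
    provenance: str = "combine",
) -> list[Cluster]:
    """Aggregate the cluster sets of several algorithms by majority voting.

    Each output group keeps the member set of its highest-density cluster
    and scores it ``density × votes / n_algorithms`` where votes is the
    number of distinct algorithms contributing a similar cluster.
    """
    if n_algorithms < 1:
        raise ValueError("n_algorithms must be ≥ 1")
    pool: list[tuple[float, Cluster]] = []
    for cset in cluster_sets:
        for c in cset:
            pool.append((weighted_density(c.members, net_for_density), c))
    pool.sort(key=lambda t: (-t[0], sorted(t[1].members), t[1].provenance))
    out: list[Cluster] = []
    for rep, members in _greedy_groups(pool, sim_threshold):
        density = members[0][0]  # representative's density (highest in group)
        votes = len({c.provenance for _, c in members})
        out.append(
            Cluster(rep.members, density * votes / n_algorithms, provenance)
        )
    return sorted(out, key=lambda c: (-c.score, sorted(c.members)))


def integrate(
    swc: list[Cluster],
    decomp: list[Cluster],
    sss: list[Cluster],
    d: float = 0.6,
    s: float = 1.0,
    sim_threshold: float = 0.75,
) -> list[Cluster]:
    """Scale-and-sum integration of the three branch cluster sets.

    DECOMP scores scale by ``d``, SSS by ``s``, SWC by 1.0.  Groups of
    similar clusters (Jaccard ≥ ``sim_threshold``) keep the member set of
    the highest scaled-score cluster and sum the scaled scores of all group
    members; scores may exceed 1 and are deliberately not renormalised.
    """
    if d < 0 or s < 0:
        raise ValueError("scale factors must be non-negative")
    pool: list[tuple[float, Cluster]] = []
    for scale, branch, cset in (
        (1.0, "swc", swc), (d, "decomp", decomp), (s, "sss", sss)
    ):
        for c in cset:
            pool.append(
                (scale * c.score, Cluster(c.members, c.score, branch))
            )
    pool.sort(key=lambda t: (-t[0], sorted(t[1].members), t[1].provenance))
    out: list[Cluster] = []
    for rep, members in _greedy_groups(pool, sim_threshold):
        total = sum(score for score, _ in members)
        branches = "+".join(sorted({c.provenance for _, c in members}))
        out.append(Cluster(rep.members, total, branches))
    return sorted(out, key=lambda c: (-c.score, sorted(c.members)))
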