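"""Size-specific supervised weighting branch (SSS) for small complexes.

Small complexes (2–3 proteins) carry no density signal, so they are
predicted from a 3-class posterior (small-co-complex / large-co-complex /
non-complex) over the full 13-feature table.  An isolatedness feature (ISO)
captures the probability that a pair sits in an isolated size-2/3 clique:
it is derived from a first-pass fit on the 12 non-ISO features, after which
the model is refit with ISO included.  Candidate size-2 and size-3 clusters
are extracted from the top-k small-co-complex-weighted edges and scored by
cohesiveness-weighted density, which discounts candidates with strong
surrounding edges.
"""

from __future__ import annotations

import itertools
import logging

import pandas as pd

from .clustering import Cluster
from .features import WeightedNetwork, network_from_weights
from .netio import ComplexCatalogue, RunConfig
from .supervised_weighting import fit_nb, label_edges, posterior_weight, top_k_edges

logger = logging.getLogger("complexpred")

__all__ = [
    "iso_feature",
    "cohesiveness_weighted_density",
    "extract_small_clusters",
    "sss_pipeline",
]


def iso_feature(
    p_small: dict[tuple[str, str], float], net: WeightedNetwork
) -> dict[tuple[str, str], float]:
    """Isolatedness of each pair under first-pass small-co-complex posteriors.

    For pair (a,b), over candidate cliques S — the pair itself and every
    triangle {a,b,c} with c adjacent to both in ``net`` —

        ISO(a,b) = max_S ∏_{internal e of S} p_small(e)
                         × ∏_{e leaving S} (1 − p_small(e)),

    so a pair scores high when its clique's edges look small-co-complex and
    every edge connecting the clique to the rest of the network does not.
    """
    def p(u: str, v: str) -> float:
        return p_small.get(tuple(sorted((u, v))), 0.0)

    def clique_score(members: tuple[str, ...]) -> float:
        inside = set(members)
        score = 1.0
        for u, v in itertools.combinations(members, 2):
            score *= p(u, v)
        if score == 0.0:
            return 0.0
        for u in members:
            if u not in net:
                continue
            for v in net.adj[u]:
                if v not in inside:
                    score *= 1.0 - p(u, v)
        return score

    out: dict[tuple[str, str], float] = {}
    for pair in p_small:
        a, b = pair
        best = clique_score((a, b))
        if a in net and b in net:
            common = sorted(set(net.adj[a]) & set(net.adj[b]))
            for c in common:
                best = max(best, clique_score((a, b, c)))
        out[pair] = best
    return out


def cohesiveness_weighted_density(
    members: set[str] | frozenset[str],
    p_small: dict[tuple[str, str], float],
    net: WeightedNetwork,
) -> float:
    """Score a size-2/3 candidate by internal density times cohesiveness.

    ``dens`` is the mean small-co-complex posterior over possible internal
    edges; cohesiveness ``W_in/(W_in+W_out)`` discounts candidates whose
    boundary edges (exactly one endpoint inside, per ``net``) also look
    small-co-complex.  A candidate with no internal posterior mass scores 0.
    """
    ms = sorted(members)
    if len(ms) not in (2, 3):
        raise ValueError("small candidates have 2 or 3 members")

    def p(u: str, v: str) -> float:
        return p_small.get(tuple(sorted((u, v))), 0.0)

    internal = [p(u, v) for u, v in itertools.combinations(ms, 2)]
    w_in = sum(internal)
    if w_in == 0:
        return 0.0
    dens = w_in / len(internal)
    w_out = 0.0
    inside = set(ms)
    for u in ms:
        if u not in net:
            continue
        for v in net.adj[u]:
            if v not in inside:
                w_out += p(u, v)
    return dens * w_in / (w_in + w_out)


def extract_small_clusters(
    posteriors: pd.DataFrame,
    net: WeightedNetwork,
    k_small: int = 10000,
    provenance: str = "sss",
) -> list[Cluster]:
    """Extract size-2/3 candidates from the top-k small-co-complex edges.

    Every retained edge is a size-2 candidate and every triangle of
    retained edges a size-3 candidate, scored by cohesiveness-weighted
    density against the full network.  A size-2 candidate contained in a
    higher-scoring emitted size-3 candidate is suppressed.
    """
    p_small = dict(zip(posteriors.index, posteriors["small_co"]))
    retained = top_k_edges(p_small, k_small)
    pair_scores: dict[frozenset, float] = {}
    for u, v in retained.edges:
        members = frozenset((u, v))
        pair_scores[members] = cohesiveness_weighted_density(members, p_small, net)
    tri_scores: dict[frozenset, float] = {}
    for u in sorted(retained.nodes):
        for v, w in itertools.combinations(sorted(retained.adj[u]), 2):
            if u < v and retained.has_edge(v, w):
                members = frozenset((u, v, w))
                if members not in tri_scores:
                    tri_scores[members] = cohesiveness_weighted_density(
                        members, p_small, net
                    )
    clusters: list[Cluster] = []
    for members, score in tri_scores.items():
        clusters.append(Cluster(members, score, provenance))
    for members, score in pair_scores.items():
        best_tri = max(
            (s for tri, s in tri_scores.items() if members <= tri),
            default=None,
        )
        if best_tri is not None and best_tri > score:
            continue  # suppressed under a better-scoring containing triangle
        clusters.append(Cluster(members, score, provenance))
    return sorted(clusters, key=lambda c: (-c.score, sorted(c.members)))


def sss_pipeline(
    feature_table: pd.DataFrame,
    training: ComplexCatalogue,
    config: RunConfig,
    net: WeightedNetwork | None = None,
) -> list[Cluster]:
    """Full SSS branch with the two-pass ISO refit.

    1. label edges 3-class from the training complexes;
    2. fit naive Bayes on the 12 non-ISO features, compute first-pass
       small-co-complex posteriors;
    3. fill the ISO column, refit on all 13 features;
    4. select the top ``k_small`` edges by small-co-complex posterior and
       extract/score size-2 and size-3 candidates.

    ``net`` is the network defining adjacency for ISO and boundary edges;
    by default it connects every feature-table pair.
    """
    if "ISO" not in feature_table.columns:
        raise ValueError("feature table lacks SSS columns (ISO missing)")
    if net is None:
        net = network_from_weights({pair: 1.0 for pair in feature_table.index})
    labels = label_edges(feature_table, training, mode="SSS")
    base = feature_table.drop(columns=["ISO"])
    model1 = fit_nb(base, labels, bins=config.bins, mle=config.mle)
    post1 = posterior_weight(model1, base)
    p_small1 = dict(zip(post1.index, post1["small_co"]))
    iso = iso_feature(p_small1, net)
    table = feature_table.copy()
    table["ISO"] = [iso.get(pair, 0.0) for pair in table.index]
    model2 = fit_nb(table, labels, bins=config.bins, mle=config.mle)
    post2 = posterior_weight(model2, table)
    return extract_small_clusters(post2, net, config.k_small)
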