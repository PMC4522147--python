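"""Evaluation protocol: size-aware matching, training-aware precision-recall,
cross-validation splits, complex stratification, GO semantic coherence and
the novel-prediction filter.

A cluster matches a reference complex only within its size class: large
complexes (>3 proteins) match large clusters at Jaccard ≥ ``lg_match``;
small complexes (≤3) must be matched by small clusters at ``sm_match``
(1.0 by default — a one-protein mismatch makes a small prediction useless).
Precision is computed only among clusters that do not match a training
complex, removing the supervised approaches' bias toward reproducing their
training set.

Reference complexes are stratified into seven groups: small, and the cross
of density DENS ∈ {[0,.35], (.35,.7], (.7,1]} with embeddedness EXT ∈
{≤3, >3}, where EXT counts external proteins adjacent to at least half of a
complex's members.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np

from .clustering import Cluster
from .combine import jaccard
from .features import WeightedNetwork
from .netio import ComplexCatalogue, OntologyAnnotation

logger = logging.getLogger("complexpred")

__all__ = [
    "MatchRule",
    "EvalPoint",
    "STRATA",
    "match",
    "precision_recall",
    "cross_validate",
    "complex_dens",
    "complex_ext",
    "stratify",
    "best_match_scores",
    "semantic_coherence",
    "filter_novel",
]


@dataclass(frozen=True)
class MatchRule:
    """Size-specific Jaccard thresholds (small complex ≡ size ≤3)."""

    lg_match: float = 0.75
    sm_match: float = 1.0

    def __post_init__(self):
        for v in (self.lg_match, self.sm_match):
            if not 0 < v <= 1:
                raise ValueError("match thresholds must be in (0,1]")


@dataclass(frozen=True)
class EvalPoint:
    threshold: float
    precision: float
    recall: float


STRATA = (
    "small",
    "dens_low/ext_low", "dens_low/ext_high",
    "dens_med/ext_low", "dens_med/ext_high",
    "dens_high/ext_low", "dens_high/ext_high",
)


def match(complex_members, cluster_members, rule: MatchRule) -> bool:
    """Size-aware match: both large with Jaccard ≥ lg_match, or both small
    with Jaccard ≥ sm_match; cross-size pairs never match."""
    c_small = len(complex_members) <= 3
    p_small = len(cluster_members) <= 3
    if c_small != p_small:
        return False
    threshold = rule.sm_match if c_small else rule.lg_match
    return jaccard(complex_members, cluster_members) >= threshold


def precision_recall(
    clusters: list[Cluster],
    test: ComplexCatalogue,
    train: ComplexCatalogue,
    rule: MatchRule,
) -> list[EvalPoint]:
    """Precision-recall curve over cluster-score thresholds.

    At threshold s, recall is the fraction of test complexes matched by a
    cluster scoring ≥ s; precision is the number of test-matching clusters
    over the clusters that either match a test complex or match no training
    complex.  Thresholds with an empty denominator are omitted.
    """
    test_sets = test.member_sets()
    train_sets = train.member_sets()
    n_test = len(test_sets)
    info = []
    best_for_complex = [-math.inf] * n_test
    for c in clusters:
        m_test = False
        for i, t_set in enumerate(test_sets):
            if match(t_set, c.members, rule):
                m_test = True
                best_for_complex[i] = max(best_for_complex[i], c.score)
        m_train = any(match(t, c.members, rule) for t in train_sets)
        info.append((c.score, m_test, m_train))
    info.sort(key=lambda t: -t[0])
    scores = np.array([t[0] for t in info])
    numer_cum = np.cumsum([t[1] for t in info])
    denom_cum = np.cumsum([t[1] or not t[2] for t in info])
    best_arr = np.array(best_for_complex)
    points: list[EvalPoint] = []
    for s in sorted({score for score, _, _ in info}, reverse=True):
        k = int(np.searchsorted(-scores, -s, side="right"))  # clusters ≥ s
        denom = int(denom_cum[k - 1]) if k else 0
        if denom == 0:
            continue
        numer = int(numer_cum[k - 1]) if k else 0
        recall = float((best_arr >= s).sum()) / n_test if n_test else 0.0
        points.append(EvalPoint(s, numer / denom, recall))
    return points


def cross_validate(
    catalogue: ComplexCatalogue,
    t_pct: float = 90.0,
    rounds: int = 10,
    seed: int = 0,
) -> list[tuple[ComplexCatalogue, ComplexCatalogue]]:
    """Random sub-sampling cross-validation splits (train, test) per round.

    Each round draws ``floor(t_pct/100 · N)`` complexes without replacement
    as the test set; the remainder trains.  Fully reproducible for a seed.
    """
    if len(catalogue) < 10:
        raise ValueError("catalogue too small for cross-validation")
    names = [n for n, _ in catalogue]
    n_test = int(math.floor(t_pct / 100.0 * len(names)))
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(rounds):
        test_names = set(rng.choice(names, size=n_test, replace=False))
        train_names = [n for n in names if n not in test_names]
        splits.append(
            (catalogue.subset(train_names), catalogue.subset(test_names))
        )
    return splits


def complex_dens(members, ppi_net: WeightedNetwork) -> float:
    """Unweighted PPI edge count over possible edges within the complex."""
    ms = sorted(members)
    if len(ms) < 2:
        raise ValueError("need ≥2 members")
    edges = sum(
        1 for u, v in itertools.combinations(ms, 2) if ppi_net.has_edge(u, v)
    )
    return edges / (len(ms) * (len(ms) - 1) / 2)


def complex_ext(members, ppi_net: WeightedNetwork) -> int:
    """Number of external proteins adjacent to at least half (⌈n/2⌉) of the
    complex's members."""
    ms = set(members)
    if len(ms) < 2:
        raise ValueError("need ≥2 members")
    need = math.ceil(len(ms) / 2)
    count = 0
    for v in ppi_net.nodes:
        if v in ms:
            continue
        links = sum(1 for m in ms if ppi_net.has_edge(v, m))
        if links >= need:
            count += 1
    return count


def _dens_bin(d: float) -> str:
    if d <= 0.35:
        return "low"
    if d <= 0.7:
        return "med"
    return "high"


def stratify(
    catalogue: ComplexCatalogue, ppi_net: WeightedNetwork
) -> dict[str, str]:
    """Assign each complex exactly one of the seven strata."""
    out: dict[str, str] = {}
    for name, members in catalogue:
        if len(members) <= 3:
            out[name] = "small"
            continue
        dens = _dens_bin(complex_dens(members, ppi_net))
        ext = "low" if complex_ext(members, ppi_net) <= 3 else "high"
        out[name] = f"dens_{dens}/ext_{ext}"
    return out


def best_match_scores(
    catalogue: ComplexCatalogue, clusters: list[Cluster], top_n: int = 1000
) -> dict[str, float]:
    """Best Jaccard between each reference complex and the top-n clusters
    (the per-complex match score used for stratified comparisons)."""
    ranked = sorted(clusters, key=lambda c: (-c.score, sorted(c.members)))[:top_n]
    out = {}
    for name, members in catalogue:
        out[name] = max(
            (jaccard(members, c.members) for c in ranked), default=0.0
        )
    return out


def semantic_coherence(
    members,
    ann_by_aspect: dict[str, OntologyAnnotation],
    direct_by_aspect: dict[str, dict[str, set[str]]],
) -> dict[str, float]:
    """Average pairwise semantic similarity of a protein set per GO aspect.

    Term information content is ``−ln(|ann(t)|/|ann(root)|)`` with
    propagated annotation counts; the similarity of two terms is the
    maximum IC over their common ancestors (most informative common
    ancestor), of two proteins the maximum over their annotated term pairs,
    and of the set the mean over unordered member pairs.  Pairs with no
    annotated terms in an aspect contribute 0.
    """
    ms = sorted(set(members))
    if len(ms) < 2:
        raise ValueError("need ≥2 members")
    out: dict[str, float] = {}
    for aspect, ann in ann_by_aspect.items():
        direct = direct_by_aspect[aspect]
        roots = ann.roots()
        root_count = max(
            (len(ann.ann(r)) for r in roots), default=0
        )
        if root_count == 0:
            out[aspect] = 0.0
            continue

        ic_cache: dict[str, float] = {}

        def ic(term: str) -> float:
            if term not in ic_cache:
                n = len(ann.ann(term))
                ic_cache[term] = -math.log(n / root_count) if n else 0.0
            return ic_cache[term]

        anc_cache: dict[str, set[str]] = {}

        def up(term: str) -> set[str]:
            if term not in anc_cache:
                anc_cache[term] = {term} | ann.ancestors(term)
            return anc_cache[term]

        def term_sim(t1: str, t2: str) -> float:
            common = up(t1) & up(t2)
            return max((ic(t) for t in common), default=0.0)

        def prot_terms(p: str) -> set[str]:
            return {t for t, prots in direct.items() if p in prots}

        total = 0.0
        pairs = 0
        for a, b in itertools.combinations(ms, 2):
            pairs += 1
            ta, tb = prot_terms(a), prot_terms(b)
            if not ta or not tb:
                continue
            total += max(term_sim(x, y) for x in ta for y in tb)
        out[aspect] = total / pairs if pairs else 0.0
    return out


def filter_novel(
    clusters: list[Cluster],
    references: ComplexCatalogue,
    precision_floor: float = 0.4,
    novel_sim: float = 0.5,
) -> list[Cluster]:
    """Keep novel, unique, high-confidence predictions.

    1. deduplicate mutually similar predictions (Jaccard ≥ ``novel_sim``),
       greedily keeping the highest-scoring;
    2. keep the largest score-ordered prefix whose precision against the
       references (Jaccard ≥ ``novel_sim``) exceeds ``precision_floor``;
    3. drop predictions that match a reference; the remainder is novel.
    """
    ranked = sorted(clusters, key=lambda c: (-c.score, sorted(c.members)))
    unique: list[Cluster] = []
    for c in ranked:
        if all(jaccard(c.members, u.members) < novel_sim for u in unique):
            unique.append(c)
    ref_sets = references.member_sets()

    def matches_ref(c: Cluster) -> bool:
        return any(jaccard(c.members, r) >= novel_sim for r in ref_sets)

    flags = [matches_ref(c) for c in unique]
    best_prefix = 0
    hits = 0
    for i, flag in enumerate(flags, start=1):
        hits += flag
        if hits / i > precision_floor:
            best_prefix = i
    if best_prefix == 0:
        logger.info("filter_novel: no prefix exceeds precision floor")
        return []
    return [c for c, flag in zip(unique[:best_prefix], flags) if not flag]
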