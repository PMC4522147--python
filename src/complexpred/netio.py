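"""Readers, writers and run configuration for complex-prediction pipelines.

All on-disk formats are plain tab-separated text:

* evidence files — ``a  b  method  pub  [score]`` (one detection event per row);
* scored-pair files — ``a  b  score`` (functional association, etc.);
* literature files — ``protein  paper1 paper2 ...`` (space-separated paper IDs);
* complex catalogues — ``name  member1 member2 ...``;
* cluster files — ``score  provenance  member1 member2 ...``.

Ontologies are read from OBO (via :mod:`obonet`) plus a GAF-style three-column
annotation table (``protein  term  aspect``).  Protein identifiers are opaque,
case-sensitive strings; no identifier mapping is performed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import yaml

logger = logging.getLogger("complexpred")

__all__ = [
    "ScoredPair",
    "EvidenceRecord",
    "ComplexCatalogue",
    "OntologyAnnotation",
    "RunConfig",
    "YEAST_PRESET",
    "HUMAN_PRESET",
    "canon",
    "read_evidence",
    "read_scored_pairs",
    "read_lit_papers",
    "read_complexes",
    "read_ontology_annotations",
    "write_clusters",
    "read_clusters",
    "write_scored_pairs",
]


def canon(a: str, b: str) -> tuple[str, str]:
    """Return the protein pair in canonical (lexicographic) order."""
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class ScoredPair:
    """A scored protein pair from one data source."""

    a: str
    b: str
    score: float

    def __post_init__(self):
        if self.a == self.b:
            raise ValueError(f"self-pair {self.a!r}")
        if not math.isfinite(self.score) or self.score < 0:
            raise ValueError(f"bad score {self.score!r} for ({self.a},{self.b})")
        if self.a > self.b:
            object.__setattr__(self, "a", self.b)
            object.__setattr__(self, "b", self.a)


@dataclass(frozen=True)
class EvidenceRecord:
    """One PPI detection event: pair, detection method, publication ID."""

    a: str
    b: str
    method: str
    pub: str

    def __post_init__(self):
        if self.a == self.b:
            raise ValueError(f"self-pair {self.a!r}")
        if self.a > self.b:
            a, b = self.b, self.a
            object.__setattr__(self, "a", a)
            object.__setattr__(self, "b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b)


@dataclass
class ComplexCatalogue:
    """A named catalogue of reference complexes (each ≥2 distinct members)."""

    complexes: list[tuple[str, frozenset[str]]] = field(default_factory=list)

    def __post_init__(self):
        names = [n for n, _ in self.complexes]
        if len(names) != len(set(names)):
            raise ValueError("duplicate complex names")
        for name, members in self.complexes:
            if len(members) < 2:
                raise ValueError(f"complex {name!r} has fewer than 2 members")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    def member_sets(self) -> list[frozenset[str]]:
        return [m for _, m in self.complexes]

    def subset(self, names: Iterable[str]) -> "ComplexCatalogue":
        keep = set(names)
        return ComplexCatalogue([(n, m) for n, m in self.complexes if n in keep])


class OntologyAnnotation:
    """A term DAG (is_a edges) with true-path-propagated protein annotations.

    ``dag`` is a directed graph with edges child → parent.  ``annotations``
    maps each term to the set of proteins annotated to it or to any of its
    descendants (the true-path rule).
    """

    def __init__(self, dag: nx.DiGraph, direct: Mapping[str, set[str]]):
        if not nx.is_directed_acyclic_graph(dag):
            raise ValueError("is_a graph contains a cycle; ontology must be a DAG")
        self.dag = dag
        self.annotations: dict[str, set[str]] = {t: set() for t in dag.nodes}
        for term, prots in direct.items():
            if term not in dag:
                continue
            self.annotations[term].update(prots)
            # child → parent edges: ancestors of `term` are its nx descendants
            for anc in nx.descendants(dag, term):
                self.annotations[anc].update(prots)

    def ann(self, term: str) -> set[str]:
        return self.annotations.get(term, set())

    def terms(self) -> list[str]:
        return sorted(self.dag.nodes)

    def roots(self) -> list[str]:
        return sorted(t for t in self.dag.nodes if self.dag.out_degree(t) == 0)

    def descendants(self, term: str) -> set[str]:
        """Terms below ``term`` in the ontology (its specialisations)."""
        return nx.ancestors(self.dag, term)

    def ancestors(self, term: str) -> set[str]:
        """Terms above ``term``, including all parents up to the root."""
        return nx.descendants(self.dag, term)

    def depth(self, term: str) -> int:
        """Shortest is_a path length from ``term`` up to a root."""
        best = math.inf
        for root in self.roots():
            try:
                best = min(best, nx.shortest_path_length(self.dag, term, root))
            except nx.NetworkXNoPath:
                continue
        return 0 if math.isinf(best) else int(best)

    def high_level_terms(self, max_depth: int = 2) -> set[str]:
        """CC-style high-level terms: depth ≤ ``max_depth`` below a root,
        excluding the roots themselves."""
        out = set()
        for t in self.dag.nodes:
            d = self.depth(t)
            if 0 < d <= max_depth:
                out.add(t)
        return out


@dataclass
class RunConfig:
    """Pipeline parameters.

    Defaults follow the yeast configuration; :data:`HUMAN_PRESET` switches the
    organism-specific values (hub threshold, GO decomposition size, score
    scale factors, large-complex match threshold).
    """

    k_large: int = 20000        # top-edge cutoff for SWC / DECOMP
    k_small: int = 10000        # top-edge cutoff for SSS
    n_hub: int = 50             # hub removal: degree > n_hub
    n_go: int = 300             # GO decomposition size threshold
    d: float = 0.6              # DECOMP score scale factor
    s: float = 1.0              # SSS score scale factor
    lg_match: float = 0.75      # Jaccard threshold matching large complexes
    sm_match: float = 1.0       # Jaccard threshold matching small complexes
    sim_threshold: float = 0.75 # cluster-similarity threshold for voting
    t_pct: float = 90.0         # percent of reference complexes held out as test
    bins: int = 10              # naive-Bayes discretisation bins
    lambda_nbc: int = 10        # NBC dampening factor
    hub_readd_frac: float = 0.5 # hub re-added if adjacent to ≥ this fraction
    mle: bool = False           # pure maximum-likelihood (no smoothing)
    seed: int = 0

    def __post_init__(self):
        for name in ("k_large", "k_small", "n_hub", "n_go", "bins", "lambda_nbc"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("lg_match", "sm_match", "sim_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0,1]")
        if not 0 < self.t_pct < 100:
            raise ValueError("t_pct must be in (0,100)")
        if self.d < 0 or self.s < 0:
            raise ValueError("scale factors d, s must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path, preset: str | None = None) -> "RunConfig":
        base = PRESETS[preset] if preset else cls()
        data = yaml.safe_load(Path(path).read_text()) or {}
        return replace(base, **data)


YEAST_PRESET = RunConfig()
HUMAN_PRESET = RunConfig(n_hub=150, n_go=1000, d=0.6, s=0.3, lg_match=0.5)
PRESETS = {"yeast": YEAST_PRESET, "human": HUMAN_PRESET}


# ---------------------------------------------------------------------------
# readers


def _binned_method(name: str, score: float) -> str:
    """Map a continuous score in [0,1] to a decile pseudo-method, bins
    numbered 1..10 (0–0.1 → 1, ..., 0.9–1.0 → 10)."""
    if not 0 <= score <= 1:
        raise ValueError(f"binned score {score} outside [0,1]")
    idx = min(int(score * 10) + 1, 10)
    return f"{name}_bin{idx}"


def read_evidence(path: str | Path) -> list[EvidenceRecord]:
    """Read PPI evidence rows ``a b method pub [score]``.

    Rows whose method label is ``BINNED:<name>`` carry a continuous score in
    a fifth column and are mapped to decile pseudo-methods ``<name>_bin1`` …
    ``<name>_bin10``.  Records are canonicalised and deduplicated on the
    full (a, b, method, pub) tuple; self-pairs are skipped with a warning.
    """
    records: dict[tuple, EvidenceRecord] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected ≥4 tab-separated fields")
            a, b, method, pub = fields[:4]
            if a == b:
                logger.warning("%s:%d: self-pair %r skipped", path, lineno, a)
                continue
            if method.startswith("BINNED:"):
                if len(fields) < 5:
                    raise ValueError(
                        f"{path}:{lineno}: BINNED method requires a score column"
                    )
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad score {fields[4]!r}") from exc
                method = _binned_method(method[len("BINNED:"):], score)
            rec = EvidenceRecord(a, b, method, pub)
            records[(rec.a, rec.b, rec.method, rec.pub)] = rec
    return sorted(records.values(), key=lambda r: (r.a, r.b, r.method, r.pub))


def read_scored_pairs(path: str | Path) -> list[ScoredPair]:
    """Read ``a b score`` rows into canonical scored pairs (last value wins
    on duplicate pairs)."""
    pairs: dict[tuple[str, str], ScoredPair] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            try:
                sp = ScoredPair(fields[0], fields[1], float(fields[2]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            pairs[(sp.a, sp.b)] = sp
    return sorted(pairs.values(), key=lambda p: (p.a, p.b))


def write_scored_pairs(pairs: Iterable[ScoredPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in sorted(pairs, key=lambda p: (p.a, p.b)):
            fh.write(f"{p.a}\t{p.b}\t{p.score:.6f}\n")


def read_lit_papers(path: str | Path) -> dict[str, set[str]]:
    """Read per-protein literature paper sets: ``protein  p1 p2 ...``."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 1 or not fields[0]:
                raise ValueError(f"{path}:{lineno}: missing protein identifier")
            papers = set(fields[1].split()) if len(fields) > 1 else set()
            out.setdefault(fields[0], set()).update(papers)
    return out


def read_complexes(path: str | Path) -> ComplexCatalogue:
    """Read a complex catalogue: one complex per line, ``name TAB members``."""
    complexes: list[tuple[str, frozenset[str]]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'name TAB members'")
            name = fields[0]
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate complex name {name!r}")
            members = frozenset(fields[1].split())
            if len(members) < 2:
                raise ValueError(
                    f"{path}:{lineno}: complex {name!r} has fewer than 2 members"
                )
            seen.add(name)
            complexes.append((name, members))
    return ComplexCatalogue(complexes)


def read_ontology_annotations(
    obo_path: str | Path, gaf_path: str | Path, aspect: str | None = None
) -> OntologyAnnotation:
    """Read an OBO ontology and a GAF-style ``protein term aspect`` table.

    Annotations are propagated to all ancestors (true-path rule); rows that
    reference obsolete or unknown terms are dropped with a log message.  If
    ``aspect`` is given, only rows with that aspect are used.
    """
    graph = obonet.read_obo(str(obo_path))
    dag = nx.DiGraph()
    dag.add_nodes_from(graph.nodes)
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            dag.add_edge(child, parent)
    direct: dict[str, set[str]] = {}
    with open(gaf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "!")):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{gaf_path}:{lineno}: expected 'protein term [aspect]'")
            protein, term = fields[0], fields[1]
            row_aspect = fields[2] if len(fields) > 2 else None
            if aspect is not None and row_aspect != aspect:
                continue
            if term not in dag:
                logger.info("%s:%d: unknown/obsolete term %s ignored", gaf_path, lineno, term)
                continue
            direct.setdefault(term, set()).add(protein)
    return OntologyAnnotation(dag, direct)


# ---------------------------------------------------------------------------
# cluster files


def write_clusters(clusters, path: str | Path) -> None:
    """Write ``score TAB provenance TAB members`` lines, best score first.

    Ties are broken by the lexicographic member list so output is
    byte-deterministic for a given cluster set.
    """
    rows = sorted(
        clusters,
        key=lambda c: (-c.score, sorted(c.members)),
    )
    with open(path, "w") as fh:
        for c in rows:
            fh.write(f"{c.score:.6f}\t{c.provenance}\t{' '.join(sorted(c.members))}\n")


def read_clusters(path: str | Path):
    """Read a cluster file written by :func:`write_clusters`."""
    from .clustering import Cluster

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            out.append(
                Cluster(frozenset(fields[2].split()), float(fields[0]), fields[1])
            )
    return out
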