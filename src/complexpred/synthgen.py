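"""Seeded generator of complete synthetic benchmark inputs.

The generator plants complexes in the four regimes the prediction system
targets and emits every input file the pipeline consumes, so all stages run
without any external download:

* **dense** — classic well-connected complexes (within-edge probability 0.9,
  density topped up to ≥0.75 so the regime is unambiguous);
* **sparse** — complexes with PPI density capped at 0.35 but strong
  functional-association and literature signal, the case supervised
  composite weighting is designed to recover;
* **embedded** — dense complexes plus ≥4 external proteins from *other*
  cellular compartments, each wired to at least half the members, the case
  GO decomposition is designed to demarcate;
* **small** — isolated size-2/3 cliques with no edges to the rest of the
  network, the size-specific branch's target.

Evidence records are sampled per detection method with method-specific
detection probabilities and unique publication IDs; association and
literature layers are generated conditionally on co-complex membership
(signal probability ≫ background), which is exactly the statistical
structure supervised weighting assumes.  A toy cellular-component ontology
(root → compartments → leaf blocks) annotates proteins such that each
planted complex lies within one leaf block.

All randomness flows from one :class:`numpy.random.Generator`; identical
configs and seeds produce byte-identical output files.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .netio import ComplexCatalogue

__all__ = ["SynthConfig", "SynthData", "generate", "summarize_truth"]


@dataclass
class SynthConfig:
    """Benchmark generator parameters (desk-scale defaults)."""

    n_proteins: int = 1000
    n_dense: int = 8
    n_sparse: int = 8
    n_embedded: int = 6
    n_small: int = 18
    large_size_min: int = 4
    large_size_max: int = 8
    p_within_dense: float = 0.9
    dens_floor_dense: float = 0.75
    p_within_sparse: float = 0.25
    dens_cap_sparse: float = 0.35
    n_ext_embedded: int = 5          # external proteins per embedded complex
    p_background: float = 0.004      # background PPI edge probability
    n_hubs: int = 5
    hub_degree: int = 80
    #: detection probability per method per true edge (two draws each)
    methods: dict = field(
        default_factory=lambda: {"tap": 0.7, "y2h": 0.55, "coip": 0.45}
    )
    p_string_signal: float = 0.9     # association edge for a co-complex pair
    p_string_background: float = 0.002
    p_lit_member: float = 0.85       # complex member appears in a complex paper
    papers_per_complex: int = 3
    solo_papers_max: int = 3
    n_compartments: int = 4
    leaves_per_compartment: int = 2
    seed: int = 0

    def __post_init__(self):
        for name in (
            "p_within_dense", "p_within_sparse", "p_background",
            "p_string_signal", "p_string_background", "p_lit_member",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0,1]")
        demand = (
            (self.n_dense + self.n_sparse + self.n_embedded)
            * self.large_size_max
            + self.n_small * 3 + self.n_hubs
        )
        if demand > self.n_proteins:
            raise ValueError(
                f"config infeasible: needs ≥{demand} proteins, has {self.n_proteins}"
            )


@dataclass
class SynthData:
    """Generated benchmark: file paths plus in-memory ground truth."""

    evidence_path: Path
    string_path: Path
    lit_path: Path
    obo_path: Path
    gaf_path: Path
    truth_path: Path
    truth: ComplexCatalogue
    truth_net: nx.Graph          # the planted PPI network (unweighted truth)
    regimes: dict[str, str]      # complex name -> regime


def _top_up_density(rng, members, edges, floor):
    possible = list(itertools.combinations(members, 2))
    need = math.ceil(floor * len(possible))
    missing = [p for p in possible if p not in edges]
    while len(edges) < need and missing:
        i = rng.integers(len(missing))
        edges.add(missing.pop(int(i)))
    return edges


def _cap_density(rng, members, edges, cap):
    possible = len(members) * (len(members) - 1) // 2
    allowed = math.floor(cap * possible)
    edges = sorted(edges)
    while len(edges) > allowed:
        i = rng.integers(len(edges))
        edges.pop(int(i))
    return set(edges)


def generate(config: SynthConfig, outdir: str | Path) -> SynthData:
    """Write the five input files plus the truth catalogue to ``outdir``."""
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteins = [f"P{i:04d}" for i in range(config.n_proteins)]

    # --- protein assignment: complexes first (disjoint), then hubs ---
    pool = list(proteins)
    complexes: list[tuple[str, list[str]]] = []
    regimes: dict[str, str] = {}

    def take(n: int) -> list[str]:
        idx = rng.choice(len(pool), size=n, replace=False)
        chosen = [pool[int(i)] for i in sorted(idx, reverse=True)]
        for i in sorted(idx, reverse=True):
            pool.pop(int(i))
        return sorted(chosen)

    for regime, count in (
        ("dense", config.n_dense),
        ("sparse", config.n_sparse),
        ("embedded", config.n_embedded),
    ):
        for j in range(count):
            size = int(rng.integers(config.large_size_min, config.large_size_max + 1))
            name = f"{regime}_{j}"
            complexes.append((name, take(size)))
            regimes[name] = regime
    for j in range(config.n_small):
        size = int(rng.integers(2, 4))
        name = f"small_{j}"
        complexes.append((name, take(size)))
        regimes[name] = "small"
    hubs = take(config.n_hubs)
    small_members = {
        p for name, ms in complexes if regimes[name] == "small" for p in ms
    }

    # --- ontology blocks: complexes placed whole into leaf blocks ---
    n_leaves = config.n_compartments * config.leaves_per_compartment
    leaf_of: dict[str, int] = {}
    for i, (name, ms) in enumerate(complexes):
        leaf = i % n_leaves
        for p in ms:
            leaf_of[p] = leaf
    rest = sorted(set(proteins) - set(leaf_of))
    for p in rest:
        leaf_of[p] = int(rng.integers(n_leaves))
    compartment_of = {p: leaf_of[p] // config.leaves_per_compartment for p in proteins}

    # --- truth PPI network ---
    truth_net = nx.Graph()
    truth_net.add_nodes_from(proteins)
    internal_edges: dict[str, set[tuple[str, str]]] = {}
    for name, ms in complexes:
        regime = regimes[name]
        edges: set[tuple[str, str]] = set()
        if regime == "small":
            edges = set(itertools.combinations(ms, 2))  # isolated clique
        else:
            p_in = (
                config.p_within_sparse if regime == "sparse"
                else config.p_within_dense
            )
            for pair in itertools.combinations(ms, 2):
                if rng.random() < p_in:
                    edges.add(pair)
            if regime in ("dense", "embedded"):
                edges = _top_up_density(rng, ms, edges, config.dens_floor_dense)
            else:
                edges = _cap_density(rng, ms, edges, config.dens_cap_sparse)
        internal_edges[name] = edges
        truth_net.add_edges_from(edges)

    # embedded complexes: wire externals from other compartments to ≥ half
    ext_edges: set[tuple[str, str]] = set()
    for name, ms in complexes:
        if regimes[name] != "embedded":
            continue
        own = compartment_of[ms[0]]
        candidates = [
            p for p in sorted(set(proteins) - set(ms) - small_members - set(hubs))
            if compartment_of[p] != own
        ]
        idx = rng.choice(len(candidates), size=config.n_ext_embedded, replace=False)
        need = math.ceil(len(ms) / 2)
        for i in sorted(int(x) for x in idx):
            ext = candidates[i]
            targets = rng.choice(len(ms), size=min(need + 1, len(ms)), replace=False)
            for t in sorted(int(x) for x in targets):
                ext_edges.add(tuple(sorted((ext, ms[t]))))
    truth_net.add_edges_from(ext_edges)

    # background edges and hubs (never touching isolated small complexes)
    eligible = sorted(set(proteins) - small_members)
    n_bg = rng.binomial(
        len(eligible) * (len(eligible) - 1) // 2, config.p_background
    )
    for _ in range(int(n_bg)):
        i, j = rng.choice(len(eligible), size=2, replace=False)
        truth_net.add_edge(*sorted((eligible[int(i)], eligible[int(j)])))
    non_hub = [p for p in eligible if p not in hubs]
    for h in hubs:
        idx = rng.choice(len(non_hub), size=config.hub_degree, replace=False)
        for i in sorted(int(x) for x in idx):
            truth_net.add_edge(*sorted((h, non_hub[i])))

    # --- evidence records ---
    pub_counter = itertools.count(1)
    evidence_rows: list[str] = []
    edges_sorted = sorted(tuple(sorted(e)) for e in truth_net.edges)
    for a, b in edges_sorted:
        for method in sorted(config.methods):
            n_det = int(rng.binomial(2, config.methods[method]))
            for _ in range(n_det):
                evidence_rows.append(
                    f"{a}\t{b}\t{method}\tPMID{next(pub_counter):06d}"
                )
    evidence_path = outdir / "evidence.tsv"
    evidence_path.write_text("\n".join(evidence_rows) + "\n")

    # --- association (STRING-like) layer ---
    co_pairs = sorted(
        {tuple(sorted(p)) for _, ms in complexes for p in itertools.combinations(ms, 2)}
    )
    co_set = set(co_pairs)
    string_rows = []
    for a, b in co_pairs:
        if rng.random() < config.p_string_signal:
            score = rng.uniform(0.6, 0.95)
            string_rows.append(f"{a}\t{b}\t{score:.4f}")
    n_bg_string = rng.binomial(
        len(eligible) * (len(eligible) - 1) // 2, config.p_string_background
    )
    for _ in range(int(n_bg_string)):
        i, j = rng.choice(len(eligible), size=2, replace=False)
        a, b = sorted((eligible[int(i)], eligible[int(j)]))
        if (a, b) in co_set:
            continue
        score = rng.uniform(0.51, 0.85)
        string_rows.append(f"{a}\t{b}\t{score:.4f}")
    string_path = outdir / "string.tsv"
    string_path.write_text("\n".join(string_rows) + "\n")

    # --- literature layer: complex papers + solo papers ---
    papers: dict[str, set[str]] = {p: set() for p in proteins}
    paper_counter = itertools.count(1)
    for name, ms in complexes:
        for _ in range(config.papers_per_complex):
            pid = f"LP{next(paper_counter):05d}"
            for p in ms:
                if rng.random() < config.p_lit_member:
                    papers[p].add(pid)
    for p in proteins:
        for _ in range(int(rng.integers(1, config.solo_papers_max + 1))):
            papers[p].add(f"LP{next(paper_counter):05d}")
    # literature noise: random non-small pairs co-mentioned in one paper
    for _ in range(len(eligible) // 3):
        i, j = rng.choice(len(eligible), size=2, replace=False)
        pid = f"LP{next(paper_counter):05d}"
        papers[eligible[int(i)]].add(pid)
        papers[eligible[int(j)]].add(pid)
    lit_rows = [
        f"{p}\t{' '.join(sorted(papers[p]))}" for p in proteins if papers[p]
    ]
    lit_path = outdir / "lit.tsv"
    lit_path.write_text("\n".join(lit_rows) + "\n")

    # --- toy cellular-component ontology + annotations ---
    obo_lines = ["format-version: 1.2", "ontology: cc", ""]

    def term_id(n: int) -> str:
        return f"CC:{n:07d}"

    root = term_id(1)
    obo_lines += [f"[Term]", f"id: {root}", "name: cellular_component", ""]
    leaf_terms: list[str] = []
    tid = itertools.count(2)
    for c in range(config.n_compartments):
        comp_term = term_id(next(tid))
        obo_lines += [
            "[Term]", f"id: {comp_term}", f"name: compartment_{c}",
            f"is_a: {root} ! cellular_component", "",
        ]
        for l in range(config.leaves_per_compartment):
            leaf_term = term_id(next(tid))
            leaf_terms.append(leaf_term)
            obo_lines += [
                "[Term]", f"id: {leaf_term}", f"name: block_{c}_{l}",
                f"is_a: {comp_term} ! compartment_{c}", "",
            ]
    obo_path = outdir / "cc.obo"
    obo_path.write_text("\n".join(obo_lines))
    gaf_rows = [f"{p}\t{leaf_terms[leaf_of[p]]}\tC" for p in proteins]
    gaf_path = outdir / "cc.gaf"
    gaf_path.write_text("\n".join(gaf_rows) + "\n")

    # --- truth catalogue ---
    truth = ComplexCatalogue(
        [(name, frozenset(ms)) for name, ms in complexes]
    )
    truth_path = outdir / "truth_complexes.tsv"
    truth_path.write_text(
        "\n".join(f"{name}\t{' '.join(sorted(ms))}" for name, ms in complexes)
        + "\n"
    )
    return SynthData(
        evidence_path, string_path, lit_path, obo_path, gaf_path, truth_path,
        truth, truth_net, regimes,
    )


def summarize_truth(truth: ComplexCatalogue, ppi_net: nx.Graph) -> dict[str, int]:
    """Count planted complexes per evaluation stratum."""
    from .evaluation import STRATA, stratify

    counts = {s: 0 for s in STRATA}
    for _, stratum in stratify(truth, ppi_net).items():
        counts[stratum] += 1
    return counts
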