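"""Synthetic end-to-end benchmark driver.

One replicate generates a fresh benchmark (1,000 proteins, planted dense /
sparse / embedded / small complexes), splits the planted catalogue into
training and test halves (stratified by regime so every regime is both
trained on and tested), runs the three prediction branches, their
integration and the reliability-only baseline, and measures:

* mean best-match Jaccard per planted regime for each approach;
* exact-match precision/recall of the small-complex branch among small
  predictions;
* each approach's precision-recall curve against the test complexes.

The per-replicate problem size (~2,500 PPI edges, ~4,000 feature rows) is
chosen so a full multi-replicate run completes in minutes on one CPU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .evaluation import (
    EvalPoint,
    MatchRule,
    best_match_scores,
    precision_recall,
)
from .features import (
    build_feature_table,
    lit_jaccard,
    method_reliability,
    ppi_reliability,
    string_filter,
)
from .netio import ComplexCatalogue, RunConfig, read_evidence, read_lit_papers, read_scored_pairs, read_ontology_annotations
from .pipeline import integrated_pipeline, ppi_combine_pipeline
from .synthgen import SynthConfig, generate

logger = logging.getLogger("complexpred")

__all__ = ["ReplicateResult", "split_catalogue", "run_replicate"]


@dataclass
class ReplicateResult:
    seed: int
    #: approach -> regime -> mean best-match Jaccard over test complexes
    best_match: dict[str, dict[str, float]] = field(default_factory=dict)
    #: approach -> PR curve on the full test catalogue
    curves: dict[str, list[EvalPoint]] = field(default_factory=dict)
    #: small-complex branch: best exact-match recall at precision ≥ floor
    sss_small_recall_at_precision: float = 0.0
    sss_small_best_precision: float = 0.0
    clusters: dict[str, list] = field(default_factory=dict)


def split_catalogue(
    truth: ComplexCatalogue, regimes: dict[str, str]
) -> tuple[ComplexCatalogue, ComplexCatalogue]:
    """Deterministic stratified 50/50 train/test split by regime."""
    train_names, test_names = [], []
    by_regime: dict[str, list[str]] = {}
    for name, _ in truth:
        by_regime.setdefault(regimes[name], []).append(name)
    for regime in sorted(by_regime):
        names = sorted(by_regime[regime])
        for i, name in enumerate(names):
            (train_names if i % 2 == 0 else test_names).append(name)
    return truth.subset(train_names), truth.subset(test_names)


def _recall_at_precision(points: list[EvalPoint], floor: float) -> float:
    return max((p.recall for p in points if p.precision >= floor), default=0.0)


def run_replicate(
    seed: int,
    workdir,
    config: RunConfig | None = None,
    synth_config: SynthConfig | None = None,
    precision_floor: float = 0.8,
) -> ReplicateResult:
    """Generate, predict and evaluate one benchmark replicate."""
    config = config or RunConfig()
    synth_config = synth_config or SynthConfig(seed=seed)
    data = generate(synth_config, workdir)
    evidence = read_evidence(data.evidence_path)
    cc = read_ontology_annotations(data.obo_path, data.gaf_path)
    rel = method_reliability(evidence, cc, cc.high_level_terms())
    ppi = ppi_reliability(evidence, rel)
    string_net = string_filter(read_scored_pairs(data.string_path))
    lit_net = lit_jaccard(read_lit_papers(data.lit_path))
    swc_table = build_feature_table(ppi, string_net, lit_net, "SWC", config.lambda_nbc)
    sss_table = build_feature_table(ppi, string_net, lit_net, "SSS", config.lambda_nbc)
    train, test = split_catalogue(data.truth, data.regimes)

    results = integrated_pipeline(swc_table, sss_table, ppi, cc, train, config)
    results["baseline"] = ppi_combine_pipeline(ppi, config)

    rule = MatchRule(config.lg_match, config.sm_match)
    out = ReplicateResult(seed=seed, clusters=results)
    for approach, clusters in results.items():
        bm = best_match_scores(test, clusters)
        per_regime: dict[str, list[float]] = {}
        for name, score in bm.items():
            per_regime.setdefault(data.regimes[name], []).append(score)
        out.best_match[approach] = {
            regime: sum(v) / len(v) for regime, v in sorted(per_regime.items())
        }
        out.curves[approach] = precision_recall(clusters, test, train, rule)

    # small-complex branch measured on small test complexes only, exact match
    small_test = test.subset(
        [n for n, m in test if len(m) <= 3]
    )
    small_points = precision_recall(results["sss"], small_test, train, rule)
    out.sss_small_recall_at_precision = _recall_at_precision(
        small_points, precision_floor
    )
    out.sss_small_best_precision = max(
        (p.precision for p in small_points), default=0.0
    )
    return out
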