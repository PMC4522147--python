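"""End-to-end pipeline drivers.

The integrated system runs three branches independently on the same inputs
and merges their cluster sets:

* SWC — supervised co-complex weighting of the composite network, then
  multi-algorithm clustering with majority voting (large clusters only);
* DECOMP — hub removal + GO decomposition of the reliability-weighted PPI
  network, then clustering with voting (large clusters only);
* SSS — size-specific 3-class weighting and small-cluster extraction.

A reliability-only baseline (clustering the PPI network without supervised
weighting or decomposition) is included for benchmark comparisons.
"""

from __future__ import annotations

import logging

import pandas as pd

from .clustering import Cluster, run_algorithms
from .combine import combine_votes, integrate
from .decomp import decomp_pipeline
from .features import WeightedNetwork
from .netio import ComplexCatalogue, OntologyAnnotation, RunConfig
from .small_complexes import sss_pipeline
from .supervised_weighting import fit_nb, label_edges, posterior_weight, top_k_edges

logger = logging.getLogger("complexpred")

DEFAULT_ALGORITHMS = ["mcl", "cmc", "clusterone", "coach"]

__all__ = [
    "DEFAULT_ALGORITHMS",
    "swc_pipeline",
    "ppi_combine_pipeline",
    "integrated_pipeline",
]


def swc_pipeline(
    feature_table: pd.DataFrame,
    training: ComplexCatalogue,
    config: RunConfig,
    algorithms: list[str] | None = None,
) -> list[Cluster]:
    """SWC branch: co-complex posterior weighting → top-k edges →
    multi-algorithm clustering → majority voting → size ≥4 filter."""
    algorithms = algorithms or DEFAULT_ALGORITHMS
    labels = label_edges(feature_table, training, mode="SWC")
    model = fit_nb(feature_table, labels, bins=config.bins, mle=config.mle)
    post = posterior_weight(model, feature_table)
    weights = dict(zip(post.index, post["co"]))
    net = top_k_edges(weights, config.k_large)
    sets = run_algorithms(net, algorithms)
    combined = combine_votes(
        sets, net, n_algorithms=len(algorithms),
        sim_threshold=config.sim_threshold, provenance="swc",
    )
    return [c for c in combined if c.size >= 4]


def ppi_combine_pipeline(
    ppi_net: WeightedNetwork,
    config: RunConfig,
    algorithms: list[str] | None = None,
    min_size: int = 2,
) -> list[Cluster]:
    """Baseline: cluster the reliability-weighted PPI network directly and
    aggregate with majority voting (no supervised weighting, no
    decomposition)."""
    algorithms = algorithms or DEFAULT_ALGORITHMS
    weights = {
        tuple(sorted((u, v))): d["weight"] for u, v, d in ppi_net.edges(data=True)
    }
    net = top_k_edges(weights, config.k_large)
    sets = run_algorithms(net, algorithms)
    combined = combine_votes(
        sets, net, n_algorithms=len(algorithms),
        sim_threshold=config.sim_threshold, provenance="ppi+combine",
    )
    return [c for c in combined if c.size >= min_size]


def integrated_pipeline(
    swc_table: pd.DataFrame,
    sss_table: pd.DataFrame,
    ppi_net: WeightedNetwork,
    ann: OntologyAnnotation,
    training: ComplexCatalogue,
    config: RunConfig,
    algorithms: list[str] | None = None,
) -> dict[str, list[Cluster]]:
    """Run all three branches and integrate their cluster sets.

    Returns the per-branch cluster sets under ``"swc"``, ``"decomp"``,
    ``"sss"`` and the scale-and-sum integration under ``"integrated"``.
    """
    algorithms = algorithms or DEFAULT_ALGORITHMS
    swc = swc_pipeline(swc_table, training, config, algorithms)
    dec = decomp_pipeline(ppi_net, ann, config, algorithms)
    # SSS isolation/boundary structure lives on the composite network (every
    # pair scored by any source), not the PPI network alone
    sss = sss_pipeline(sss_table, training, config)
    merged = integrate(
        swc, dec, sss, d=config.d, s=config.s,
        sim_threshold=config.sim_threshold,
    )
    return {"swc": swc, "decomp": dec, "sss": sss, "integrated": merged}
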