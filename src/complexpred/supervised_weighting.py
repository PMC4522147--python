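"""Supervised edge weighting with a discretised naive-Bayes model.

Edges are labelled from training complexes (*co-complex* vs *non-co-complex*;
in size-specific mode the co-complex class splits into *small_co* for
complexes of ≤3 proteins and *large_co* otherwise).  Each feature is
discretised into equal-frequency bins, class-conditional bin frequencies are
estimated, and every edge is re-weighted with its class posterior
probabilities.  The top-k posterior-weighted edges feed the clustering stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import WeightedNetwork, network_from_weights
from .netio import ComplexCatalogue

logger = logging.getLogger("complexpred")

__all__ = ["NBModel", "label_edges", "fit_nb", "posterior_weight", "top_k_edges"]

SWC_CLASSES = ("co", "non")
SSS_CLASSES = ("small_co", "large_co", "non")

_FLOOR = 1e-12


def label_edges(
    table: pd.DataFrame, training: ComplexCatalogue, mode: str = "SWC"
) -> pd.Series:
    """Label every feature-table row from the training complexes.

    A pair is *co* iff both proteins co-occur in some training complex.  In
    SSS mode co-complex pairs are split by the size of that complex
    (small ≤ 3 members); a pair found in both a small and a large training
    complex is labelled ``small_co``.
    """
    if mode not in ("SWC", "SSS"):
        raise ValueError(f"mode must be SWC or SSS, got {mode!r}")
    small_pairs: set[tuple[str, str]] = set()
    large_pairs: set[tuple[str, str]] = set()
    for _, members in training:
        ms = sorted(members)
        target = small_pairs if len(ms) <= 3 else large_pairs
        for i, a in enumerate(ms):
            for b in ms[i + 1:]:
                target.add((a, b))
    labels = []
    for pair in table.index:
        if pair in small_pairs:
            labels.append("small_co" if mode == "SSS" else "co")
        elif pair in large_pairs:
            labels.append("large_co" if mode == "SSS" else "co")
        else:
            labels.append("non")
    out = pd.Series(labels, index=table.index, name="label")
    counts = out.value_counts()
    logger.info("edge labels: %s", counts.to_dict())
    positives = counts.drop("non", errors="ignore").sum()
    if positives == 0:
        raise ValueError("degenerate training set: no co-complex edge in table")
    if mode == "SSS" and counts.get("small_co", 0) == 0:
        raise ValueError("degenerate training set: no small-co-complex edge")
    return out


@dataclass
class NBModel:
    """Binned naive-Bayes model: class priors and per-feature bin likelihoods.

    ``bin_edges[f]`` holds interior cut points for the positive-value bins of
    feature *f*; the value 0 always occupies its own lowest bin (missing
    values are encoded as 0).  ``likelihoods[f]`` is a (n_bins, n_classes)
    array of within-class bin frequencies.
    """

    classes: tuple[str, ...]
    priors: dict[str, float]
    bin_edges: dict[str, np.ndarray]
    likelihoods: dict[str, np.ndarray]

    def bin_index(self, feature: str, values: np.ndarray) -> np.ndarray:
        edges = self.bin_edges[feature]
        idx = np.zeros(len(values), dtype=int)
        pos = values > 0
        # bin 0 is the zero/missing bin; positive bins start at 1
        idx[pos] = 1 + np.searchsorted(edges, values[pos], side="right")
        n_bins = self.likelihoods[feature].shape[0]
        return np.clip(idx, 0, n_bins - 1)


def _positive_bin_edges(values: np.ndarray, bins: int) -> np.ndarray:
    """Interior cut points for the positive-value bins of one feature.

    Features on the unit interval (data-source scores, shared-neighbour and
    connectivity ratios, isolatedness) are probability-like: their absolute
    scale is meaningful and their positive mass is often extremely skewed,
    which collapses quantile cuts — so they get equal-width cuts on (0, 1].
    Unbounded features (the degree sums) have arbitrary scale and get
    equal-frequency (quantile) cuts.
    """
    pos = values[values > 0]
    if len(pos) == 0 or bins <= 2:
        return np.array([])
    if pos.max() <= 1.0:
        return np.linspace(0.0, 1.0, bins)[1:-1]
    qs = np.linspace(0, 1, bins)[1:-1]  # bins-1 positive bins
    return np.unique(np.quantile(pos, qs))


def fit_nb(
    table: pd.DataFrame,
    labels: pd.Series,
    bins: int = 10,
    mle: bool = False,
) -> NBModel:
    """Fit the maximum-likelihood naive-Bayes model.

    Each feature is discretised into ``bins`` bins: a dedicated bin for the
    value 0 plus equal-frequency bins over the positive values (computed on
    all edges, unsupervised).  Priors are class frequencies; likelihoods are
    within-class bin frequencies, by default with add-one smoothing over
    bins so unseen bins never zero out a posterior (set ``mle=True`` for the
    unsmoothed estimate, floored at a tiny epsilon).
    """
    present = set(labels)
    classes = tuple(
        c for c in ("co", "small_co", "large_co", "non") if c in present
    )
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to fit")
    y = labels.to_numpy()
    n = len(y)
    priors = {c: float((y == c).sum()) / n for c in classes}
    bin_edges: dict[str, np.ndarray] = {}
    likelihoods: dict[str, np.ndarray] = {}
    for feature in table.columns:
        values = table[feature].to_numpy(dtype=float)
        edges = _positive_bin_edges(values, bins)
        n_bins = len(edges) + 2  # zero bin + positive bins
        model_stub = NBModel(classes, priors, {feature: edges},
                             {feature: np.zeros((n_bins, len(classes)))})
        idx = model_stub.bin_index(feature, values)
        lik = np.zeros((n_bins, len(classes)))
        for j, c in enumerate(classes):
            counts = np.bincount(idx[y == c], minlength=n_bins).astype(float)
            total = counts.sum()
            if mle:
                lik[:, j] = np.maximum(counts / max(total, 1.0), _FLOOR)
            else:
                lik[:, j] = (counts + 1.0) / (total + n_bins)
        bin_edges[feature] = edges
        likelihoods[feature] = lik
    return NBModel(classes, priors, bin_edges, likelihoods)


def posterior_weight(model: NBModel, table: pd.DataFrame) -> pd.DataFrame:
    """Posterior class probabilities per edge (rows sum to 1).

    Values outside the fitted range fall into the nearest boundary bin.
    """
    n = len(table)
    log_post = np.zeros((n, len(model.classes)))
    for j, c in enumerate(model.classes):
        log_post[:, j] = math.log(max(model.priors[c], _FLOOR))
    for feature in table.columns:
        if feature not in model.likelihoods:
            raise KeyError(f"model was not fitted on feature {feature!r}")
        idx = model.bin_index(feature, table[feature].to_numpy(dtype=float))
        log_post += np.log(np.maximum(model.likelihoods[feature][idx, :], _FLOOR))
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    return pd.DataFrame(post, index=table.index, columns=list(model.classes))


def top_k_edges(weights: dict[tuple[str, str], float], k: int) -> WeightedNetwork:
    """Keep the k highest-weight edges (ties at the cutoff broken by
    lexicographic pair order, so selection is deterministic and nested in k)."""
    if k < 1:
        raise ValueError("k must be ≥ 1")
    ranked = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
    return network_from_weights(dict(ranked[:k]))
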