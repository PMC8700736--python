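"""ReliefF feature weighting and the iterative ReliefF (IRF) selector.

ReliefF scores each feature by how well it separates nearby instances of
different classes while staying stable among nearby instances of the same
class: for every instance the k nearest same-class neighbours (hits) and the
k nearest neighbours in each other class (misses) are found, and the weight
of a feature is decreased by its mean hit difference and increased by the
class-prior-weighted mean miss difference.  Differences are normalized by
each feature's observed range, so weights live in [-1, 1] and a constant
feature scores exactly 0.

IRF wraps ReliefF in a model-selection loop: the features are ranked once,
then every prefix length in a range is scored by a classifier loss and the
minimum-loss prefix is kept, breaking ties toward the shorter subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .features import LabeledFeatureMatrix


@dataclass
class ReliefFWeights:
    """Per-feature ReliefF weights plus the settings that produced them."""

    weights: np.ndarray
    k: int
    m: int
    feature_range: np.ndarray


@dataclass
class RankedIndices:
    """Feature indices sorted by descending ReliefF weight.

    Ties are broken toward the smaller column index so that rankings are
    reproducible.
    """

    order: np.ndarray
    weights: ReliefFWeights


@dataclass
class IRFResult:
    """Outcome of the iterative ReliefF sweep over candidate subset lengths."""

    candidate_lengths: np.ndarray
    losses: np.ndarray
    best_length: int
    selected: np.ndarray
    ranking: RankedIndices


def relieff_weights(data: LabeledFeatureMatrix, k: int = 10) -> ReliefFWeights:
    """Multiclass ReliefF weights using every instance (m = n).

    Distances between instances are Manhattan distances on range-normalized
    features.  Each instance contributes its k nearest hits and, per other
    class, its k nearest misses; miss contributions are weighted by
    P(C) / (1 - P(class(instance))).  Requires every class to have at least
    k + 1 members so hits exist.
    """
    X, y = data.X, data.y
    n, p = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    classes, counts = np.unique(y, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < k + 1:
            raise ValueError(
                f"class {cls!r} has {cnt} members; needs >= {k + 1} "
                f"to find {k} nearest hits"
            )
    rng_ = X.max(axis=0) - X.min(axis=0)
    # constant features: define diff = 0 (range set to 1 to avoid 0/0)
    safe_range = np.where(rng_ > 0, rng_, 1.0)
    Xn = X / safe_range
    Xn[:, rng_ == 0] = 0.0

    priors = {cls: cnt / n for cls, cnt in zip(classes, counts)}
    W = np.zeros(p)
    for i in range(n):
        diffs = np.abs(Xn - Xn[i])          # (n, p) per-feature diffs
        dist = diffs.sum(axis=1)            # Manhattan distance
        same = y == y[i]
        # hits: k nearest same-class neighbours, excluding self
        hit_idx = np.where(same)[0]
        hit_idx = hit_idx[hit_idx != i]
        hit_idx = hit_idx[np.argsort(dist[hit_idx], kind="stable")[:k]]
        W -= diffs[hit_idx].mean(axis=0) / n
        # misses: k nearest per other class, prior-weighted
        denom = 1.0 - priors[y[i]]
        for cls in classes:
            if cls == y[i]:
                continue
            miss_idx = np.where(y == cls)[0]
            miss_idx = miss_idx[np.argsort(dist[miss_idx], kind="stable")[:k]]
            W += (priors[cls] / denom) * diffs[miss_idx].mean(axis=0) / n
    return ReliefFWeights(weights=W, k=k, m=n, feature_range=rng_)


def rank_features(data: LabeledFeatureMatrix, k: int = 10) -> RankedIndices:
    """Rank features by descending ReliefF weight (stable on ties)."""
    w = relieff_weights(data, k=k)
    order = np.argsort(-w.weights, kind="stable")
    return RankedIndices(order=order, weights=w)


def select_top(data: LabeledFeatureMatrix, ranking: RankedIndices,
               n_keep: int) -> LabeledFeatureMatrix:
    """Keep the n_keep best-ranked columns, in ranked order.

    Labels are unchanged and provenance is carried through.  Asking for more
    columns than exist is an error — callers clamp explicitly.
    """
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    if n_keep > data.p:
        raise ValueError(
            f"n_keep={n_keep} exceeds available feature count {data.p}"
        )
    cols = ranking.order[:n_keep]
    prov = [data.provenance[j] for j in cols] if data.provenance else []
    return LabeledFeatureMatrix(X=data.X[:, cols], y=data.y, provenance=prov)


def irf_select(data: LabeledFeatureMatrix,
               loss_fn: Callable[[LabeledFeatureMatrix], float],
               range_lo: int = 100, range_hi: int = 1000,
               k: int = 10) -> IRFResult:
    """Iterative ReliefF: score every ranked prefix length, keep the argmin.

    The ReliefF ranking is computed once on the full matrix; for each length
    l in [range_lo, range_hi] (unit step) the top-l columns are scored by
    ``loss_fn`` (a misclassification rate in [0, 1]).  The minimum-loss
    length wins; ties break toward the smaller length.
    """
    if not (1 <= range_lo <= range_hi <= data.p):
        raise ValueError(
            f"need 1 <= range_lo <= range_hi <= p; "
            f"got [{range_lo}, {range_hi}] with p={data.p}"
        )
    ranking = rank_features(data, k=k)
    lengths = np.arange(range_lo, range_hi + 1)
    losses = np.empty(lengths.shape[0])
    for t, length in enumerate(lengths):
        subset = select_top(data, ranking, int(length))
        loss = float(loss_fn(subset))
        if not np.isfinite(loss):
            raise ValueError(
                f"loss function returned non-finite value at length {length}"
            )
        losses[t] = loss
    best_t = int(np.argmin(losses))   # argmin takes the first = smallest length
    best_length = int(lengths[best_t])
    return IRFResult(
        candidate_lengths=lengths,
        losses=losses,
        best_length=best_length,
        selected=ranking.order[:best_length].copy(),
        ranking=ranking,
    )
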