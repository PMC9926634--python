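"""Shapley value sampling and view-level attribution aggregation.

Shapley sampling estimates per-feature attributions model-agnostically:
features are added one by one to a baseline input in a random order, the
change in model output when a feature flips from its baseline to its actual
value is recorded, and the mean over random orders is the attribution.  At
full enumeration of orders this is the exact Shapley value.

Because per-gene attributions of thousands of correlated inputs are hard to
interpret, attributions are aggregated to the view (omics) level: the
normalized per-view *sum* measures a view's total influence, the per-view
*mean* the average influence of one of its features.  Normalization divides
by the total absolute attribution, so view sums are nonnegative and total 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _permutations

import numpy as np

from .architectures import TrainedModel

__all__ = ["AttributionReport", "shapley_sampling", "aggregate_views", "attribute_model"]


@dataclass(frozen=True)
class AttributionReport:
    """Per-feature attributions plus normalized per-view summaries."""

    view_names: tuple[str, ...]
    view_boundaries: tuple[int, ...]  # cumulative feature offsets, len = n_views + 1
    attributions: np.ndarray          # samples × total features (raw, signed)
    view_sums: np.ndarray             # normalized, totals 1
    view_means: np.ndarray            # view sum / view feature count
    signed: bool = False

    def summary(self) -> dict[str, dict[str, float]]:
        return {
            name: {"sum": float(s), "mean": float(m)}
            for name, s, m in zip(self.view_names, self.view_sums, self.view_means)
        }


def shapley_sampling(predict: TrainedModel | callable, samples: np.ndarray,
                     baseline: np.ndarray, n_permutations: int = 50,
                     seed: int = 0, exhaustive: bool = False) -> np.ndarray:
    """Estimate per-feature Shapley attributions for each sample.

    ``predict`` maps a samples × features matrix to one score per sample
    (a fitted :class:`TrainedModel` is accepted and queried through its
    concatenated-feature interface).  ``baseline`` is one reference input
    (all zeros is the customary choice here: the off state of binary views,
    the mean of standardized expression).  ``n_permutations`` random feature
    orders are averaged (50 by default); ``exhaustive=True`` replaces them
    with all d! orders for exact values on small d.
    """
    f = predict.predict_concat if isinstance(predict, TrainedModel) else predict
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    base = np.asarray(baseline, dtype=float).reshape(-1)
    n, d = X.shape
    if base.shape[0] != d:
        raise ValueError(f"baseline has {base.shape[0]} features, samples have {d}")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    if exhaustive:
        orders = [np.asarray(p, dtype=int) for p in _permutations(range(d))]
    else:
        orders = [rng.permutation(d) for _ in range(n_permutations)]
    attr = np.zeros((n, d))
    for order in orders:
        cur = np.tile(base, (n, 1))
        prev = f(cur)
        if np.asarray(prev).shape != (n,):
            raise ValueError("predict must return one score per sample")
        for j in order:
            cur[:, j] = X[:, j]
            now = f(cur)
            attr[:, j] += now - prev
            prev = now
    return attr / len(orders)


def aggregate_views(attributions: np.ndarray, view_boundaries,
                    view_names=None, signed: bool = False) -> AttributionReport:
    """Normalize total attribution to one and report per-view sums and means.

    ``view_boundaries`` are the per-view feature counts or the cumulative
    offsets partitioning the feature axis.  By default magnitudes are
    aggregated (|a| / Σ|a|), matching nonnegative view shares that total 1;
    ``signed=True`` keeps signs and normalizes by the signed total instead.
    """
    a = np.atleast_2d(np.asarray(attributions, dtype=float))
    vb = np.asarray(view_boundaries, dtype=int)
    if vb[0] != 0:  # feature counts given, not offsets
        vb = np.r_[0, np.cumsum(vb)]
    if vb[-1] != a.shape[1] or (np.diff(vb) <= 0).any():
        raise ValueError("view boundaries must partition the feature axis")
    names = tuple(view_names) if view_names else tuple(f"view_{i}" for i in range(len(vb) - 1))
    per_feature = a.sum(axis=0)
    values = per_feature if signed else np.abs(per_feature)
    total = values.sum()
    if total == 0:
        raise ValueError("total attribution is zero: nothing to normalize")
    values = values / total
    sums = np.array([values[lo:hi].sum() for lo, hi in zip(vb[:-1], vb[1:])])
    counts = np.diff(vb)
    return AttributionReport(names, tuple(int(x) for x in vb), a, sums, sums / counts,
                             signed=signed)


def attribute_model(model: TrainedModel, data, n_permutations: int = 50,
                    seed: int = 0, signed: bool = False) -> AttributionReport:
    """Shapley-sample ``model`` on ``data`` (typically the external split)
    against an all-zeros baseline and aggregate to the view level."""
    X = np.concatenate(data.matrices(), axis=1)
    attr = shapley_sampling(model, X, np.zeros(X.shape[1]),
                            n_permutations=n_permutations, seed=seed)
    return aggregate_views(attr, [v.n_features for v in data.views],
                           view_names=data.view_names, signed=signed)
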