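"""Training objectives: online all-triplets mining, triplet loss, and the
composite losses of the MOLI and OmiEmbed architectures.

The triplet loss pushes same-class embeddings together and opposite-class
embeddings apart by at least a margin α:

    L_triplet = Σ_i [ ||f(a_i) − f(p_i)||² − ||f(a_i) − f(n_i)||² + α ]₊

summed (not averaged) over every valid (anchor, positive, negative) triple of
a batch — the "all triplets" online mining scheme.  An optional mean
reduction exists for batch-size robustness but is off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .nn import Var, relu, take_rows

logger = logging.getLogger(__name__)

__all__ = [
    "TripletIndexSet",
    "LatentDistribution",
    "mine_all_triplets",
    "triplet_loss",
    "moli_loss",
    "kl_standard_normal",
    "omiembed_embed_loss",
    "omiembed_total_loss",
]

_BCE_EPS = 1e-7  # probability clip for log() on reconstruction targets


@dataclass(frozen=True)
class TripletIndexSet:
    """(anchor, positive, negative) row indices into an embedding batch."""

    triples: tuple[tuple[int, int, int], ...]

    def __len__(self) -> int:
        return len(self.triples)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if not self.triples:
            z = np.zeros(0, dtype=int)
            return z, z, z
        t = np.asarray(self.triples, dtype=int)
        return t[:, 0], t[:, 1], t[:, 2]


@dataclass(frozen=True)
class LatentDistribution:
    """Diagonal Gaussian (μ, σ) of a variational latent space."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu and sigma must share a shape")
        if (self.sigma <= 0).any():
            raise ValueError("sigma must be positive elementwise")


def mine_all_triplets(labels: np.ndarray) -> TripletIndexSet:
    """Enumerate every ordered (a, p, n) with a≠p, label(a)=label(p)≠label(n).

    The count is Σ_c n_c·(n_c−1)·(n−n_c).  A batch with fewer than two
    members of some class simply contributes no triplets anchored there; a
    single-class batch yields the empty set (triplet loss is then 0).
    """
    y = np.asarray(labels, dtype=int)
    triples = []
    for c in np.unique(y):
        same = np.flatnonzero(y == c)
        other = np.flatnonzero(y != c)
        if len(same) < 2 or len(other) == 0:
            continue
        for a, p in permutations(same, 2):
            for nidx in other:
                triples.append((int(a), int(p), int(nidx)))
    if not triples:
        counts = tuple(np.bincount(y, minlength=2).tolist())
        if counts not in _warned_degenerate:  # routine under class imbalance: warn once
            _warned_degenerate.add(counts)
            logger.warning(
                "no valid triplets in batch of %d (class counts %s); triplet loss is 0",
                len(y), list(counts),
            )
    return TripletIndexSet(tuple(triples))


_warned_degenerate: set[tuple[int, int]] = set()


def triplet_loss(embeddings, triples: TripletIndexSet, margin: float,
                 reduction: str = "sum"):
    """Hinge triplet loss over a mined index set.

    Accepts a plain array (returns a float) or an autodiff :class:`~omicstack.nn.Var`
    (returns a ``Var`` for backprop).  Squared Euclidean distances, hinge at
    zero, summed over triples by default.
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    if reduction not in ("sum", "mean"):
        raise ValueError("reduction must be 'sum' or 'mean'")
    is_var = isinstance(embeddings, Var)
    if len(triples) == 0:
        return Var(0.0) if is_var else 0.0
    ai, pi, ni = triples.arrays()
    if is_var:
        a, p, n = take_rows(embeddings, ai), take_rows(embeddings, pi), take_rows(embeddings, ni)
        d_pos = ((a - p) ** 2.0).sum(axis=1)
        d_neg = ((a - n) ** 2.0).sum(axis=1)
        per = relu(d_pos - d_neg + margin)
        return per.mean() if reduction == "mean" else per.sum()
    e = np.asarray(embeddings, dtype=float)
    d_pos = ((e[ai] - e[pi]) ** 2).sum(axis=1)
    d_neg = ((e[ai] - e[ni]) ** 2).sum(axis=1)
    per = np.maximum(d_pos - d_neg + margin, 0.0)
    return float(per.mean() if reduction == "mean" else per.sum())


def moli_loss(classification_loss, triplet, gamma: float):
    """MOLI's composite objective: BCE + γ · triplet loss."""
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    return classification_loss + gamma * triplet


def kl_standard_normal(latent: LatentDistribution) -> float:
    """Closed-form KL( N(μ, σ) ‖ N(0, 1) ), summed over dimensions.

    Per dimension: ½(μ² + σ² − 1 − ln σ²).  For batched (2-D) μ/σ the batch
    mean of per-sample sums is returned.
    """
    mu, sigma = latent.mu, latent.sigma
    per = 0.5 * (mu ** 2 + sigma ** 2 - 1.0 - 2.0 * np.log(sigma))
    if per.ndim == 2:
        return float(per.sum(axis=1).mean())
    return float(per.sum())


def _bce_mean(x: np.ndarray, recon: np.ndarray) -> float:
    r = np.clip(recon, _BCE_EPS, 1.0 - _BCE_EPS)
    return float(-(x * np.log(r) + (1.0 - x) * np.log(1.0 - r)).mean())


def omiembed_embed_loss(inputs, reconstructions, latent: LatentDistribution) -> float:
    """Unsupervised VAE loss: (1/M)·Σ per-view BCE(x, x′) + KL(N(μ,σ)‖N(0,1)).

    The BCE is computed individually for each of the M views and averaged;
    reconstructions must be probabilities, and inputs are expected in [0, 1]
    (binary views natively, continuous views min–max scaled upstream).
    """
    if len(inputs) != len(reconstructions) or len(inputs) == 0:
        raise ValueError("need matching, nonempty input/reconstruction lists")
    bce = 0.0
    for x, r in zip(inputs, reconstructions):
        x = np.asarray(x, dtype=float)
        r = np.asarray(r, dtype=float)
        if x.shape != r.shape:
            raise ValueError("reconstruction shaped unlike its input")
        binary_coded = np.isin(x, (0.0, 1.0)).all()
        if binary_coded and ((r < 0.0) | (r > 1.0)).any():
            raise ValueError(
                "reconstruction values outside (0,1) for a binary-coded view"
            )
        bce += _bce_mean(x, r)
    return bce / len(inputs) + kl_standard_normal(latent)


def omiembed_total_loss(embed: float, task_ce: float, lam: float) -> float:
    """Total OmiEmbed objective: λ·L_embed + L_CE."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    return lam * embed + task_ce
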