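"""Metrics and comparison statistics.

AUROC (Mann–Whitney formulation, ties credited ½), AUPRC as step-wise
average precision, mean-rank tables across datasets (rank 1 = best, ties
averaged), the Nemenyi critical difference at α = 0.05, and an
exact-distribution two-sided Wilcoxon signed-rank test for small paired
samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "RankTable",
    "PairedDifferenceSet",
    "auroc",
    "auprc",
    "mean_ranks",
    "nemenyi_cd",
    "significant_pairs",
    "wilcoxon_signed_rank",
    "count_positive",
]

#: Studentized-range-based critical values q_α(m)/√2 for the Nemenyi test,
#: α = 0.05, m = 2..10 methods (Demšar's tabulation).
NEMENYI_Q_05 = {
    2: 1.960, 3: 2.343, 4: 2.569, 5: 2.728, 6: 2.850,
    7: 2.949, 8: 3.031, 9: 3.102, 10: 3.164,
}


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels, dtype=int)
    if y.ndim != 1 or (y.size and not np.isin(y, (0, 1)).all()):
        raise ValueError("labels must be a 1-D 0/1 vector")
    return y


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """P(random positive outranks random negative), ties counted ½."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: both classes must be present")
    r = rankdata(s)  # average ranks handle ties ⇒ 0.5 credit
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average precision: Σ over newly recalled positives of the precision
    there (step-wise, no interpolation).  Chance level is the prevalence."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("AUPRC undefined: no positive labels")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    precision = tp / np.arange(1, len(y) + 1)
    # tied scores form one operating point: use the precision at the end of
    # each tie block for every positive inside it
    block_end = np.r_[np.flatnonzero(np.diff(s_sorted) != 0), len(s_sorted) - 1]
    end_for = np.repeat(block_end, np.diff(np.r_[-1, block_end]))
    return float(precision[end_for][y_sorted == 1].sum() / n_pos)


@dataclass(frozen=True)
class RankTable:
    """Methods × datasets metric matrix with per-dataset fractional ranks."""

    methods: tuple[str, ...]
    datasets: tuple[str, ...]
    values: np.ndarray
    ranks: np.ndarray
    mean_ranks: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.methods, columns=self.datasets)
        df["mean_rank"] = self.mean_ranks
        return df


def mean_ranks(values, methods=None, datasets=None) -> RankTable:
    """Rank methods within each dataset (1 = best, higher value = better,
    ties get the average of the tied positions) and average across datasets."""
    if isinstance(values, pd.DataFrame):
        methods = methods or tuple(values.index)
        datasets = datasets or tuple(values.columns)
        values = values.to_numpy(dtype=float)
    v = np.asarray(values, dtype=float)
    if v.ndim != 2:
        raise ValueError("values must be a methods × datasets matrix")
    if np.isnan(v).any():
        i, j = map(int, np.argwhere(np.isnan(v))[0])
        raise ValueError(f"NaN metric for method index {i}, dataset index {j}")
    m, d = v.shape
    methods = tuple(methods) if methods else tuple(f"method_{i}" for i in range(m))
    datasets = tuple(datasets) if datasets else tuple(f"dataset_{j}" for j in range(d))
    ranks = np.column_stack([rankdata(-v[:, j], method="average") for j in range(d)])
    return RankTable(methods, datasets, v, ranks, ranks.mean(axis=1))


def nemenyi_cd(m: int, n_datasets: int, alpha: float = 0.05) -> float:
    """Critical difference CD = q_α(m)·√(m(m+1)/(6·N)); two methods differ
    significantly when their mean ranks differ by at least CD."""
    if alpha != 0.05:
        raise ValueError("only alpha = 0.05 is tabulated")
    if m not in NEMENYI_Q_05:
        raise ValueError(f"method count {m} outside the tabulated range 2..10")
    if n_datasets < 1:
        raise ValueError("need at least one dataset")
    return float(NEMENYI_Q_05[m] * np.sqrt(m * (m + 1) / (6.0 * n_datasets)))


def significant_pairs(table: RankTable, alpha: float = 0.05) -> list[tuple[str, str, float]]:
    """Method pairs whose mean-rank gap reaches the critical difference."""
    cd = nemenyi_cd(len(table.methods), len(table.datasets), alpha)
    out = []
    for i in range(len(table.methods)):
        for j in range(i + 1, len(table.methods)):
            gap = abs(table.mean_ranks[i] - table.mean_ranks[j])
            if gap >= cd:
                out.append((table.methods[i], table.methods[j], float(gap)))
    return out


@dataclass(frozen=True)
class PairedDifferenceSet:
    """Per-dataset paired metric differences (e.g. with − without triplet loss)."""

    differences: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "differences", np.asarray(self.differences, dtype=float))

    @property
    def n_positive(self) -> int:
        return count_positive(self.differences)

    def p_value(self) -> float:
        return wilcoxon_signed_rank(self.differences)


def wilcoxon_signed_rank(differences: np.ndarray) -> float:
    """Exact two-sided Wilcoxon signed-rank p-value.

    Zero differences are dropped before ranking; the null distribution of
    W⁺ is enumerated over all 2ⁿ sign assignments (n ≤ 25), and the
    two-sided p is 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w)) capped at 1.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero: test degenerate")
    if n > 25:
        raise ValueError("exact enumeration supported for n <= 25 only")
    ranks = rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    # distribution of W+ under random signs: convolve over rank contributions
    # (ranks may be fractional under ties; use a dict-based convolution)
    dist: dict[float, float] = {0.0: 1.0}
    for r in ranks:
        nxt: dict[float, float] = {}
        for w, c in dist.items():
            nxt[w] = nxt.get(w, 0.0) + c
            nxt[w + r] = nxt.get(w + r, 0.0) + c
        dist = nxt
    total = 2.0 ** n
    le = sum(c for w, c in dist.items() if w <= w_obs + 1e-9) / total
    ge = sum(c for w, c in dist.items() if w >= w_obs - 1e-9) / total
    return float(min(1.0, 2.0 * min(le, ge)))


def count_positive(differences: np.ndarray) -> int:
    """Number of strictly positive paired differences."""
    return int((np.asarray(differences, dtype=float) > 0).sum())
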