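"""Fair-comparison engine: stratified nested cross-validation with random
hyperparameter search and an upper-bound pruning rule.

Protocol (defaults match the published study design):

* 5×5 stratified cross-validation;
* 200 hyperparameter sets drawn uniformly from the grid per outer fold;
* inner-CV model selection by mean AUROC, with early termination of a
  candidate once even perfect scores (AUROC = 1) on its remaining inner
  folds could no longer beat the best completed mean;
* the winner is retrained on the combined train+validation data and scored
  on the outer test fold and, with the same model, on the untouched
  external set (AUROC and AUPRC for both).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .architectures import (
    ARCHITECTURES,
    ArchitectureSpec,
    HYPERPARAMETER_GRID,
    HyperparameterSet,
    TrainedModel,
    fit,
)
from .data_core import MultiOmicsDataset
from .stats_eval import auprc, auroc

logger = logging.getLogger(__name__)

__all__ = [
    "FoldPlan",
    "SearchTrace",
    "stratified_kfold",
    "draw_hyperparameters",
    "inner_cv_with_pruning",
    "run_comparison",
]


@dataclass(frozen=True)
class FoldPlan:
    """Outer test folds and, per outer fold, inner validation folds."""

    outer_folds: tuple[np.ndarray, ...]
    inner_folds: tuple[tuple[np.ndarray, ...], ...]
    seed: int


@dataclass
class CandidateTrace:
    hyperparameters: HyperparameterSet
    fold_scores: list[float]
    status: str  # "completed" | "pruned"

    @property
    def mean(self) -> float | None:
        return float(np.mean(self.fold_scores)) if self.status == "completed" else None


@dataclass
class SearchTrace:
    candidates: list[CandidateTrace] = field(default_factory=list)

    @property
    def best_so_far(self) -> list[float]:
        best, out = -np.inf, []
        for c in self.candidates:
            if c.status == "completed":
                best = max(best, c.mean)
            out.append(best)
        return out

    @property
    def n_pruned(self) -> int:
        return sum(c.status == "pruned" for c in self.candidates)


def stratified_kfold(labels: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """k disjoint folds covering all indices, class-proportional within ±1."""
    y = np.asarray(labels, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"stratification impossible: minority class has {counts.min()} "
            f"members but k={k} folds were requested"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    return [test for _, test in skf.split(np.zeros(len(y)), y)]


def draw_hyperparameters(grid: dict[str, tuple], n: int, seed: int) -> list[HyperparameterSet]:
    """``n`` independent uniform draws from the grid (with replacement).

    ``layer_dim`` is drawn independently for the encoder width, the latent
    width and the MOMA module count; the OmiEmbed λ reuses the gamma values.
    """
    for key, values in grid.items():
        if len(values) == 0:
            raise ValueError(f"grid dimension {key!r} is empty")
    rng = np.random.default_rng(seed)

    def pick(key):
        vals = grid[key]
        return vals[rng.integers(len(vals))]

    out = []
    for _ in range(n):
        out.append(HyperparameterSet(
            batch_size=pick("batch_size"),
            dropout=pick("dropout"),
            epochs=pick("epochs"),
            gamma=pick("gamma"),
            layer_dim=pick("layer_dim"),
            latent_dim=pick("layer_dim"),
            learning_rate=pick("learning_rate"),
            margin=pick("margin"),
            weight_decay=pick("weight_decay"),
            pca_variance=pick("pca_variance"),
            n_modules=pick("layer_dim"),
            lam=pick("gamma"),
        ))
    return out


def _search(score_fold: Callable[[HyperparameterSet, int], float],
            candidates: Sequence[HyperparameterSet], k: int) -> tuple[SearchTrace, HyperparameterSet]:
    """Sequential evaluation with the upper-bound pruning rule.

    After j of k folds with scores a₁..a_j, the candidate's best attainable
    mean is (Σa + (k−j)·1.0)/k; once that bound is ≤ the best completed mean
    the candidate is pruned.  Ties keep the first-seen candidate.
    """
    trace = SearchTrace()
    best_mean, best_hp = -np.inf, None
    failures = []
    for hp in candidates:
        scores: list[float] = []
        status = "completed"
        try:
            for j in range(k):
                scores.append(float(score_fold(hp, j)))
                bound = (sum(scores) + (k - len(scores)) * 1.0) / k
                if len(scores) < k and bound <= best_mean:
                    status = "pruned"
                    break
        except Exception as exc:  # noqa: BLE001 - candidate-level diagnostics
            failures.append((hp, repr(exc)))
            logger.warning("candidate failed: %r (%s)", hp, exc)
            continue
        trace.candidates.append(CandidateTrace(hp, scores, status))
        if status == "completed":
            mean = float(np.mean(scores))
            if mean > best_mean:
                best_mean, best_hp = mean, hp
    if best_hp is None:
        detail = "; ".join(f"{hp}: {err}" for hp, err in failures[:5])
        raise RuntimeError(f"hyperparameter search failed for all candidates ({detail})")
    return trace, best_hp


def inner_cv_with_pruning(arch_kind: str, candidates: Sequence[HyperparameterSet],
                          train_data: MultiOmicsDataset,
                          inner_folds: Sequence[np.ndarray],
                          variant: str = "standard",
                          seed: int = 0) -> tuple[SearchTrace, HyperparameterSet]:
    """Inner-CV random search for one architecture, AUROC model selection."""
    folds = [np.asarray(f, dtype=int) for f in inner_folds]
    all_idx = np.concatenate(folds)
    if len(np.unique(all_idx)) != len(all_idx) or all_idx.max() >= train_data.n_samples:
        raise ValueError("inner folds must be disjoint valid indices into train_data")

    def score_fold(hp: HyperparameterSet, j: int) -> float:
        val_idx = folds[j]
        tr_idx = np.concatenate([f for i, f in enumerate(folds) if i != j])
        spec = ArchitectureSpec(arch_kind, hp, variant=variant, seed=seed)
        model = fit(spec, train_data.subset(tr_idx))
        val = train_data.subset(val_idx)
        return auroc(model.predict_proba(val), val.labels)

    return _search(score_fold, candidates, len(folds))


def run_comparison(architectures: Sequence[str | tuple[str, str]],
                   data: MultiOmicsDataset,
                   external_data: MultiOmicsDataset,
                   seed: int,
                   n_candidates: int = 200,
                   k_outer: int = 5,
                   k_inner: int = 5,
                   grid: dict[str, tuple] = HYPERPARAMETER_GRID) -> pd.DataFrame:
    """Full nested-CV comparison; returns a tidy frame with one row per
    (architecture, outer fold, split ∈ {test, external}).

    ``architectures`` entries are kinds, or ("omics_stacking", variant)
    tuples for the ablation variants.  The external set is scored with the
    very model retrained for each outer fold and is never used for selection.
    """
    if tuple(v.n_features for v in data.views) != tuple(v.n_features for v in external_data.views):
        raise ValueError("external data views do not match the training views")
    rows = []
    outer = stratified_kfold(data.labels, k_outer, seed)
    all_test = np.concatenate(outer)
    assert len(np.unique(all_test)) == data.n_samples, "outer folds must partition the data"
    for arch in architectures:
        kind, variant = arch if isinstance(arch, tuple) else (arch, "standard")
        for f, test_idx in enumerate(outer):
            fold_seed = (seed ^ f) % (2**31)
            train_idx = np.setdiff1d(np.arange(data.n_samples), test_idx)
            assert not np.intersect1d(train_idx, test_idx).size  # leakage audit
            train = data.subset(train_idx)
            inner = stratified_kfold(train.labels, k_inner, fold_seed)
            candidates = draw_hyperparameters(grid, n_candidates, fold_seed)
            trace, best_hp = inner_cv_with_pruning(
                kind, candidates, train, inner, variant=variant, seed=fold_seed
            )
            model = fit(ArchitectureSpec(kind, best_hp, variant=variant, seed=fold_seed), train)
            test = data.subset(test_idx)
            scores_t = model.predict_proba(test)
            scores_e = model.predict_proba(external_data)
            label = kind if variant == "standard" else f"{kind}:{variant}"
            for split, scores, labels in (
                ("test", scores_t, test.labels),
                ("external", scores_e, external_data.labels),
            ):
                rows.append({
                    "architecture": label,
                    "outer_fold": f,
                    "split": split,
                    "auroc": auroc(scores, labels),
                    "auprc": auprc(scores, labels),
                    "n_pruned": trace.n_pruned,
                    "selected_hyperparameters": json.dumps(dataclasses.asdict(best_hp)),
                })
    return pd.DataFrame(rows)
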