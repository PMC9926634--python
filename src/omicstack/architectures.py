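"""The seven multi-omics integration architectures under one fit/predict contract.

All methods classify samples into responders / non-responders from a
:class:`~omicstack.data_core.MultiOmicsDataset`:

* ``early_integration`` — concatenate views, one encoder, one classifier (BCE);
* ``pca`` — per-view PCA up to a cumulative explained-variance threshold,
  concatenated components feed a classifier;
* ``moli`` — per-view encoders, concatenated latents, one classifier; loss
  BCE + γ·triplet on the concatenated latents, end-to-end;
* ``superfelt`` — phase 1 trains each view's encoder with triplet loss alone;
  phase 2 freezes the encoders and trains a classifier on concatenated latents;
* ``omics_stacking`` — per-view encoders; classifier heads per view plus one
  on the concatenation, combined by a single-fully-connected-layer
  meta-learner, trained end-to-end with BCE + γ·triplet.  Variants:
  ``complete_integration`` adds one head per pair of views,
  ``without_integration`` keeps only the per-view heads (late integration),
  ``without_triplet`` forces γ = 0;
* ``moma`` — per-view module encoders emit K unit-norm 2-d module vectors;
  pairwise cosine-similarity attention (softmax rows) re-weights modules;
  per-view sigmoid outputs trained with cross-entropy, then a logistic
  regression combines the per-view outputs;
* ``omiembed`` — a multi-view variational autoencoder with shared latent
  (μ, σ) plus a downstream classifier, trained in three phases (VAE only;
  VAE frozen + classifier; joint fine-tune) with loss λ·L_embed + L_CE.

Each encoder is one hidden layer of width ``hp.layer_dim`` (ReLU + dropout)
followed by a linear map to ``hp.latent_dim``; depths are not part of the
published hyperparameter grid, so they are fixed design choices here.
Optimization uses Adagrad with L2 weight decay throughout.  Fixed
(seed, hyperparameters, data) gives bit-reproducible training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from . import nn
from .data_core import MultiOmicsDataset
from .losses import (
    LatentDistribution,
    kl_standard_normal,
    mine_all_triplets,
    triplet_loss,
)
from .nn import Adagrad, Dropout, Linear, Param, Var, bce_with_logits, concat, relu, sigmoid, softmax

__all__ = [
    "HYPERPARAMETER_GRID",
    "HyperparameterSet",
    "ArchitectureSpec",
    "TrainedModel",
    "ARCHITECTURES",
    "OMICS_STACKING_VARIANTS",
    "fit",
    "predict",
    "fit_early_integration",
    "fit_pca_integration",
    "fit_moli",
    "fit_superfelt",
    "fit_omics_stacking",
    "fit_moma",
    "fit_omiembed",
]

#: The published random-search grid.  ``layer_dim`` values are drawn
#: independently for the encoder hidden width, the latent width and MOMA's
#: module count; ``lambda`` (OmiEmbed loss weight) reuses the gamma values.
HYPERPARAMETER_GRID: dict[str, tuple] = {
    "batch_size": (8, 16, 32),
    "dropout": (0.1, 0.3, 0.5, 0.7),
    "epochs": tuple(range(2, 21)),
    "gamma": (0.0, 0.1, 0.3, 0.5),
    "layer_dim": (32, 64, 128, 256, 512, 1024),
    "learning_rate": (0.001, 0.01),
    "margin": (0.2, 0.5, 1),
    "weight_decay": (0.0001, 0.001, 0.01, 0.05, 0.1),
    "pca_variance": (0.9, 0.95, 0.975, 0.99),
}

ARCHITECTURES = (
    "early_integration",
    "pca",
    "moli",
    "superfelt",
    "omics_stacking",
    "moma",
    "omiembed",
)

OMICS_STACKING_VARIANTS = (
    "standard",
    "complete_integration",
    "without_integration",
    "without_triplet",
)


@dataclass(frozen=True)
class HyperparameterSet:
    """One draw from the search grid governing training of any architecture."""

    batch_size: int = 16
    dropout: float = 0.3
    epochs: int = 10
    gamma: float = 0.3
    layer_dim: int = 64      # encoder hidden width
    latent_dim: int = 32     # latent width (independent layer_dim draw)
    learning_rate: float = 0.01
    margin: float = 0.5
    weight_decay: float = 0.001
    pca_variance: float = 0.95
    n_modules: int = 32      # MOMA module count (independent layer_dim draw)
    lam: float = 0.1         # OmiEmbed loss weight (drawn from the gamma values)

    def validate_grid(self, grid: dict[str, tuple] = HYPERPARAMETER_GRID) -> None:
        members = {
            "batch_size": grid["batch_size"],
            "dropout": grid["dropout"],
            "epochs": grid["epochs"],
            "gamma": grid["gamma"],
            "layer_dim": grid["layer_dim"],
            "latent_dim": grid["layer_dim"],
            "learning_rate": grid["learning_rate"],
            "margin": grid["margin"],
            "weight_decay": grid["weight_decay"],
            "pca_variance": grid["pca_variance"],
            "n_modules": grid["layer_dim"],
            "lam": grid["gamma"],
        }
        for name, allowed in members.items():
            if getattr(self, name) not in allowed:
                raise ValueError(f"hyperparameter {name}={getattr(self, name)} not in grid {allowed}")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Which architecture to train, with which hyperparameters and seed."""

    kind: str
    hyperparameters: HyperparameterSet = field(default_factory=HyperparameterSet)
    variant: str = "standard"
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.kind!r}; choose from {ARCHITECTURES}")
        if self.variant not in OMICS_STACKING_VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant != "standard" and self.kind != "omics_stacking":
            raise ValueError(
                f"variant {self.variant!r} is only defined for omics_stacking, not {self.kind!r}"
            )


class TrainedModel:
    """Opaque fitted predictor: responder probabilities and latent embeddings."""

    def __init__(self, spec: ArchitectureSpec, view_widths: Sequence[int],
                 predict_fn: Callable[[list[np.ndarray]], np.ndarray],
                 embed_fn: Callable[[list[np.ndarray]], np.ndarray] | None,
                 training_log: list[float], extras: dict | None = None):
        self.spec = spec
        self.view_widths = tuple(view_widths)
        self._predict = predict_fn
        self._embed = embed_fn
        self.training_log = training_log
        self.extras = extras or {}

    def _check(self, mats: list[np.ndarray]) -> list[np.ndarray]:
        if len(mats) != len(self.view_widths):
            raise ValueError(
                f"model expects {len(self.view_widths)} views, got {len(mats)}"
            )
        for i, (m, w) in enumerate(zip(mats, self.view_widths)):
            if m.shape[1] != w:
                raise ValueError(
                    f"view {i} has {m.shape[1]} features but the model expects {w}"
                )
        return [np.asarray(m, dtype=float) for m in mats]

    def predict_views(self, mats: list[np.ndarray]) -> np.ndarray:
        return self._predict(self._check(mats))

    def predict_proba(self, data: MultiOmicsDataset) -> np.ndarray:
        return self.predict_views(data.matrices())

    def predict_concat(self, X: np.ndarray) -> np.ndarray:
        """Predict from a single concatenated matrix (attribution interface)."""
        X = np.asarray(X, dtype=float)
        splits = np.cumsum(self.view_widths)[:-1]
        return self.predict_views(list(np.split(X, splits, axis=1)))

    def embed(self, data: MultiOmicsDataset) -> np.ndarray:
        if self._embed is None:
            raise NotImplementedError(f"{self.spec.kind} defines no embedding")
        return self._embed(self._check(data.matrices()))


def predict(model: TrainedModel, data: MultiOmicsDataset) -> np.ndarray:
    """One responder probability per sample of ``data``."""
    return model.predict_proba(data)


# ---------------------------------------------------------------------------
# shared plumbing

def _require_both_classes(data: MultiOmicsDataset):
    y = data.labels
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError(
            "training data must contain at least 2 samples of each class "
            f"(got {int((y==1).sum())} responders / {int((y==0).sum())} non-responders)"
        )


def _minibatches(n: int, batch_size: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield perm[start:start + batch_size]


def _train(params: list[Param], batch_loss: Callable[[np.ndarray], Var],
           n: int, hp: HyperparameterSet, rng: np.random.Generator,
           epochs: int | None = None) -> list[float]:
    opt = Adagrad(params, hp.learning_rate, hp.weight_decay)
    log: list[float] = []
    for _ in range(hp.epochs if epochs is None else epochs):
        total, nb = 0.0, 0
        for idx in _minibatches(n, hp.batch_size, rng):
            opt.zero_grad()
            loss = batch_loss(idx)
            loss.backward()
            opt.step()
            total += float(loss.data)
            nb += 1
        log.append(total / max(nb, 1))
    return log


class _Encoder:
    """One hidden layer (ReLU + dropout) followed by a linear latent map."""

    def __init__(self, n_in: int, hp: HyperparameterSet, rng: np.random.Generator):
        self.hidden = Linear(n_in, hp.layer_dim, rng)
        self.drop = Dropout(hp.dropout, rng)
        self.out = Linear(hp.layer_dim, hp.latent_dim, rng)

    def __call__(self, x: Var) -> Var:
        return self.out(self.drop(relu(self.hidden(x))))

    def params(self) -> list[Param]:
        return self.hidden.params() + self.out.params()

    def snapshot(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]


def _eval_mode(drops: list[Dropout]):
    for d in drops:
        d.training = False


def _train_mode(drops: list[Dropout]):
    for d in drops:
        d.training = True


# ---------------------------------------------------------------------------
# early integration

def fit_early_integration(data: MultiOmicsDataset, hp: HyperparameterSet,
                          seed: int) -> TrainedModel:
    """Concatenate all views into one input; encoder + classifier, BCE loss."""
    _require_both_classes(data)
    rng = np.random.default_rng(seed)
    mats = data.matrices()
    X = np.concatenate(mats, axis=1)
    y = data.labels.astype(float)
    enc = _Encoder(X.shape[1], hp, rng)
    head = Linear(hp.latent_dim, 1, rng)
    params = enc.params() + head.params()

    def batch_loss(idx):
        logits = head(enc(Var(X[idx]))).reshape(-1)
        return bce_with_logits(logits, y[idx])

    log = _train(params, batch_loss, X.shape[0], hp, rng)
    _eval_mode([enc.drop])

    def predict_fn(ms):
        z = enc(Var(np.concatenate(ms, axis=1)))
        return sigmoid(head(z)).data.reshape(-1)

    def embed_fn(ms):
        return enc(Var(np.concatenate(ms, axis=1))).data

    spec = ArchitectureSpec("early_integration", hp, seed=seed)
    return TrainedModel(spec, [m.shape[1] for m in mats], predict_fn, embed_fn, log,
                        extras={"encoder": enc, "head": head})


# ---------------------------------------------------------------------------
# PCA intermediate integration

def fit_pca_integration(data: MultiOmicsDataset, hp: HyperparameterSet,
                        seed: int) -> TrainedModel:
    """Per-view PCA (labels unused) up to cumulative explained variance
    ``hp.pca_variance``; concatenated components feed the classifier."""
    _require_both_classes(data)
    if not 0.0 < hp.pca_variance <= 1.0:
        raise ValueError(f"pca_variance must lie in (0, 1], got {hp.pca_variance}")
    rng = np.random.default_rng(seed)
    mats = data.matrices()
    y = data.labels.astype(float)
    pcas = []
    for m in mats:
        nc = hp.pca_variance if hp.pca_variance < 1.0 else min(m.shape)
        p = PCA(n_components=nc, svd_solver="full")
        p.fit(m)
        pcas.append(p)

    def transform(ms):
        return np.concatenate([p.transform(m) for p, m in zip(pcas, ms)], axis=1)

    Z = transform(mats)
    enc = _Encoder(Z.shape[1], hp, rng)
    head = Linear(hp.latent_dim, 1, rng)
    params = enc.params() + head.params()

    def batch_loss(idx):
        logits = head(enc(Var(Z[idx]))).reshape(-1)
        return bce_with_logits(logits, y[idx])

    log = _train(params, batch_loss, Z.shape[0], hp, rng)
    _eval_mode([enc.drop])

    def predict_fn(ms):
        return sigmoid(head(enc(Var(transform(ms))))).data.reshape(-1)

    def embed_fn(ms):
        return transform(ms)

    spec = ArchitectureSpec("pca", hp, seed=seed)
    return TrainedModel(spec, [m.shape[1] for m in mats], predict_fn, embed_fn, log,
                        extras={"pcas": pcas, "n_components": [p.n_components_ for p in pcas]})


# ---------------------------------------------------------------------------
# MOLI

def fit_moli(data: MultiOmicsDataset, hp: HyperparameterSet, seed: int) -> TrainedModel:
    """Per-view encoders → concatenated latents → classifier, trained
    end-to-end with BCE + γ·triplet loss on the concatenated latents."""
    _require_both_classes(data)
    rng = np.random.default_rng(seed)
    mats = data.matrices()
    y = data.labels.astype(float)
    encs = [_Encoder(m.shape[1], hp, rng) for m in mats]
    head = Linear(hp.latent_dim * len(encs), 1, rng)
    params = [p for e in encs for p in e.params()] + head.params()

    def latents(ms_idx):
        return concat([e(Var(m)) for e, m in zip(encs, ms_idx)], axis=1)

    def batch_loss(idx):
        Zb = latents([m[idx] for m in mats])
        logits = head(Zb).reshape(-1)
        ce = bce_with_logits(logits, y[idx])
        trip = triplet_loss(Zb, mine_all_triplets(data.labels[idx]), hp.margin)
        return ce + hp.gamma * trip

    log = _train(params, batch_loss, len(y), hp, rng)
    _eval_mode([e.drop for e in encs])

    def predict_fn(ms):
        return sigmoid(head(latents(ms))).data.reshape(-1)

    def embed_fn(ms):
        return latents(ms).data

    spec = ArchitectureSpec("moli", hp, seed=seed)
    return TrainedModel(spec, [m.shape[1] for m in mats], predict_fn, embed_fn, log,
                        extras={"encoders": encs, "head": head})


# ---------------------------------------------------------------------------
# Super.FELT

def fit_superfelt(data: MultiOmicsDataset, hp: HyperparameterSet, seed: int) -> TrainedModel:
    """Two phases: (1) each view's encoder trained with triplet loss on its
    own embeddings; (2) encoders frozen, classifier on concatenated latents."""
    _require_both_classes(data)
    rng = np.random.default_rng(seed)
    mats = data.matrices()
    y = data.labels.astype(float)
    encs = [_Encoder(m.shape[1], hp, rng) for m in mats]

    # phase 1: supervised encoding, one view at a time, no classifier
    phase1_log = []
    for e, m in zip(encs, mats):
        def batch_loss(idx, e=e, m=m):
            Zb = e(Var(m[idx]))
            return triplet_loss(Zb, mine_all_triplets(data.labels[idx]), hp.margin) + Var(0.0)
        phase1_log.append(_train(e.params(), batch_loss, len(y), hp, rng))
    encoder_snapshot = [e.snapshot() for e in encs]

    # phase 2: encoders frozen (their params are simply not optimized)
    _eval_mode([e.drop for e in encs])
    Z = np.concatenate([e(Var(m)).data for e, m in zip(encs, mats)], axis=1)
    head = Linear(Z.shape[1], 1, rng)

    def clf_loss(idx):
        return bce_with_logits(head(Var(Z[idx])).reshape(-1), y[idx])

    phase2_log = _train(head.params(), clf_loss, len(y), hp, rng)

    def latents(ms):
        return np.concatenate([e(Var(m)).data for e, m in zip(encs, ms)], axis=1)

    def predict_fn(ms):
        return sigmoid(head(Var(latents(ms)))).data.reshape(-1)

    spec = ArchitectureSpec("superfelt", hp, seed=seed)
    return TrainedModel(
        spec, [m.shape[1] for m in mats], predict_fn, latents,
        [sum(l) / len(l) for l in zip(*phase1_log)] + phase2_log,
        extras={"encoders": encs, "head": head, "encoder_snapshot": encoder_snapshot},
    )


# ---------------------------------------------------------------------------
# Omics Stacking

def _stacking_head_plan(n_views: int, variant: str) -> list[tuple[int, ...]]:
    """Which view index groups get a classifier head."""
    singles = [(i,) for i in range(n_views)]
    pairs = [(i, j) for i in range(n_views) for j in range(i + 1, n_views)]
    full = tuple(range(n_views))
    if variant == "without_integration":
        return singles
    if variant == "complete_integration":
        return singles + pairs + [full]
    return singles + [full]  # standard / without_triplet


def fit_omics_stacking(data: MultiOmicsDataset, hp: HyperparameterSet, seed: int,
                       variant: str = "standard") -> TrainedModel:
    """Per-view encoders with one classifier head per view group (per view,
    optionally per pair, and on the full concatenation), combined by a single
    fully connected meta-learner; BCE + γ·triplet on the concatenated
    latents, all end-to-end."""
    _require_both_classes(data)
    if variant not in OMICS_STACKING_VARIANTS:
        raise ValueError(f"unknown omics_stacking variant {variant!r}")
    gamma = 0.0 if variant == "without_triplet" else hp.gamma
    rng = np.random.default_rng(seed)
    mats = data.matrices()
    y = data.labels.astype(float)
    encs = [_Encoder(m.shape[1], hp, rng) for m in mats]
    plan = _stacking_head_plan(len(mats), variant)
    heads = [Linear(hp.latent_dim * len(group), 1, rng) for group in plan]
    meta = Linear(len(heads), 1, rng)
    params = [p for e in encs for p in e.params()]
    for h in heads:
        params += h.params()
    params += meta.params()

    def forward(ms):
        zs = [e(Var(m)) for e, m in zip(encs, ms)]
        zcat = concat(zs, axis=1)
        head_probs = []
        for group, h in zip(plan, heads):
            zin = zs[group[0]] if len(group) == 1 else concat([zs[g] for g in group], axis=1)
            head_probs.append(sigmoid(h(zin)))
        stacked = concat(head_probs, axis=1)
        return meta(stacked).reshape(-1), zcat

    def batch_loss(idx):
        logits, zcat = forward([m[idx] for m in mats])
        ce = bce_with_logits(logits, y[idx])
        trip = triplet_loss(zcat, mine_all_triplets(data.labels[idx]), hp.margin)
        return ce + gamma * trip

    log = _train(params, batch_loss, len(y), hp, rng)
    _eval_mode([e.drop for e in encs])

    def predict_fn(ms):
        logits, _ = forward(ms)
        return sigmoid(logits).data.reshape(-1)

    def embed_fn(ms):
        return np.concatenate([e(Var(m)).data for e, m in zip(encs, ms)], axis=1)

    spec = ArchitectureSpec("omics_stacking", hp, variant=variant, seed=seed)
    return TrainedModel(spec, [m.shape[1] for m in mats], predict_fn, embed_fn, log,
                        extras={"encoders": encs, "heads": heads, "meta": meta,
                                "head_plan": plan, "n_heads": len(heads)})


# ---------------------------------------------------------------------------
# MOMA

class _MomaNet:
    """Module encoders + pairwise cosine attention + per-view output layers."""

    def __init__(self, widths: Sequence[int], hp: HyperparameterSet,
                 rng: np.random.Generator):
        if hp.n_modules < 1:
            raise ValueError("MOMA needs at least one module")
        self.k = hp.n_modules
        self.hidden = [Linear(w, hp.layer_dim, rng) for w in widths]
        self.drops = [Dropout(hp.dropout, rng) for _ in widths]
        self.to_modules = [Linear(hp.layer_dim, 2 * self.k, rng) for _ in widths]
        self.out = [Linear(2 * self.k, 1, rng) for _ in widths]
        self.n_views = len(widths)

    def modules(self, ms: list[np.ndarray]) -> list[Var]:
        """K unit-norm 2-d module vectors per view: (batch, K, 2)."""
        out = []
        for m, hid, drop, tm in zip(ms, self.hidden, self.drops, self.to_modules):
            h = drop(relu(hid(Var(m))))
            mod = tm(h).reshape(m.shape[0], self.k, 2)
            norm = ((mod ** 2.0).sum(axis=2, keepdims=True) + 1e-12) ** 0.5
            out.append(mod / norm)
        return out

    def attention(self, mu: Var, mv: Var) -> Var:
        """Softmax rows of the K×K cosine-similarity matrix (unit vectors ⇒
        cosine = dot product)."""
        sim = mu @ mv.transpose(0, 2, 1)
        return softmax(sim, axis=-1)

    def view_logits(self, ms: list[np.ndarray]) -> list[Var]:
        mods = self.modules(ms)
        logits = []
        for u in range(self.n_views):
            attended = []
            for v in range(self.n_views):
                if u == v:
                    continue
                att = self.attention(mods[u], mods[v])  # (B, K, K)
                attended.append(att @ mods[v])          # (B, K, 2)
            rep = attended[0]
            for a in attended[1:]:
                rep = rep + a
            rep = rep * (1.0 / len(attended))
            flat = rep.reshape(rep.shape[0], 2 * self.k)
            logits.append(self.out[u](flat).reshape(-1))
        return logits

    def params(self) -> list[Param]:
        ps: list[Param] = []
        for group in (self.hidden, self.to_modules, self.out):
            for layer in group:
                ps += layer.params()
        return ps


def fit_moma(data: MultiOmicsDataset, hp: HyperparameterSet, seed: int) -> TrainedModel:
    """Module attention network with per-view outputs (cross-entropy), then a
    logistic regression combining the per-view probabilities."""
    _require_both_classes(data)
    rng = np.random.default_rng(seed)
    mats = data.matrices()
    y = data.labels.astype(float)
    net = _MomaNet([m.shape[1] for m in mats], hp, rng)

    def batch_loss(idx):
        logits = net.view_logits([m[idx] for m in mats])
        loss = bce_with_logits(logits[0], y[idx])
        for lg in logits[1:]:
            loss = loss + bce_with_logits(lg, y[idx])
        return loss

    log = _train(net.params(), batch_loss, len(y), hp, rng)
    _eval_mode(net.drops)

    def view_probs(ms):
        return np.column_stack([sigmoid(lg).data for lg in net.view_logits(ms)])

    combiner = LogisticRegression(max_iter=1000)
    combiner.fit(view_probs(mats), data.labels)

    def predict_fn(ms):
        return combiner.predict_proba(view_probs(ms))[:, 1]

    def embed_fn(ms):
        mods = net.modules(ms)
        return np.concatenate([mo.data.reshape(mo.shape[0], -1) for mo in mods], axis=1)

    spec = ArchitectureSpec("moma", hp, seed=seed)
    return TrainedModel(spec, [m.shape[1] for m in mats], predict_fn, embed_fn, log,
                        extras={"net": net, "combiner": combiner})


# ---------------------------------------------------------------------------
# OmiEmbed

class _VAENet:
    def __init__(self, widths: Sequence[int], hp: HyperparameterSet,
                 rng: np.random.Generator):
        self.view_enc = [Linear(w, hp.layer_dim, rng) for w in widths]
        self.drops = [Dropout(hp.dropout, rng) for _ in widths]
        self.mu = Linear(hp.layer_dim * len(widths), hp.latent_dim, rng)
        self.logvar = Linear(hp.layer_dim * len(widths), hp.latent_dim, rng)
        self.dec_hidden = Linear(hp.latent_dim, hp.layer_dim, rng)
        self.dec_out = [Linear(hp.layer_dim, w, rng) for w in widths]

    def encode(self, ms: list[np.ndarray]) -> tuple[Var, Var]:
        h = concat([d(relu(e(Var(m)))) for e, d, m in zip(self.view_enc, self.drops, ms)], axis=1)
        return self.mu(h), self.logvar(h)

    def decode(self, z: Var) -> list[Var]:
        h = relu(self.dec_hidden(z))
        return [sigmoid(o(h)) for o in self.dec_out]

    def params(self) -> list[Param]:
        ps: list[Param] = []
        for layer in (*self.view_enc, self.mu, self.logvar, self.dec_hidden, *self.dec_out):
            ps += layer.params()
        return ps

    def snapshot(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]


def _phase_split(epochs: int) -> tuple[int, int, int]:
    p1 = math.ceil(epochs / 3)
    p2 = math.ceil(epochs / 3)
    return p1, p2, epochs - p1 - p2


def fit_omiembed(data: MultiOmicsDataset, hp: HyperparameterSet, seed: int) -> TrainedModel:
    """Multi-view VAE with shared (μ, σ) latent and a downstream classifier.

    Three-phase schedule over ``hp.epochs`` (ceil/ceil/remainder): VAE alone
    on the embedding loss; VAE frozen while the classifier trains on μ; joint
    fine-tuning of everything on λ·L_embed + L_CE.  Continuous views are
    min–max scaled to [0, 1] internally so the per-view reconstruction BCE is
    well defined alongside the binary views.
    """
    _require_both_classes(data)
    if hp.epochs < 3:
        raise ValueError(f"omiembed needs epochs >= 3 (one per phase), got {hp.epochs}")
    p1, p2, p3 = _phase_split(hp.epochs)
    rng = np.random.default_rng(seed)
    y = data.labels.astype(float)

    # scale continuous views into [0, 1] for the reconstruction target
    lows, spans = [], []
    scaled = []
    for v in data.views:
        if v.encoding == "binary":
            lows.append(None)
            spans.append(None)
            scaled.append(v.matrix)
        else:
            lo = v.matrix.min(axis=0)
            span = np.where(v.matrix.max(axis=0) - lo > 0, v.matrix.max(axis=0) - lo, 1.0)
            lows.append(lo)
            spans.append(span)
            scaled.append((v.matrix - lo) / span)

    def scale(ms):
        out = []
        for m, lo, span in zip(ms, lows, spans):
            out.append(m if lo is None else np.clip((m - lo) / span, 0.0, 1.0))
        return out

    widths = [m.shape[1] for m in scaled]
    net = _VAENet(widths, hp, rng)
    clf = Linear(hp.latent_dim, 1, rng)
    eps_scale = 1.0  # reparameterization noise scale

    def embed_terms(idx):
        ms = [m[idx] for m in scaled]
        mu, logvar = net.encode(ms)
        noise = rng.standard_normal(mu.shape) * eps_scale
        z = mu + nn.exp(logvar * 0.5) * Var(noise)
        recons = net.decode(z)
        bce = Var(0.0)
        for x, r in zip(ms, recons):
            bce = bce + nn.bce_probs(r, x)
        bce = bce * (1.0 / len(ms))
        kl = ((mu ** 2.0 + nn.exp(logvar) - 1.0 - logvar) * 0.5).sum(axis=1).mean()
        return bce + kl, mu, z

    def phase1_loss(idx):
        embed, _, _ = embed_terms(idx)
        return embed

    log = _train(net.params(), phase1_loss, len(y), hp, rng, epochs=p1)
    vae_snapshot = net.snapshot()

    def phase2_loss(idx):
        ms = [m[idx] for m in scaled]
        mu, _ = net.encode(ms)
        logits = clf(mu.detach()).reshape(-1)
        return bce_with_logits(logits, y[idx])

    _eval_mode(net.drops)  # frozen VAE acts deterministically in phase 2
    log += _train(clf.params(), phase2_loss, len(y), hp, rng, epochs=p2)
    assert all(
        np.array_equal(a, b.data) for a, b in zip(vae_snapshot, net.params())
    ), "VAE weights moved during the frozen phase"
    _train_mode(net.drops)

    def phase3_loss(idx):
        embed, mu, z = embed_terms(idx)
        ce = bce_with_logits(clf(z).reshape(-1), y[idx])
        return Var(hp.lam) * embed + ce

    if p3 > 0:
        log += _train(net.params() + clf.params(), phase3_loss, len(y), hp, rng, epochs=p3)
    _eval_mode(net.drops)

    def predict_fn(ms):
        mu, _ = net.encode(scale(ms))
        return sigmoid(clf(mu)).data.reshape(-1)

    def embed_fn(ms):
        mu, _ = net.encode(scale(ms))
        return mu.data

    spec = ArchitectureSpec("omiembed", hp, seed=seed)
    return TrainedModel(spec, widths, predict_fn, embed_fn, log,
                        extras={"net": net, "classifier": clf,
                                "vae_snapshot_after_phase1": vae_snapshot,
                                "phase_epochs": (p1, p2, p3)})


# ---------------------------------------------------------------------------
# dispatch

_FITTERS = {
    "early_integration": fit_early_integration,
    "pca": fit_pca_integration,
    "moli": fit_moli,
    "superfelt": fit_superfelt,
    "moma": fit_moma,
    "omiembed": fit_omiembed,
}


def fit(spec: ArchitectureSpec, data: MultiOmicsDataset) -> TrainedModel:
    """Train the architecture described by ``spec`` on ``data``."""
    if spec.kind == "omics_stacking":
        return fit_omics_stacking(data, spec.hyperparameters, spec.seed, spec.variant)
    return _FITTERS[spec.kind](data, spec.hyperparameters, spec.seed)
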