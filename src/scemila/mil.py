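"""Attention-based multiple instance learning with class-wise attention.

A patient is a bag B = {x_1..x_N} of single-cell feature vectors with one
weak label y (genetic AML subtype or control). The model is

    h_k     = f_emb(x_k)                      instance embedding (MLP + ReLU)
    e_ik    = w_i' tanh(V_i h_k)              raw attention, class i, cell k
    a_ik    = softmax_k(e_ik)                 per-class softmax over instances
    z_i     = sum_k a_ik h_k                  class-wise attention pooling
    s_i     = u_i' z_i + c_i                  per-class logit from its own z_i
    p       = softmax(s),  y_hat = argmax p

Each class owns an attention row, so attention values never compete across
classes: perturbing class i's attention parameters leaves every other row of
the attention matrix A unchanged. Training minimizes bag-level categorical
cross-entropy with one optimizer step per bag, shuffled bag order and permuted
within-bag instance order each epoch, and early stopping on validation loss.

The model/results split follows the convention of statistical modelling
packages: :class:`AttentionMIL` is built from the data and configuration;
``fit()`` returns an :class:`AttentionMILResults` carrying the parameters,
training history, prediction and attention methods and a ``summary()``.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import (average_precision_score, confusion_matrix,
                             f1_score, roc_auc_score)

from ._nn import softmax

CLASS_NAMES = ("PML::RARA", "NPM1", "CBFB::MYH11", "RUNX1::RUNX1T1", "control")


@dataclass
class Bag:
    """One patient: an ordered bag of instance feature vectors and a label."""

    patient_id: str
    label: int | None
    features: np.ndarray                  # (N, d)
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError("bag features must be a non-empty (N, d) matrix")
        if not self.cell_ids:
            self.cell_ids = [f"{self.patient_id}_cell{k:04d}"
                             for k in range(len(self.features))]

    @property
    def n_instances(self) -> int:
        return self.features.shape[0]


@dataclass(frozen=True)
class MILConfig:
    """Hyperparameters of the attention-MIL model and its training loop.

    Defaults are the full-scale recipe: 500-dim embedding, 128-dim attention
    space, learning rate 5e-5, early stopping after 20 epochs without
    validation improvement, at most 150 epochs.
    """

    embed_dim: int = 500
    attention_dim: int = 128
    embed_depth: int = 1
    learning_rate: float = 5e-5
    patience: int = 20
    max_epochs: int = 150
    min_delta: float = 0.0
    weight_decay: float = 0.0
    n_restarts: int = 1
    optimizer: str = "adam"
    shared_head: bool = False
    seed: int = 0
    class_names: tuple[str, ...] = CLASS_NAMES

    def validate(self) -> None:
        if self.embed_dim < 1 or self.attention_dim < 1 or self.embed_depth < 1:
            raise ValueError("embed_dim, attention_dim and embed_depth must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (1 <= self.patience <= self.max_epochs):
            raise ValueError("need 1 <= patience <= max_epochs")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if len(self.class_names) < 2:
            raise ValueError("need at least 2 classes")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass
class MILParams:
    """Learnable parameters; one (V_i, w_i, u_i, c_i) block per class."""

    W_emb: list[np.ndarray]               # embed_depth matrices, first is (d, L)
    b_emb: list[np.ndarray]
    V: np.ndarray                         # (C, L_att, L)
    w_att: np.ndarray                     # (C, L_att)
    U: np.ndarray                         # (C, L); rows identical if shared head
    c: np.ndarray                         # (C,)
    shared_head: bool = False

    def flat(self) -> list[np.ndarray]:
        return [*self.W_emb, *self.b_emb, self.V, self.w_att, self.U, self.c]

    def copy(self) -> "MILParams":
        return MILParams([w.copy() for w in self.W_emb], [b.copy() for b in self.b_emb],
                         self.V.copy(), self.w_att.copy(), self.U.copy(), self.c.copy(),
                         self.shared_head)

    @property
    def input_dim(self) -> int:
        return self.W_emb[0].shape[0]


def desk_scale_config(**overrides) -> MILConfig:
    """Reduced-scale configuration for CPU-sized experiments.

    Sized for cohorts of a few hundred bags with d around 64: a full 5-fold
    cross-validation of the default synthetic cohort runs in a few minutes on
    one core. The class defaults on :class:`MILConfig` remain the full-scale
    recipe.
    """
    kw = dict(embed_dim=128, attention_dim=64, embed_depth=2,
              learning_rate=1e-3, patience=5, max_epochs=30)
    kw.update(overrides)
    return MILConfig(**kw)


def init_params(d: int, cfg: MILConfig, rng: np.random.Generator) -> MILParams:
    L, La, C = cfg.embed_dim, cfg.attention_dim, cfg.n_classes
    dims = [d] + [L] * cfg.embed_depth
    W_emb = [rng.normal(0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1]))
             for i in range(cfg.embed_depth)]
    b_emb = [np.zeros(dims[i + 1]) for i in range(cfg.embed_depth)]
    V = rng.normal(0, np.sqrt(1.0 / L), size=(C, La, L))
    # attention vectors start at zero: every attention row is exactly uniform
    # at initialization, so training first fits a mean-pooled bag classifier
    # and sharpens attention only where doing so reduces the loss
    w_att = np.zeros((C, La))
    U = rng.normal(0, np.sqrt(1.0 / L), size=(C, L))
    if cfg.shared_head:
        U = np.broadcast_to(U[0], U.shape).copy()
    return MILParams(W_emb, b_emb, V, w_att, U, np.zeros(C), cfg.shared_head)


# ---------------------------------------------------------------------------
# forward operations


def embed_instances(X: np.ndarray, params: MILParams) -> np.ndarray:
    """Instance-wise embedding H (N x L); row order equals bag order."""
    H = np.asarray(X, dtype=float)
    if H.ndim != 2:
        raise ValueError("expected an (N, d) instance matrix")
    if H.shape[1] != params.input_dim:
        raise ValueError(f"feature dim {H.shape[1]} does not match "
                         f"embedder input dim {params.input_dim}")
    for W, b in zip(params.W_emb, params.b_emb):
        H = np.maximum(H @ W + b, 0.0)
    return H


def classwise_attention(H: np.ndarray, params: MILParams,
                        return_scores: bool = False):
    """Class-wise attention matrix A (C x N); each row is a softmax over instances.

    Raw scores e_ik = w_i' tanh(V_i h_k) are normalized per class row with
    max subtraction, so every row sums to 1 and all entries lie in (0, 1).
    """
    if not np.all(np.isfinite(H)):
        raise ValueError("non-finite embeddings passed to attention")
    T = np.tanh(np.einsum("cal,nl->cna", params.V, H))       # (C, N, La)
    E = np.einsum("cna,ca->cn", T, params.w_att)             # (C, N)
    A = softmax(E, axis=1)
    return (A, E) if return_scores else A


def attention_pool(H: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Per-class pooled bag features z_i = sum_k a_ik h_k, stacked (C x L)."""
    if A.shape[1] != H.shape[0]:
        raise ValueError(f"attention matrix has {A.shape[1]} columns "
                         f"but bag has {H.shape[0]} instances")
    return A @ H


@dataclass
class BagPrediction:
    """Bag-level output: class probabilities plus the winning attention row."""

    probabilities: np.ndarray             # (C,), sums to 1
    predicted_index: int
    predicted_label: str
    attention: np.ndarray                 # (N,) = attention_matrix[predicted]
    attention_matrix: np.ndarray          # (C, N)
    pooled: np.ndarray                    # (C, L)
    logits: np.ndarray                    # (C,)
    patient_id: str | None = None


def classify_bag(Z: np.ndarray, params: MILParams,
                 A: np.ndarray | None = None,
                 class_names: tuple[str, ...] = CLASS_NAMES,
                 patient_id: str | None = None) -> BagPrediction:
    """Per-class linear head on each class's own pooled vector, then softmax.

    Ties at the argmax resolve to the lowest class index.
    """
    if Z.shape[0] != params.U.shape[0]:
        raise ValueError("need one pooled vector per class")
    s = np.einsum("cl,cl->c", Z, params.U) + params.c
    p = softmax(s)
    yhat = int(np.argmax(p))              # argmax returns the first (lowest) index on ties
    if A is None:
        A = np.full((len(s), 1), 1.0)
    return BagPrediction(p, yhat, class_names[yhat], A[yhat].copy(), A, Z, s, patient_id)


def forward(bag, params: MILParams,
            class_names: tuple[str, ...] | None = None) -> BagPrediction:
    """Full bag pass: embed -> class-wise attention -> pool -> classify.

    Permutation invariant: reordering the bag's instances changes neither the
    predicted label nor (up to float roundoff) the probability vector.
    """
    X = bag.features if hasattr(bag, "features") else np.asarray(bag)
    names = class_names or (CLASS_NAMES if params.U.shape[0] == len(CLASS_NAMES)
                            else tuple(f"class{i}" for i in range(params.U.shape[0])))
    H = embed_instances(X, params)
    A = classwise_attention(H, params)
    Z = attention_pool(H, A)
    return classify_bag(Z, params, A, names, getattr(bag, "patient_id", None))


# ---------------------------------------------------------------------------
# backward pass (manual gradients)


def _bag_loss_and_grads(X: np.ndarray, y: int, params: MILParams, grads: MILParams
                        ) -> float:
    """Accumulate d(CCE)/d(params) for one bag into ``grads``; returns the loss."""
    X = np.asarray(X, dtype=float)
    # forward, caching intermediates
    acts = [X]
    pres = []
    H = X
    for W, b in zip(params.W_emb, params.b_emb):
        pre = H @ W + b
        H = np.maximum(pre, 0.0)
        pres.append(pre)
        acts.append(H)
    T = np.tanh(np.einsum("cal,nl->cna", params.V, H))
    E = np.einsum("cna,ca->cn", T, params.w_att)
    A = softmax(E, axis=1)
    Z = A @ H
    s = np.einsum("cl,cl->c", Z, params.U) + params.c
    p = softmax(s)
    loss = -np.log(p[y] + 1e-12)

    ds = p.copy()
    ds[y] -= 1.0
    dZ = ds[:, None] * params.U
    if params.shared_head:
        grads.U += np.sum(ds[:, None] * Z, axis=0)        # broadcast-summed below
    else:
        grads.U += ds[:, None] * Z
    grads.c += ds
    dA = dZ @ H.T                                         # (C, N)
    dH = A.T @ dZ                                         # pooling path
    dE = A * (dA - np.sum(A * dA, axis=1, keepdims=True))
    grads.w_att += np.einsum("cn,cna->ca", dE, T)
    dT = dE[:, :, None] * params.w_att[:, None, :]
    dpreT = dT * (1.0 - T * T)
    grads.V += np.einsum("cna,nl->cal", dpreT, H)
    dH += np.einsum("cna,cal->nl", dpreT, params.V)
    for i in reversed(range(len(params.W_emb))):
        dpre = dH * (pres[i] > 0)
        grads.W_emb[i] += acts[i].T @ dpre
        grads.b_emb[i] += dpre.sum(axis=0)
        dH = dpre @ params.W_emb[i].T
    return float(loss)


class _AdamState:
    """Adam with decoupled (AdamW-style) weight decay."""

    def __init__(self, params: list[np.ndarray], lr: float, weight_decay: float = 0.0):
        self.lr, self.b1, self.b2, self.eps = lr, 0.9, 0.999, 1e-8
        self.wd = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            if self.wd:
                p -= self.lr * self.wd * p
            p -= self.lr * (m / (1 - self.b1 ** self.t)) / \
                (np.sqrt(v / (1 - self.b2 ** self.t)) + self.eps)


def _zero_like(params: MILParams) -> MILParams:
    g = params.copy()
    for arr in g.flat():
        arr[...] = 0.0
    return g


def train_mil(bags: list, train_idx, val_idx, cfg: MILConfig
              ) -> tuple[MILParams, pd.DataFrame, int]:
    """Train by bag-level cross-entropy with one optimizer step per bag.

    Each epoch shuffles the bag order and permutes the instance order within
    every bag. Stops when validation loss has not improved for ``cfg.patience``
    epochs (no minimum delta), capped at ``cfg.max_epochs``; the weights from
    the best-validation epoch (earliest on ties) are returned. A non-finite
    training loss aborts the epoch loop and falls back to the last good
    checkpoint, noted in the history.

    With ``cfg.n_restarts`` > 1, training is repeated from independent random
    initializations and the run with the lowest best validation loss wins.
    """
    cfg.validate()
    train_idx, val_idx = list(train_idx), list(val_idx)
    if not train_idx or not val_idx:
        raise ValueError("train and validation sets must be non-empty")
    train_labels = {int(bags[i].label) for i in train_idx}
    if len(train_labels) < 2:
        raise ValueError("training set must contain at least 2 classes")

    runs = []
    for child in np.random.SeedSequence(cfg.seed).spawn(cfg.n_restarts):
        runs.append(_train_once(bags, train_idx, val_idx, cfg, child))
    return min(runs, key=lambda r: (r[3], r[2]))[:3]


def _train_once(bags, train_idx, val_idx, cfg: MILConfig,
                seed_seq: np.random.SeedSequence
                ) -> tuple[MILParams, pd.DataFrame, int, float]:
    d = bags[train_idx[0]].features.shape[1]
    rng_init, rng_shuffle = (np.random.default_rng(s) for s in seed_seq.spawn(2))
    params = init_params(d, cfg, rng_init)
    grads = _zero_like(params)
    if cfg.optimizer.lower() != "adam":
        raise ValueError(f"unsupported optimizer {cfg.optimizer!r}")
    opt = _AdamState(params.flat(), cfg.learning_rate, cfg.weight_decay)

    def val_loss() -> float:
        losses = []
        for i in val_idx:
            pred = forward(bags[i], params, cfg.class_names)
            losses.append(-np.log(pred.probabilities[bags[i].label] + 1e-12))
        return float(np.mean(losses))

    best = {"loss": np.inf, "params": params.copy(), "epoch": 0}
    since_best = 0
    hist = []
    aborted = False
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng_shuffle.permutation(train_idx)
        ep_loss = 0.0
        for i in order:
            bag = bags[i]
            perm = rng_shuffle.permutation(bag.n_instances)
            for arr in grads.flat():
                arr[...] = 0.0
            loss = _bag_loss_and_grads(bag.features[perm], int(bag.label), params, grads)
            if not np.isfinite(loss):
                aborted = True
                break
            opt.step(params.flat(), grads.flat())
            ep_loss += loss
        if aborted:
            break
        vl = val_loss()
        hist.append({"epoch": epoch, "train_loss": ep_loss / len(order), "val_loss": vl})
        if vl < best["loss"] - cfg.min_delta:
            best = {"loss": vl, "params": params.copy(), "epoch": epoch}
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    history = pd.DataFrame(hist)
    history.attrs["aborted_nonfinite"] = aborted
    return best["params"], history, best["epoch"], best["loss"]


# ---------------------------------------------------------------------------
# Model / Results objects


class AttentionMIL:
    """The attention-MIL model, built from a list of bags and a configuration.

    Parameters
    ----------
    bags : list of Bag-like
        Each needs ``features`` (N x d), ``label`` (class index) and
        ``patient_id``; :class:`Bag` and the synthetic generator's bags both
        qualify.
    config : MILConfig, optional
    """

    def __init__(self, bags: list, config: MILConfig | None = None):
        if not bags:
            raise ValueError("need at least one bag")
        self.bags = list(bags)
        self.config = config or MILConfig()
        self.config.validate()
        dims = {b.features.shape[1] for b in self.bags}
        if len(dims) != 1:
            raise ValueError(f"bags disagree on feature dimension: {sorted(dims)}")
        self.d = dims.pop()

    @classmethod
    def from_cohort(cls, cohort_dir: str | os.PathLike,
                    config: MILConfig | None = None) -> "AttentionMIL":
        from .reporting import load_cohort
        _, bags = load_cohort(cohort_dir,
                              class_names=(config or MILConfig()).class_names)
        return cls(bags, config)

    def fit(self, train_idx=None, val_idx=None) -> "AttentionMILResults":
        """Train and return a results object.

        Without explicit indices a seeded, class-stratified 75/25
        train/validation split of all bags is used.
        """
        if train_idx is None or val_idx is None:
            labels = np.array([b.label for b in self.bags])
            rng = np.random.default_rng(self.config.seed)
            train_idx, val_idx = [], []
            for c in np.unique(labels):
                idx = np.nonzero(labels == c)[0]
                rng.shuffle(idx)
                n_val = max(1, int(round(0.25 * len(idx))))
                val_idx += list(idx[:n_val])
                train_idx += list(idx[n_val:])
        params, history, best_epoch = train_mil(self.bags, train_idx, val_idx, self.config)
        return AttentionMILResults(self, params, history, best_epoch,
                                   train_idx=list(train_idx), val_idx=list(val_idx))


class AttentionMILResults:
    """Fitted attention-MIL model: parameters, history, prediction methods."""

    def __init__(self, model: AttentionMIL, params: MILParams,
                 history: pd.DataFrame, best_epoch: int,
                 train_idx: list[int] | None = None,
                 val_idx: list[int] | None = None):
        self.model = model
        self.params = params
        self.history = history
        self.best_epoch = best_epoch
        self.train_idx = train_idx or []
        self.val_idx = val_idx or []

    @property
    def config(self) -> MILConfig:
        return self.model.config

    @property
    def class_names(self) -> tuple[str, ...]:
        return self.config.class_names

    def predict(self, bag) -> BagPrediction:
        return forward(bag, self.params, self.class_names)

    def predict_many(self, bags: list) -> list[BagPrediction]:
        return [self.predict(b) for b in bags]

    def predict_proba(self, bags: list) -> np.ndarray:
        return np.stack([self.predict(b).probabilities for b in bags])

    def attention_matrix(self, bag) -> np.ndarray:
        return self.predict(bag).attention_matrix

    def score(self, bags: list) -> float:
        """Accuracy against the bags' own labels."""
        preds = self.predict_many(bags)
        return float(np.mean([p.predicted_index == b.label
                              for p, b in zip(preds, bags)]))

    def save(self, path: str | os.PathLike) -> None:
        """Checkpoint as npz with a JSON sidecar (class order, dims, config)."""
        path = os.fspath(path)
        arrays = {f"W_emb_{i}": w for i, w in enumerate(self.params.W_emb)}
        arrays.update({f"b_emb_{i}": b for i, b in enumerate(self.params.b_emb)})
        arrays.update(V=self.params.V, w_att=self.params.w_att,
                      U=self.params.U, c=self.params.c)
        np.savez(path, **arrays)
        sidecar = dataclasses.asdict(self.config)
        sidecar.update(d=self.model.d, best_epoch=self.best_epoch,
                       embed_depth=self.config.embed_depth)
        with open(path + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True, default=list)

    def summary(self) -> str:
        cfg = self.config
        n_params = sum(p.size for p in self.params.flat())
        lines = [
            "Attention-MIL results",
            "=" * 54,
            f"classes:            {', '.join(cfg.class_names)}",
            f"bags (train/val):   {len(self.train_idx)}/{len(self.val_idx)}",
            f"feature dim d:      {self.model.d}",
            f"embed dim L:        {cfg.embed_dim}   attention dim: {cfg.attention_dim}",
            f"parameters:         {n_params}",
            f"epochs run:         {len(self.history)}   best epoch: {self.best_epoch}",
        ]
        if len(self.history):
            lines.append(f"best val loss:      {self.history['val_loss'].min():.4f}")
        train_bags = [self.model.bags[i] for i in self.train_idx]
        if train_bags:
            lines.append(f"train accuracy:     {self.score(train_bags):.3f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class FoldSplit:
    """Patient-level, class-stratified train/val/test partition for one fold."""

    fold: int
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]

    def validate(self) -> None:
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if (sets[0] & sets[1]) or (sets[0] & sets[2]) or (sets[1] & sets[2]):
            raise AssertionError("fold partitions overlap")


def make_folds(patient_ids: list[str], labels: list[int], k: int = 5,
               fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
               seed: int = 0,
               class_names: tuple[str, ...] = CLASS_NAMES) -> list[FoldSplit]:
    """Patient-level stratified k-fold splits with ~60/20/20 proportions.

    Each class's patients are shuffled once and cut into k chunks whose sizes
    follow largest-remainder rounding (they differ by at most one). Fold i
    tests on chunk i and validates on the following chunk(s); every patient
    appears in exactly one test set across folds.
    """
    labels = np.asarray(labels)
    patient_ids = np.asarray(patient_ids)
    n_val_chunks = max(1, int(round(fractions[1] * k)))
    if k - 1 - n_val_chunks < 1:
        raise ValueError("fractions leave no training chunks")
    rng = np.random.default_rng(seed)
    chunks_per_class: dict[int, list[np.ndarray]] = {}
    for c in np.unique(labels):
        ids = patient_ids[labels == c].copy()
        if len(ids) < k:
            name = class_names[c] if c < len(class_names) else str(c)
            raise ValueError(f"class {name!r} has {len(ids)} patients, fewer than k={k}")
        rng.shuffle(ids)
        base, rem = divmod(len(ids), k)
        sizes = [base + 1] * rem + [base] * (k - rem)
        cuts = np.cumsum(sizes)[:-1]
        chunks_per_class[c] = np.split(ids, cuts)
    folds = []
    for f in range(k):
        tr: list[str] = []
        va: list[str] = []
        te: list[str] = []
        for chunks in chunks_per_class.values():
            te += list(chunks[f])
            val_js = [(f + 1 + j) % k for j in range(n_val_chunks)]
            for j in range(k):
                if j == f:
                    continue
                (va if j in val_js else tr).extend(chunks[j])
        fold = FoldSplit(f, tr, va, te)
        fold.validate()
        folds.append(fold)
    return folds


class CrossValidationResults:
    """Pooled k-fold evaluation: every patient predicted exactly once."""

    def __init__(self, folds, fold_results, y_true, y_pred, probabilities,
                 patient_ids, class_names):
        self.folds = folds
        self.fold_results = fold_results
        self.y_true = np.asarray(y_true)
        self.y_pred = np.asarray(y_pred)
        self.probabilities = np.asarray(probabilities)
        self.patient_ids = list(patient_ids)
        self.class_names = tuple(class_names)

    @property
    def confusion(self) -> pd.DataFrame:
        cm = confusion_matrix(self.y_true, self.y_pred,
                              labels=range(len(self.class_names)))
        return pd.DataFrame(cm, index=self.class_names, columns=self.class_names)

    def f1_by_fold(self) -> pd.DataFrame:
        rows = []
        for fold, res in zip(self.folds, self.fold_results):
            in_fold = np.isin(self.patient_ids, fold.test_ids)
            f1 = f1_score(self.y_true[in_fold], self.y_pred[in_fold],
                          labels=range(len(self.class_names)), average=None,
                          zero_division=0)
            rows.append(f1)
        return pd.DataFrame(rows, columns=self.class_names)

    def f1_summary(self) -> pd.DataFrame:
        by_fold = self.f1_by_fold()
        return pd.DataFrame({"mean": by_fold.mean(), "sd": by_fold.std(ddof=1)})

    def macro_f1(self) -> float:
        """Macro F1 over the pooled predictions."""
        return float(f1_score(self.y_true, self.y_pred,
                              labels=range(len(self.class_names)),
                              average="macro", zero_division=0))

    def auc_summary(self) -> pd.DataFrame:
        """Pooled one-vs-rest ROC-AUC and PR-AUC per class."""
        rows = {}
        for i, name in enumerate(self.class_names):
            onevs = (self.y_true == i).astype(int)
            rows[name] = {
                "roc_auc": roc_auc_score(onevs, self.probabilities[:, i]),
                "pr_auc": average_precision_score(onevs, self.probabilities[:, i]),
            }
        return pd.DataFrame(rows).T

    def aml_vs_control_accuracy(self, control_index: int | None = None) -> float:
        """Accuracy of the collapsed binary task: any-AML vs control."""
        ci = control_index if control_index is not None else len(self.class_names) - 1
        return float(np.mean((self.y_true == ci) == (self.y_pred == ci)))

    def summary(self) -> str:
        f1 = self.f1_summary()
        auc = self.auc_summary()
        lines = [
            "Attention-MIL cross-validation (pooled over folds)",
            "=" * 54,
            f"patients: {len(self.y_true)}   folds: {len(self.folds)}",
            "",
            "per-class F1 (mean +/- s.d. over folds), pooled AUCs:",
        ]
        for name in self.class_names:
            lines.append(f"  {name:<16} F1 {f1.loc[name, 'mean']:.2f}+/-{f1.loc[name, 'sd']:.2f}"
                         f"   ROC-AUC {auc.loc[name, 'roc_auc']:.3f}"
                         f"   PR-AUC {auc.loc[name, 'pr_auc']:.3f}")
        lines += [
            "",
            f"pooled macro F1:          {self.macro_f1():.3f}",
            f"AML vs control accuracy:  {self.aml_vs_control_accuracy():.3f}",
            "",
            "pooled confusion matrix (rows = truth):",
            self.confusion.to_string(),
        ]
        return "\n".join(lines)


def cross_validate(bags: list, cfg: MILConfig | None = None, k: int = 5,
                   seed: int | None = None) -> CrossValidationResults:
    """Train one model per fold and pool the test predictions.

    Fold splitting is patient-level and class-stratified; pooling the folds'
    test sets counts every patient exactly once in the final confusion matrix.
    """
    cfg = cfg or MILConfig()
    seed = cfg.seed if seed is None else seed
    pids = [b.patient_id for b in bags]
    labels = [int(b.label) for b in bags]
    folds = make_folds(pids, labels, k=k, seed=seed, class_names=cfg.class_names)
    index_of = {pid: i for i, pid in enumerate(pids)}

    fold_results = []
    y_true, y_pred, probs, pooled_ids = [], [], [], []
    for fold in folds:
        fold_cfg = replace(cfg, seed=int(np.random.SeedSequence([seed, fold.fold])
                                         .generate_state(1)[0] % (2 ** 31)))
        model = AttentionMIL(bags, fold_cfg)
        res = model.fit(train_idx=[index_of[p] for p in fold.train_ids],
                        val_idx=[index_of[p] for p in fold.val_ids])
        fold_results.append(res)
        for pid in fold.test_ids:
            bag = bags[index_of[pid]]
            pred = res.predict(bag)
            y_true.append(bag.label)
            y_pred.append(pred.predicted_index)
            probs.append(pred.probabilities)
            pooled_ids.append(pid)
    return CrossValidationResults(folds, fold_results, y_true, y_pred,
                                  probs, pooled_ids, cfg.class_names)
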