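"""Single-cell feature extraction: the f_feat contract.

A supervised single-cell classifier is trained on annotated cell images; its
pre-pooling convolutional activations, flattened, become the fixed-length
feature vector x_i of each cell. Two backbones implement the contract:

* ``resnet34`` — the full-scale recipe (SGD at 5e-4, patience 10, flip /
  rotation / translation / rescale / random-erasing augmentation, probabilistic
  oversampling). At 144x144 input the pre-pooling stage is 512x5x5, giving
  d = 12800. Provided forward-only here: training it requires an annotated
  corpus of a scale this package does not ship.
* ``tiny_cnn`` — a three-stage stride-2 CNN (8/16/8 channels) that trains on a
  CPU in minutes and is the tested path on synthetic cell images.

The feature dimension is a pure function of backbone and input size.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from ._nn import (Adam, Conv2d, GlobalAvgPool, Layer, Linear, MaxPool2d, ReLU,
                  SGD, Sequential, cross_entropy, softmax)


@dataclass(frozen=True)
class ExtractorConfig:
    backbone: str = "resnet34"              # 'resnet34' | 'tiny_cnn'
    input_size: int = 144
    num_classes: int = 21                   # 23 annotated cell types minus 2 excluded
    init: str = "random"                    # 'random' | 'pretrained-imagenet'
    optimizer: str = "sgd"
    learning_rate: float = 5e-4
    patience: int = 10
    max_epochs: int = 100
    batch_size: int = 32
    augment: tuple[str, ...] = ("hflip", "vflip", "rotate", "translate", "rescale", "erase")
    oversample: bool = True
    excluded_classes: tuple[str, ...] = ()  # e.g. tiny annotated classes to drop
    seed: int = 0

    def validate(self) -> None:
        if self.backbone not in ("resnet34", "tiny_cnn"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.input_size < 8:
            raise ValueError("input_size must be >= 8")


# ---------------------------------------------------------------------------
# backbones


class _Backbone:
    """A feature trunk plus a (pool + linear) classification head."""

    trunk: Sequential
    head: Sequential
    input_size: int

    def forward_features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Pre-pooling activations, unflattened (N, C, H, W)."""
        return self.trunk.forward(x, train=train)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.head.forward(self.forward_features(x, train=train), train=train)

    @property
    def feature_dim(self) -> int:
        """Flattened length of the pre-pooling activations; depends only on
        the architecture and the input size."""
        probe = np.zeros((1, 3, self.input_size, self.input_size), dtype=np.float32)
        return int(np.prod(self.forward_features(probe).shape[1:]))


class TinyCNN(_Backbone):
    """Three stride-2 conv stages, channels (8, 16, 8); trainable on CPU.

    The spatial extent of the final map is ceil(input/8), so a 24-pixel input
    yields an 8x3x3 map (d = 72) and a 144-pixel input yields 8x18x18.
    """

    trainable = True

    def __init__(self, num_classes: int, input_size: int, rng: np.random.Generator):
        self.input_size = input_size
        self.trunk = Sequential(
            Conv2d(3, 8, 3, stride=2, pad=1, rng=rng), ReLU(),
            Conv2d(8, 16, 3, stride=2, pad=1, rng=rng), ReLU(),
            Conv2d(16, 8, 3, stride=2, pad=1, rng=rng), ReLU(),
        )
        self.head = Sequential(GlobalAvgPool(), Linear(8, num_classes, rng=rng))

    def backward(self, dlogits: np.ndarray) -> None:
        self.trunk.backward(self.head.backward(dlogits))

    def zero_grads(self) -> None:
        self.trunk.zero_grads()
        self.head.zero_grads()

    @property
    def params_and_grads(self):
        return (self.trunk.all_params + self.head.all_params,
                self.trunk.all_grads + self.head.all_grads)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params_and_grads[0]]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params_and_grads[0], weights):
            p[...] = w


class _BasicBlock(Layer):
    """Two 3x3 convs with identity (or 1x1 projection) shortcut."""

    def __init__(self, c_in: int, c_out: int, stride: int, rng):
        super().__init__()
        self.conv1 = Conv2d(c_in, c_out, 3, stride=stride, pad=1, rng=rng)
        self.conv2 = Conv2d(c_out, c_out, 3, stride=1, pad=1, rng=rng)
        self.relu = ReLU()
        self.down = (Conv2d(c_in, c_out, 1, stride=stride, rng=rng)
                     if stride != 1 or c_in != c_out else None)

    def forward(self, x, train=False):
        out = self.conv2.forward(self.relu.forward(self.conv1.forward(x)))
        skip = self.down.forward(x) if self.down is not None else x
        return np.maximum(out + skip, 0)


class ResNet34(_Backbone):
    """Standard 34-layer residual trunk, inference only (normalization layers
    are folded into the convolutions, as in deployment-time inference).

    Stage plan: 7x7/2 conv (64) -> 3x3/2 maxpool -> blocks [3, 4, 6, 3] at
    channels [64, 128, 256, 512] with stride 2 between stages. At 144x144 the
    trunk output is 512x5x5 -> d = 12800.
    """

    trainable = False

    def __init__(self, num_classes: int, input_size: int, rng: np.random.Generator):
        self.input_size = input_size
        layers: list[Layer] = [
            Conv2d(3, 64, 7, stride=2, pad=3, rng=rng), ReLU(),
            MaxPool2d(3, stride=2, pad=1),
        ]
        c_in = 64
        for c_out, n_blocks, stride in ((64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2)):
            for b in range(n_blocks):
                layers.append(_BasicBlock(c_in, c_out, stride if b == 0 else 1, rng))
                c_in = c_out
        self.trunk = Sequential(*layers)
        self.head = Sequential(GlobalAvgPool(), Linear(512, num_classes, rng=rng))


def build_backbone(cfg: ExtractorConfig) -> _Backbone:
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    cls = {"tiny_cnn": TinyCNN, "resnet34": ResNet34}[cfg.backbone]
    return cls(cfg.num_classes, cfg.input_size, rng)


def feature_dim(backbone: str, input_size: int) -> int:
    """Flattened pre-pooling feature length for a backbone at a given input size."""
    cfg = ExtractorConfig(backbone=backbone, input_size=input_size, num_classes=2)
    return build_backbone(cfg).feature_dim


# ---------------------------------------------------------------------------
# augmentation


def _augment_batch(batch: np.ndarray, flags: tuple[str, ...],
                   rng: np.random.Generator) -> np.ndarray:
    """Apply the configured random augmentations to an NCHW float batch."""
    out = batch.copy()
    n = len(out)
    if "hflip" in flags:
        idx = rng.random(n) < 0.5
        out[idx] = out[idx, :, :, ::-1]
    if "vflip" in flags:
        idx = rng.random(n) < 0.5
        out[idx] = out[idx, :, ::-1, :]
    if "rotate" in flags:
        for i in np.nonzero(rng.random(n) < 0.5)[0]:
            ang = rng.uniform(-20, 20)
            out[i] = ndimage.rotate(out[i], ang, axes=(1, 2), reshape=False,
                                    order=1, mode="nearest")
    if "translate" in flags:
        for i in np.nonzero(rng.random(n) < 0.5)[0]:
            dy, dx = rng.integers(-3, 4, size=2)
            out[i] = np.roll(out[i], (dy, dx), axis=(1, 2))
    if "rescale" in flags:
        for i in np.nonzero(rng.random(n) < 0.3)[0]:
            z = rng.uniform(0.9, 1.1)
            img = ndimage.zoom(out[i], (1, z, z), order=1)
            img = _center_fit(img, out.shape[2], out.shape[3])
            out[i] = img
    if "erase" in flags:
        h, w = out.shape[2], out.shape[3]
        for i in np.nonzero(rng.random(n) < 0.3)[0]:
            eh, ew = rng.integers(2, max(3, h // 6), 2)
            y0 = rng.integers(0, h - eh)
            x0 = rng.integers(0, w - ew)
            out[i, :, y0:y0 + eh, x0:x0 + ew] = 0.0
    return out


def _center_fit(img: np.ndarray, h: int, w: int) -> np.ndarray:
    """Center-crop or zero-pad a CHW image to (h, w)."""
    c, ih, iw = img.shape
    if ih >= h:
        y0 = (ih - h) // 2
        img = img[:, y0:y0 + h, :]
    if iw >= w:
        x0 = (iw - w) // 2
        img = img[:, :, x0:x0 + w]
    c, ih, iw = img.shape
    if ih < h or iw < w:
        padded = np.zeros((c, h, w), dtype=img.dtype)
        padded[:, (h - ih) // 2:(h - ih) // 2 + ih, (w - iw) // 2:(w - iw) // 2 + iw] = img
        img = padded
    return img


def oversampling_probabilities(labels: np.ndarray) -> np.ndarray:
    """Per-sample probabilities inversely proportional to class frequency.

    Sampling an epoch with these makes the expected class distribution uniform.
    """
    labels = np.asarray(labels)
    _, inverse, counts = np.unique(labels, return_inverse=True, return_counts=True)
    p = 1.0 / counts[inverse]
    return p / p.sum()


# ---------------------------------------------------------------------------
# training and extraction


@dataclass
class TrainedExtractor:
    """A fitted single-cell classifier with its evaluation artifacts."""

    backbone: _Backbone
    config: ExtractorConfig
    confusion_matrix: np.ndarray        # test-set rows = true class
    history: pd.DataFrame               # per-epoch train/val loss
    best_epoch: int

    @property
    def feature_dim(self) -> int:
        return self.backbone.feature_dim

    @property
    def test_accuracy(self) -> float:
        cm = self.confusion_matrix
        return float(np.trace(cm) / cm.sum())


def _to_nchw(images: np.ndarray | list) -> np.ndarray:
    """HWC uint8 images -> NCHW float32 in [0, 1]."""
    arr = np.stack([np.asarray(im) for im in images])
    if arr.ndim == 3:                       # grayscale
        arr = np.repeat(arr[:, :, :, None], 3, axis=3)
    return (arr.transpose(0, 3, 1, 2).astype(np.float32)) / 255.0


def train_extractor(images, labels, cfg: ExtractorConfig,
                    split: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
                    ) -> TrainedExtractor:
    """Train a single-cell classifier with CCE, augmentation and oversampling.

    ``split`` gives (train, val, test) index arrays; when omitted a seeded
    60-20-20 stratified split is drawn. Training early-stops when validation
    loss has not improved for ``cfg.patience`` consecutive epochs and restores
    the best-validation weights (earliest epoch on ties).
    """
    cfg.validate()
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes present")
    x = _to_nchw(images)
    if x.shape[2] != cfg.input_size:
        raise ValueError(f"images are {x.shape[2]}px but config expects {cfg.input_size}px")
    y = np.searchsorted(classes, labels)

    rng = np.random.default_rng(cfg.seed)
    if split is None:
        split = _stratified_split(y, (0.6, 0.2, 0.2), rng)
    tr, va, te = split

    backbone = build_backbone(cfg)
    if not getattr(backbone, "trainable", False):
        raise NotImplementedError(
            f"backbone {cfg.backbone!r} is provided for inference/feature extraction; "
            "training it requires a full-scale annotated corpus and is not supported here")
    params, grads = backbone.params_and_grads
    opt_cls = {"adam": Adam, "sgd": SGD}[cfg.optimizer.lower()]
    opt = opt_cls(params, grads, lr=cfg.learning_rate)

    sample_p = oversampling_probabilities(y[tr]) if cfg.oversample else None
    best_val, best_weights, best_epoch, since_best = np.inf, backbone.get_weights(), 0, 0
    hist = []
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.choice(tr, size=len(tr), replace=cfg.oversample, p=sample_p)
        ep_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = _augment_batch(x[idx], cfg.augment, rng) if cfg.augment else x[idx]
            backbone.zero_grads()
            logits = backbone.forward(xb, train=True)
            probs = softmax(logits)
            loss = cross_entropy(probs, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    f"lr={cfg.learning_rate}, batch classes={np.bincount(y[idx])}")
            dlogits = probs.copy()
            dlogits[np.arange(len(idx)), y[idx]] -= 1.0
            backbone.backward(dlogits / len(idx))
            opt.step()
            ep_loss += loss * len(idx)
        val_loss = cross_entropy(softmax(backbone.forward(x[va])), y[va])
        hist.append({"epoch": epoch, "train_loss": ep_loss / len(order), "val_loss": val_loss})
        if val_loss < best_val:
            best_val, best_weights, best_epoch, since_best = val_loss, backbone.get_weights(), epoch, 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    backbone.set_weights(best_weights)

    pred = backbone.forward(x[te]).argmax(axis=1)
    k = len(classes)
    cm = np.zeros((k, k), dtype=int)
    np.add.at(cm, (y[te], pred), 1)
    return TrainedExtractor(backbone, cfg, cm, pd.DataFrame(hist), best_epoch)


def _stratified_split(y: np.ndarray, fractions, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    parts: list[list[int]] = [[], [], []]
    for c in np.unique(y):
        idx = np.nonzero(y == c)[0]
        rng.shuffle(idx)
        n = len(idx)
        n_tr = int(round(fractions[0] * n))
        n_va = int(round(fractions[1] * n))
        parts[0] += list(idx[:n_tr])
        parts[1] += list(idx[n_tr:n_tr + n_va])
        parts[2] += list(idx[n_tr + n_va:])
    return tuple(np.array(p) for p in parts)


def extract_features(backbone: _Backbone | TrainedExtractor, images,
                     batch_size: int = 64) -> np.ndarray:
    """Flattened pre-pooling activations for each image, (N, d) float32.

    Inference mode: no augmentation, deterministic.
    """
    if isinstance(backbone, TrainedExtractor):
        backbone = backbone.backbone
    x = _to_nchw(images)
    if x.shape[2] != backbone.input_size or x.shape[3] != backbone.input_size:
        raise ValueError(f"expected {backbone.input_size}px square input, "
                         f"got {x.shape[2]}x{x.shape[3]}")
    chunks = [backbone.forward_features(x[i:i + batch_size]).reshape(len(x[i:i + batch_size]), -1)
              for i in range(0, len(x), batch_size)]
    return np.concatenate(chunks).astype(np.float32)


def export_bags(features: np.ndarray, image_ids: list[str], patient_ids: list[str],
                manifest: pd.DataFrame, out_dir: str | os.PathLike) -> pd.DataFrame:
    """Write one N x d feature matrix per patient plus a row index.

    Row order follows the order of ``image_ids`` within each patient (frozen at
    export so attention scores can later be joined back to images). Every image
    must belong to a manifest patient.
    """
    out_dir = os.fspath(out_dir)
    known = set(manifest["patient_id"])
    orphans = sorted({p for p in patient_ids if p not in known})
    if orphans:
        raise ValueError(f"images reference patients absent from the manifest: {orphans}")
    os.makedirs(out_dir, exist_ok=True)
    patient_ids = np.asarray(patient_ids)
    index_rows = []
    for pid in manifest["patient_id"]:
        rows = np.nonzero(patient_ids == pid)[0]
        pdir = os.path.join(out_dir, pid)
        os.makedirs(pdir, exist_ok=True)
        np.save(os.path.join(pdir, "features.npy"), features[rows].astype(np.float32))
        for k, r in enumerate(rows):
            index_rows.append({"patient_id": pid, "row": k, "image_id": image_ids[r]})
    index = pd.DataFrame(index_rows)
    index.to_csv(os.path.join(out_dir, "bag_index.tsv"), sep="\t", index=False)
    return index
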