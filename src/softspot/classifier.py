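"""Small VGG-style binary fruit-fate classifier.

Training protocol: stochastic gradient descent at learning rate 0.001 with
categorical cross-entropy, class weighting, a stratified 3:1 train/validation
split and light flip/shift augmentation.  The network is a stack of 3x3
convolution + ReLU + 2x2 max-pool blocks followed by a small dense head with
a two-way softmax; it is trained from scratch, so block widths stay modest.

Two convolutional layers are exposed by name for the saliency stage:
``conv_last`` (the deepest, coarsest feature map) and ``conv_shallow`` (one
block up, with twice the spatial resolution) — mirroring the practice of
moving class-activation mapping to a shallower layer when the deepest map is
too coarse to localise small surface features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .images import LabeledImage

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "build_model",
    "split_train_val",
    "train_classifier",
    "predict",
    "evaluate",
    "extract_embeddings",
    "save_model",
    "load_model",
]

POSITIVE, NEGATIVE = 1, 0
DECISION_THRESHOLD = 0.5  # confidence >= 0.5 -> positive (tie goes positive)


@dataclass(frozen=True)
class ModelSpec:
    input_side: int = 224
    block_widths: tuple[int, ...] = (8, 16, 32, 32)
    embed_dim: int = 32

    def __post_init__(self):
        if len(self.block_widths) < 2:
            raise ValueError("need at least two conv blocks for a depth contrast")
        if self.input_side % (2 ** len(self.block_widths)):
            raise ValueError("input_side must be divisible by 2^n_blocks")

    @property
    def named_layers(self) -> dict[str, str]:
        n = len(self.block_widths)
        return {"conv_shallow": f"conv{n - 2}", "conv_last": f"conv{n - 1}"}


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    momentum: float = 0.9
    epochs: int = 30
    batch_size: int = 16
    class_weights: tuple[float, float] | None = None  # (negative, positive); None -> n/(2 n_c)
    augment: bool = True
    shift_px: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.class_weights is not None and min(self.class_weights) <= 0:
            raise ValueError("class weights must be positive")


def build_model(spec: ModelSpec, rng: np.random.Generator) -> nn.Sequential:
    layers = []
    in_ch = 3
    side = spec.input_side
    for i, width in enumerate(spec.block_widths):
        layers.append(nn.Conv2D(in_ch, width, rng, name=f"conv{i}"))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool2())
        in_ch = width
        side //= 2
    layers.append(nn.Flatten())
    layers.append(nn.Dense(in_ch * side * side, spec.embed_dim, rng, name="embed_pre"))
    layers.append(nn.ReLU())
    layers[-1].name = "embed"
    layers.append(nn.Dense(spec.embed_dim, 2, rng, name="logits"))
    model = nn.Sequential(layers, input_offset=0.5)
    model.spec = spec
    model.aliases = dict(spec.named_layers)
    return model


def resolve_layer(model: nn.Sequential, name: str) -> str:
    """Map a logical alias (conv_shallow / conv_last) to a concrete layer."""
    return getattr(model, "aliases", {}).get(name, name)


# ---------------------------------------------------------------------------
# data plumbing


def _to_batch(images) -> np.ndarray:
    """List of LabeledImage or HxWx3 arrays -> (N, 3, H, W) float32."""
    arrs = [im.pixels if isinstance(im, LabeledImage) else np.asarray(im) for im in images]
    x = np.stack(arrs).astype(np.float32)
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def split_train_val(dataset: list[LabeledImage], ratio: tuple[int, int] = (3, 1),
                    seed: int = 0):
    """Stratified disjoint split; ratio (3, 1) puts 3/4 in the train set."""
    labels = np.array([im.label for im in dataset])
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to stratify")
    frac_train = ratio[0] / (ratio[0] + ratio[1])
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        k = int(round(frac_train * len(idx)))
        train_idx.extend(idx[:k])
        val_idx.extend(idx[k:])
    return ([dataset[i] for i in sorted(train_idx)],
            [dataset[i] for i in sorted(val_idx)])


def _augment_batch(x: np.ndarray, rng: np.random.Generator, shift_px: int) -> np.ndarray:
    out = x.copy()
    n = len(out)
    flip_h = rng.random(n) < 0.5
    flip_v = rng.random(n) < 0.5
    shifts = rng.integers(-shift_px, shift_px + 1, size=(n, 2))
    for i in range(n):
        im = out[i]
        if flip_h[i]:
            im = im[:, :, ::-1]
        if flip_v[i]:
            im = im[:, ::-1, :]
        dy, dx = shifts[i]
        if dy or dx:
            im = np.roll(np.roll(im, dy, axis=1), dx, axis=2)
        out[i] = im
    return out


# ---------------------------------------------------------------------------
# training / inference


def train_classifier(train_set, val_set, spec: ModelSpec, cfg: TrainConfig):
    """Train the CNN; returns (model, per-epoch curves DataFrame)."""
    y_train = np.array([im.label for im in train_set])
    if len(np.unique(y_train)) < 2:
        raise ValueError("both classes must be present in the training set")
    x_train = _to_batch(train_set)
    x_val = _to_batch(val_set) if val_set else None
    y_val = np.array([im.label for im in val_set]) if val_set else None

    if cfg.class_weights is None:
        n = len(y_train)
        counts = np.bincount(y_train, minlength=2)
        class_w = n / (2.0 * np.maximum(counts, 1))
    else:
        class_w = np.asarray(cfg.class_weights, dtype=np.float64)

    ss = np.random.SeedSequence(cfg.seed).spawn(2)
    init_rng = np.random.Generator(np.random.PCG64(ss[0]))
    loop_rng = np.random.Generator(np.random.PCG64(ss[1]))

    model = build_model(spec, init_rng)
    opt = nn.SGD(model, lr=cfg.learning_rate, momentum=cfg.momentum)

    onehot = np.eye(2, dtype=np.float32)
    rows = []
    for epoch in range(cfg.epochs):
        order = loop_rng.permutation(len(x_train))
        losses, hits, nseen = [], 0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            if cfg.augment:
                xb = _augment_batch(xb, loop_rng, cfg.shift_px)
            logits = model.forward(xb)
            if not np.isfinite(logits).all():
                raise FloatingPointError("non-finite activations during training")
            loss, dlogits = nn.softmax_xent(logits, onehot[yb], class_w[yb])
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite training loss")
            model.backward(dlogits.astype(np.float32))
            opt.step()
            losses.append(loss * len(idx))
            hits += int((logits.argmax(axis=1) == yb).sum())
            nseen += len(idx)
        row = dict(epoch=epoch, train_loss=float(np.sum(losses) / nseen),
                   train_acc=hits / nseen)
        if x_val is not None:
            p_val = _forward_in_chunks(model, x_val)
            val_loss, _ = nn.softmax_xent(p_val, onehot[y_val])
            row["val_loss"] = val_loss
            row["val_acc"] = float((p_val.argmax(axis=1) == y_val).mean())
        rows.append(row)
    return model, pd.DataFrame(rows)


def _forward_in_chunks(model, x, chunk=32):
    return np.concatenate([model.forward(x[i : i + chunk])
                           for i in range(0, len(x), chunk)])


def predict(model: nn.Sequential, images, model_id: str = "A") -> pd.DataFrame:
    """One PredictionRecord row per image (fruit_id, confidence, labels)."""
    x = _to_batch(images)
    if x.shape[2] != model.spec.input_side:
        raise ValueError(f"images are {x.shape[2]}px, model expects "
                         f"{model.spec.input_side}px")
    probs = nn.softmax(_forward_in_chunks(model, x))
    conf = probs[:, POSITIVE]
    rows = []
    for i, im in enumerate(images):
        fid = im.fruit_id if isinstance(im, LabeledImage) else f"img{i:04d}"
        true = im.label if isinstance(im, LabeledImage) else None
        rows.append(dict(fruit_id=fid, model_id=model_id,
                         confidence_positive=float(conf[i]),
                         predicted_label=int(conf[i] >= DECISION_THRESHOLD),
                         true_label=true))
    return pd.DataFrame(rows)


def evaluate(records: pd.DataFrame) -> dict:
    """ROC/AUC, accuracy, per-class precision/recall, confusion matrix @0.5."""
    from sklearn import metrics as skm

    if records["true_label"].isna().any():
        raise ValueError("records must carry true labels")
    y = records["true_label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: only one class present")
    conf = records["confidence_positive"].to_numpy()
    pred = records["predicted_label"].to_numpy(dtype=int)
    fpr, tpr, thr = skm.roc_curve(y, conf)
    cm = skm.confusion_matrix(y, pred, labels=[NEGATIVE, POSITIVE])
    prec, rec, _, _ = skm.precision_recall_fscore_support(
        y, pred, labels=[NEGATIVE, POSITIVE], zero_division=0.0)
    return {
        "auc": float(skm.auc(fpr, tpr)),
        "accuracy": float((pred == y).mean()),
        "roc": {"fpr": fpr.tolist(), "tpr": tpr.tolist(), "thresholds": thr.tolist()},
        "precision": {"negative": float(prec[0]), "positive": float(prec[1])},
        "recall": {"negative": float(rec[0]), "positive": float(rec[1])},
        "confusion_matrix": cm.tolist(),  # rows true [neg, pos], cols predicted
    }


def extract_embeddings(model: nn.Sequential, images) -> np.ndarray:
    """Penultimate-layer (post-ReLU dense) feature vectors, one per image."""
    x = _to_batch(images)
    if x.shape[2] != model.spec.input_side:
        raise ValueError("image size mismatch")
    feats = []
    for i in range(0, len(x), 32):
        model.forward(x[i : i + 32], keep=True)
        feats.append(model.activation("embed").copy())
    return np.concatenate(feats)


# ---------------------------------------------------------------------------
# checkpoints (NPZ arrays + JSON spec)


def save_model(model: nn.Sequential, path):
    path = Path(path)
    arrays, meta = {}, []
    for i, lyr in enumerate(model.layers):
        for j, (w, _) in enumerate(lyr.params()):
            arrays[f"p{i}_{j}"] = w
        meta.append(lyr.name)
    spec = model.spec
    arrays["__spec__"] = np.frombuffer(json.dumps({
        "input_side": spec.input_side,
        "block_widths": list(spec.block_widths),
        "embed_dim": spec.embed_dim,
    }).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> nn.Sequential:
    with np.load(path) as data:
        spec_d = json.loads(bytes(data["__spec__"]).decode())
        spec = ModelSpec(spec_d["input_side"], tuple(spec_d["block_widths"]),
                         spec_d["embed_dim"])
        model = build_model(spec, np.random.default_rng(0))
        for i, lyr in enumerate(model.layers):
            for j, (w, _) in enumerate(lyr.params()):
                w[...] = data[f"p{i}_{j}"]
    return model
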