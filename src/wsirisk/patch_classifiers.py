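"""The four one-vs-rest binary patch classifiers.

Each classifier trains a small CNN (NumPy backbone by default; a torch
ResNet-18 backbone can be selected where torch is installed) with
cross-entropy on the binary relabeling of annotated patches,
class-balanced weighted random sampling, and an exponential
learning-rate schedule lr_k = initial_lr * decay^k.
"""

from __future__ import annotations

import io
import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from wsirisk._random import substream
from wsirisk.nn import Adam, SGDMomentum, SmallCNN, softmax_cross_entropy
from wsirisk.synthetic import CLASSES
from wsirisk.tiling import (
    NORMALIZE_TARGET_MEAN,
    NORMALIZE_TARGET_STD,
    FormatError,
    Patch,
    normalize_patch,
)

__all__ = [
    "TrainConfig",
    "BinaryPatchModel",
    "split_train_validation",
    "train_binary_classifier",
    "predict_patch",
    "predict_patches",
    "patch_to_features",
    "make_weighted_sampler",
    "save_model",
    "load_model",
]

#: Side length of the downsampled CNN input.
FEATURE_SIZE = 28


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    initial_lr: float = 0.005
    lr_decay_per_epoch: float = 0.9
    batch_size: int = 64
    val_slide_fraction: float = 0.1
    positive_threshold: float = 0.5
    seed: int = 0
    backbone: str = "small_cnn"
    optimizer: str = "adam"  # or "sgd" (momentum SGD)
    momentum: float = 0.9
    augment: bool = True
    #: Lower bound on optimizer steps per epoch, so small patch sets
    #: still make progress within a fixed epoch budget.
    min_steps_per_epoch: int = 25

    def __post_init__(self) -> None:
        if not 0 < self.lr_decay_per_epoch <= 1:
            raise ValidationError("lr_decay_per_epoch must be in (0, 1]")
        if not 0 < self.val_slide_fraction < 1:
            raise ValidationError("val_slide_fraction must be in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")

    def lr_at_epoch(self, epoch: int) -> float:
        return self.initial_lr * self.lr_decay_per_epoch**epoch


@dataclass
class BinaryPatchModel:
    """A trained one-vs-rest classifier for a single histologic class."""

    target_class: str
    net: SmallCNN
    config: TrainConfig
    epochs_run: int = 0
    best_epoch: int = 0
    best_val_f1: float = float("nan")
    log: list[dict] = field(default_factory=list)


def split_train_validation(
    slide_ids: Sequence[str], fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive slide-level split with |val| = max(1, round(f*n))."""
    ids = list(slide_ids)
    if len(ids) < 2:
        raise ValidationError("need at least 2 slides to split")
    if not 0 < fraction < 1:
        raise ValidationError("fraction must be in (0, 1)")
    rng = substream(seed, "train-val-split")
    perm = rng.permutation(len(ids))
    n_val = min(max(1, round(fraction * len(ids))), len(ids) - 1)
    val = sorted(ids[i] for i in perm[:n_val])
    train = sorted(ids[i] for i in perm[n_val:])
    return train, val


def patch_to_features(patch: Patch | np.ndarray) -> np.ndarray:
    """Map a patch to the standardized (3, S, S) CNN input.

    uint8 patches pass through color normalization first; float input is
    assumed already normalized to the reference statistics.
    """
    pixels = patch.pixels if isinstance(patch, Patch) else patch
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise FormatError(f"expected (H, W, 3) patch, got {pixels.shape}")
    if np.issubdtype(pixels.dtype, np.integer):
        pixels = normalize_patch(pixels)
    z = (pixels.astype(np.float64) - NORMALIZE_TARGET_MEAN) / NORMALIZE_TARGET_STD
    h, w = z.shape[:2]
    fy, fx = max(h // FEATURE_SIZE, 1), max(w // FEATURE_SIZE, 1)
    hc, wc = (h // fy) * fy, (w // fx) * fx
    z = z[:hc, :wc]
    z = z.reshape(hc // fy, fy, wc // fx, fx, 3).mean(axis=(1, 3))
    if z.shape[0] != FEATURE_SIZE or z.shape[1] != FEATURE_SIZE:
        # Pad or crop to the canonical size for odd input shapes.
        out = np.zeros((FEATURE_SIZE, FEATURE_SIZE, 3))
        sy, sx = min(FEATURE_SIZE, z.shape[0]), min(FEATURE_SIZE, z.shape[1])
        out[:sy, :sx] = z[:sy, :sx]
        z = out
    return z.transpose(2, 0, 1).astype(np.float32)


def make_weighted_sampler(labels: np.ndarray, rng: np.random.Generator):
    """Sampler drawing with replacement, per-example weight ∝ 1/class freq."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    weight_of = {c: 1.0 / n for c, n in zip(classes, counts)}
    weights = np.array([weight_of[c] for c in labels])
    p = weights / weights.sum()

    def sample(batch_size: int) -> np.ndarray:
        return rng.choice(len(labels), size=batch_size, replace=True, p=p)

    return sample


def _augment_features(batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Flips, 90-degree rotations, and mild brightness jitter on the
    standardized feature tensors (cheap stand-in for full-resolution
    augmentation during the training loop)."""
    out = np.empty_like(batch)
    flips_h = rng.random(len(batch)) < 0.5
    flips_v = rng.random(len(batch)) < 0.5
    rots = rng.integers(0, 4, size=len(batch))
    jitter = rng.uniform(0.95, 1.05, size=len(batch))
    for i, x in enumerate(batch):
        if flips_h[i]:
            x = x[:, :, ::-1]
        if flips_v[i]:
            x = x[:, ::-1, :]
        x = np.rot90(x, k=int(rots[i]), axes=(1, 2))
        out[i] = x * jitter[i]
    return out


def _binary_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0


def train_binary_classifier(
    patches: Sequence[Patch],
    target_class: str,
    config: TrainConfig = TrainConfig(),
    features: np.ndarray | None = None,
) -> BinaryPatchModel:
    """Train a one-vs-rest classifier for `target_class`.

    Patches must carry annotation classes; negatives are the union of
    the other three classes. Validation is held out at the slide level,
    and the checkpoint with the best validation F1 is returned.
    `features` may pass precomputed `patch_to_features` tensors to avoid
    recomputation across the four tasks.
    """
    if target_class not in CLASSES:
        raise ValidationError(f"unknown target class {target_class!r}")
    if config.backbone not in ("small_cnn", "resnet18"):
        raise ValidationError(f"unknown backbone {config.backbone!r}")
    if config.backbone == "resnet18":
        raise ValidationError(
            "the resnet18 backbone requires torch, which is not installed; "
            "use backbone='small_cnn'"
        )

    labeled = [(i, p) for i, p in enumerate(patches) if p.annotation_class]
    if not labeled:
        raise ValidationError("no annotated patches provided")
    y_all = np.array(
        [1 if p.annotation_class == target_class else 0 for _, p in labeled]
    )
    if y_all.sum() == 0:
        raise ValidationError(f"no positive examples for class {target_class!r}")
    if y_all.sum() == len(y_all):
        raise ValidationError(f"no negative examples for class {target_class!r}")

    if features is None:
        feats = np.stack([patch_to_features(p) for _, p in labeled])
    else:
        feats = np.stack([features[i] for i, _ in labeled])

    slide_ids = sorted({p.slide_id for _, p in labeled})
    if len(slide_ids) >= 2:
        train_slides, val_slides = split_train_validation(
            slide_ids, config.val_slide_fraction, config.seed
        )
        in_val = np.array([p.slide_id in set(val_slides) for _, p in labeled])
        # Degenerate splits (a class only present on one side) fall back
        # to patch-level validation.
        if len(set(y_all[~in_val])) < 2:
            in_val = np.zeros(len(labeled), dtype=bool)
    else:
        warnings.warn("only one slide available; validating on training patches")
        in_val = np.zeros(len(labeled), dtype=bool)
    x_train, y_train = feats[~in_val], y_all[~in_val]
    if in_val.any() and len(set(y_all[in_val].tolist())) == 2:
        x_val, y_val = feats[in_val], y_all[in_val]
    else:
        x_val, y_val = x_train, y_train

    rng = substream(config.seed, f"train:{target_class}")
    net = SmallCNN(rng, n_classes=2)
    if config.optimizer == "adam":
        optimizer = Adam(net.params)
    elif config.optimizer == "sgd":
        optimizer = SGDMomentum(net.params, momentum=config.momentum)
    else:
        raise ValidationError(f"unknown optimizer {config.optimizer!r}")
    sampler = make_weighted_sampler(y_train, rng)
    batches_per_epoch = max(
        config.min_steps_per_epoch, math.ceil(len(y_train) / config.batch_size)
    )

    log: list[dict] = []
    best = {"epoch": -1, "f1": -1.0, "params": None}
    for epoch in range(config.epochs):
        lr = config.lr_at_epoch(epoch)
        epoch_loss = 0.0
        for _ in range(batches_per_epoch):
            idx = sampler(config.batch_size)
            xb = x_train[idx].astype(np.float64)
            if config.augment:
                xb = _augment_features(xb, rng)
            logits, cache = net.forward(xb)
            loss, dlogits = softmax_cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch} for class {target_class!r} "
                    f"(lr={lr}); reduce the learning rate"
                )
            grads = net.backward(cache, dlogits)
            optimizer.step(net.params, grads, lr)
            epoch_loss += loss
        probs = net.predict_proba(x_val.astype(np.float64))[:, 1]
        y_hat = (probs >= config.positive_threshold).astype(int)
        val_acc = float((y_hat == y_val).mean())
        val_f1 = _binary_f1(y_val, y_hat)
        log.append(
            {
                "epoch": epoch,
                "loss": epoch_loss / batches_per_epoch,
                "val_accuracy": val_acc,
                "val_f1": val_f1,
                "lr": lr,
            }
        )
        # >= keeps the most-trained checkpoint among ties.
        if val_f1 >= best["f1"]:
            best = {
                "epoch": epoch,
                "f1": val_f1,
                "params": {k: v.copy() for k, v in net.params.items()},
            }
    net.params = best["params"]
    return BinaryPatchModel(
        target_class=target_class,
        net=net,
        config=config,
        epochs_run=config.epochs,
        best_epoch=best["epoch"],
        best_val_f1=best["f1"],
        log=log,
    )


def predict_patches(
    model: BinaryPatchModel,
    patches: Sequence[Patch | np.ndarray],
    features: np.ndarray | None = None,
) -> np.ndarray:
    """Positive-class probabilities for a batch of patches."""
    if features is None:
        features = np.stack([patch_to_features(p) for p in patches])
    return model.net.predict_proba(np.asarray(features, dtype=np.float64))[:, 1]


def predict_patch(model: BinaryPatchModel, patch: Patch | np.ndarray) -> tuple[float, bool]:
    """(probability, binary label); label is positive when probability
    reaches the configured threshold (>= convention)."""
    prob = float(predict_patches(model, [patch])[0])
    return prob, prob >= model.config.positive_threshold


# ---------------------------------------------------------------------------
# Serialization: single-file .npz archive with a JSON metadata entry.


def save_model(model: BinaryPatchModel, path) -> Path:
    path = Path(path)
    meta = {
        "target_class": model.target_class,
        "config": asdict(model.config),
        "epochs_run": model.epochs_run,
        "best_epoch": model.best_epoch,
        "best_val_f1": model.best_val_f1,
        "log": model.log,
    }
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode("utf-8"), dtype=np.uint8),
        **model.net.params,
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_model(path) -> BinaryPatchModel:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode("utf-8"))
        params = {k: archive[k] for k in archive.files if k != "__meta__"}
    config = TrainConfig(**meta["config"])
    net = SmallCNN(substream(0, "load"), n_classes=params["bf"].shape[0])
    net.params = params
    return BinaryPatchModel(
        target_class=meta["target_class"],
        net=net,
        config=config,
        epochs_run=meta["epochs_run"],
        best_epoch=meta["best_epoch"],
        best_val_f1=meta["best_val_f1"],
        log=meta["log"],
    )


def write_training_log(model: BinaryPatchModel, path) -> None:
    import pandas as pd

    pd.DataFrame(model.log).to_csv(path, index=False)
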