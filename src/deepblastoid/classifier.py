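"""Training and inference harness for microwell morphology classification.

The recipe mirrors common practice for fine-tuning a small CNN on a few
thousand labeled microwell tiles: horizontal/vertical flips, color jitter
(p = 0.4), random scaling with factor in [0.8, 1.0], random erasing
(p = 0.2), cross-entropy loss, AdamW (lr 3e-4, weight decay 1e-3) with
gradient clipping, and a 10x learning-rate multiplier on the
classification head. The default schedule is 36 epochs at batch size 62,
which puts ceil(1796/62) = 29 parameter updates in one epoch of a
1796-image training set.

The central object is :class:`BlastoidClassifier`, a scikit-learn style
estimator (``fit`` / ``predict`` / ``predict_proba``) backed by a NumPy
CNN. ``tiny_cnn`` is the desk-scale backbone, operating on 64 x 64 inputs;
the backbone registry is pluggable for larger architectures.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import _nn
from .labels import ClassLabel, CLASS_NAMES, N_CLASSES, encode_labels

__all__ = [
    "TrainConfig",
    "TrainingLog",
    "BlastoidClassifier",
    "augment",
    "cross_entropy",
    "iterations_per_epoch",
    "cumulative_iterations",
    "train",
    "predict_proba",
    "ablate_augmentations",
    "BACKBONES",
]


@dataclasses.dataclass
class TrainConfig:
    """Hyperparameters of the training recipe (defaults follow the recipe
    described in the module docstring)."""

    epochs: int = 36
    learning_rate: float = 3e-4
    weight_decay: float = 1e-3
    batch_size: int = 62
    grad_clip_max_norm: float = 1.0
    head_lr_multiplier: float = 10.0
    backbone: str = "tiny_cnn"
    input_size: int | None = None  # None -> backbone default
    hflip: bool = True
    vflip: bool = True
    jitter: bool = True
    scaling: bool = True
    erasing: bool = True
    jitter_prob: float = 0.4
    erasing_prob: float = 0.2
    scale_range: tuple[float, float] = (0.8, 1.0)
    jitter_factor_range: tuple[float, float] = (0.8, 1.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        for name in ("learning_rate", "weight_decay", "batch_size", "grad_clip_max_norm", "head_lr_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.jitter_prob <= 1 or not 0 <= self.erasing_prob <= 1:
            raise ValueError("augmentation probabilities must lie in [0, 1]")


def iterations_per_epoch(n_train: int, batch_size: int) -> int:
    """Number of parameter updates in one pass over the training set."""
    if n_train < 1 or batch_size < 1:
        raise ValueError("n_train and batch_size must be >= 1")
    return math.ceil(n_train / batch_size)


def cumulative_iterations(epochs: int, n_train: int, batch_size: int) -> int:
    """Total parameter updates after a number of whole epochs."""
    return epochs * iterations_per_epoch(n_train, batch_size)


# ---------------------------------------------------------------------------
# augmentation


def _resize(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if img.shape == shape:
        return img
    return _sk_resize(img, shape, order=1, anti_aliasing=False, preserve_range=True).astype(
        img.dtype if np.issubdtype(img.dtype, np.floating) else np.float32
    )


def augment(
    image: np.ndarray,
    config: TrainConfig,
    seed: int | np.random.Generator = 0,
    return_ops: bool = False,
):
    """Apply the stochastic training augmentations to one float image.

    Flips are drawn at p = 0.5 each, color jitter at ``jitter_prob``
    (brightness and contrast factors uniform in ``jitter_factor_range``),
    random scaling always when enabled (factor uniform in ``scale_range``,
    the shrunk image is padded back to size with the image median), random
    erasing at ``erasing_prob`` (a random rectangle covering 2-20% of the
    area, filled with the image median). With every augmentation disabled
    the input is returned unchanged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img = np.asarray(image, dtype=np.float32)
    ops: dict[str, bool | float] = {}

    if config.hflip:
        if rng.random() < 0.5:
            img = img[:, ::-1]
            ops["hflip"] = True
    if config.vflip:
        if rng.random() < 0.5:
            img = img[::-1, :]
            ops["vflip"] = True

    if config.scaling:
        f = float(rng.uniform(*config.scale_range))
        ops["scale_factor"] = f
        h, w = img.shape
        nh, nw = max(1, round(h * f)), max(1, round(w * f))
        if (nh, nw) != (h, w):
            small = _resize(img, (nh, nw))
            fill = float(np.median(img))
            out = np.full((h, w), fill, dtype=np.float32)
            oy, ox = (h - nh) // 2, (w - nw) // 2
            out[oy : oy + nh, ox : ox + nw] = small
            img = out

    if config.jitter and rng.random() < config.jitter_prob:
        b = rng.uniform(*config.jitter_factor_range)
        c = rng.uniform(*config.jitter_factor_range)
        mean = img.mean()
        img = (img * b - mean) * c + mean
        ops["jitter"] = True

    if config.erasing and rng.random() < config.erasing_prob:
        h, w = img.shape
        area = rng.uniform(0.02, 0.2) * h * w
        aspect = rng.uniform(0.3, 3.3)
        eh = min(h, max(1, round(np.sqrt(area * aspect))))
        ew = min(w, max(1, round(np.sqrt(area / aspect))))
        y0 = int(rng.integers(0, h - eh + 1))
        x0 = int(rng.integers(0, w - ew + 1))
        img = img.copy()
        img[y0 : y0 + eh, x0 : x0 + ew] = np.median(img)
        ops["erasing"] = True

    img = np.ascontiguousarray(img)
    return (img, ops) if return_ops else img


# ---------------------------------------------------------------------------
# loss


def cross_entropy(p: Sequence[float], true_label: ClassLabel | str | int, eps: float = 1e-12) -> float:
    """Cross-entropy of a single 5-class probability vector against a one-hot
    target: ``-log(p_true)``. Zero iff the true class has probability 1;
    a zero probability is clamped at ``eps`` rather than returning inf."""
    p = np.asarray(p, dtype=np.float64)
    if p.shape != (N_CLASSES,):
        raise ValueError(f"probability vector must have {N_CLASSES} entries")
    if np.any(p < 0):
        raise ValueError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("probabilities must sum to 1 (within 1e-6)")
    code = int(ClassLabel.from_any(true_label))
    return float(-np.log(max(p[code], eps)))


# ---------------------------------------------------------------------------
# backbones


def _build_tiny_cnn(input_size: int, rng: np.random.Generator):
    """Three conv/pool stages, a hidden dense layer and a 5-way head.

    Designed for 64 x 64 tiles; any input size divisible by 8 works.
    """
    if input_size % 8:
        raise ValueError("tiny_cnn input size must be divisible by 8")
    s8 = input_size // 8
    layers = [
        _nn.Conv2d(1, 8, 3, rng),
        _nn.BatchNorm2d(8),
        _nn.ReLU(),
        _nn.MaxPool2(),
        _nn.Conv2d(8, 16, 3, rng),
        _nn.BatchNorm2d(16),
        _nn.ReLU(),
        _nn.MaxPool2(),
        _nn.Conv2d(16, 32, 3, rng),
        _nn.BatchNorm2d(32),
        _nn.ReLU(),
        _nn.MaxPool2(),
        _nn.Flatten(),
        _nn.Linear(32 * s8 * s8, 64, rng),
        _nn.ReLU(),
        _nn.Linear(64, N_CLASSES, rng),
    ]
    net = _nn.Sequential(layers)
    return net, layers[-1]  # head is the final fully connected layer


#: name -> (builder(input_size, rng) -> (net, head_layer), default input size)
BACKBONES: dict = {"tiny_cnn": (_build_tiny_cnn, 64)}


@dataclasses.dataclass
class TrainingLog:
    """Per-iteration training loss and per-epoch validation metrics."""

    iter_loss: list[float] = dataclasses.field(default_factory=list)
    epoch_val_loss: list[float] = dataclasses.field(default_factory=list)
    epoch_top1: list[float] = dataclasses.field(default_factory=list)
    epoch_top2: list[float] = dataclasses.field(default_factory=list)
    iterations_per_epoch: int = 0
    epochs: int = 0

    @property
    def iterations(self) -> int:
        return len(self.iter_loss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"iteration": np.arange(1, self.iterations + 1), "loss": self.iter_loss})


class BlastoidClassifier(BaseEstimator, ClassifierMixin):
    """Five-class CNN classifier over grayscale microwell tiles.

    Parameters mirror :class:`TrainConfig`; see the module docstring for
    the recipe. ``X`` is an array of shape (n, h, w): uint16 images are
    mapped to [0, 1] by a fixed /65535 scale (not per-image min-max) so
    intensity semantics are comparable across tiles; floats are assumed
    already in [0, 1]. Images are resized to ``input_size`` (backbone
    default when None) at fit/predict time.

    Evaluation-mode inference is deterministic: identical inputs give
    bit-identical probability vectors.
    """

    def __init__(
        self,
        backbone: str = "tiny_cnn",
        epochs: int = 36,
        learning_rate: float = 3e-4,
        weight_decay: float = 1e-3,
        batch_size: int = 62,
        grad_clip_max_norm: float = 1.0,
        head_lr_multiplier: float = 10.0,
        input_size: int | None = None,
        hflip: bool = True,
        vflip: bool = True,
        jitter: bool = True,
        scaling: bool = True,
        erasing: bool = True,
        random_state: int = 0,
    ) -> None:
        self.backbone = backbone
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.grad_clip_max_norm = grad_clip_max_norm
        self.head_lr_multiplier = head_lr_multiplier
        self.input_size = input_size
        self.hflip = hflip
        self.vflip = vflip
        self.jitter = jitter
        self.scaling = scaling
        self.erasing = erasing
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    def _config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            batch_size=self.batch_size,
            grad_clip_max_norm=self.grad_clip_max_norm,
            head_lr_multiplier=self.head_lr_multiplier,
            backbone=self.backbone,
            input_size=self.input_size,
            hflip=self.hflip,
            vflip=self.vflip,
            jitter=self.jitter,
            scaling=self.scaling,
            erasing=self.erasing,
            seed=self.random_state,
        )

    def _preprocess(self, X: np.ndarray, size: int) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 3:
            raise ValueError("X must have shape (n, h, w)")
        if np.issubdtype(X.dtype, np.integer):
            X = X.astype(np.float32) / 65535.0
        else:
            X = X.astype(np.float32)
        if X.shape[1:] != (size, size):
            X = np.stack([_resize(img, (size, size)) for img in X])
        return X[:, None, :, :]  # (n, 1, s, s)

    # -- estimator API ----------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None) -> "BlastoidClassifier":
        """Train on images X with labels y (names, codes or ClassLabel).

        An optional validation set adds per-epoch validation loss and
        top-1/top-2 accuracy to the training log.
        """
        cfg = self._config()
        if cfg.backbone not in BACKBONES:
            raise ValueError(
                f"unknown backbone {cfg.backbone!r}; registered: {sorted(BACKBONES)}"
            )
        builder, default_size = BACKBONES[cfg.backbone]
        size = cfg.input_size or default_size
        y = encode_labels(y)
        X = np.asarray(X)
        if len(X) == 0 or len(X) != len(y):
            raise ValueError("X and y must be nonempty and aligned")
        if np.unique(y).size < 2 and cfg.epochs > 0:
            raise ValueError("training data must contain at least 2 classes")

        rng = np.random.default_rng(cfg.seed)
        net, head = builder(size, rng)
        opt = _nn.AdamW(
            net,
            lr=cfg.learning_rate,
            weight_decay=cfg.weight_decay,
            lr_multipliers={id(head): cfg.head_lr_multiplier},
        )
        Xp = self._preprocess(X, size)
        n = len(Xp)
        ipe = iterations_per_epoch(n, cfg.batch_size)
        log = TrainingLog(iterations_per_epoch=ipe, epochs=cfg.epochs)

        if X_val is not None:
            Xv = self._preprocess(np.asarray(X_val), size)
            yv = encode_labels(y_val)

        aug_enabled = cfg.hflip or cfg.vflip or cfg.jitter or cfg.scaling or cfg.erasing
        for _epoch in range(cfg.epochs):
            net.train()
            perm = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = perm[start : start + cfg.batch_size]
                xb = Xp[idx]
                if aug_enabled:
                    xb = np.stack([augment(img[0], cfg, rng) for img in xb])[:, None]
                logits = net.forward(xb)
                loss, dlogits = _nn.softmax_cross_entropy(logits, y[idx])
                net.backward(dlogits)
                _nn.clip_grad_norm(net, cfg.grad_clip_max_norm)
                opt.step()
                log.iter_loss.append(loss)
            if X_val is not None:
                net.eval()
                vlogits = net.forward(Xv)
                vloss, _ = _nn.softmax_cross_entropy(vlogits, yv)
                vp = _nn.softmax(vlogits)
                order = np.argsort(-vp, axis=1, kind="stable")
                log.epoch_val_loss.append(vloss)
                log.epoch_top1.append(float((order[:, 0] == yv).mean()))
                log.epoch_top2.append(float((order[:, :2] == yv[:, None]).any(axis=1).mean()))

        net.eval()
        self.net_ = net
        self.classes_ = np.array(CLASS_NAMES)
        self.input_size_ = size
        self.training_log_ = log
        self.config_ = cfg
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Softmax class probabilities, rows summing to 1; deterministic."""
        check_is_fitted(self, "net_")
        Xp = self._preprocess(np.asarray(X), self.input_size_)
        logits = self.net_.forward(Xp)
        return _nn.softmax(logits.astype(np.float64))

    def predict(self, X) -> np.ndarray:
        """Predicted class names; argmax ties break to the lowest class index."""
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def predict_codes(self, X) -> np.ndarray:
        """Predicted integer class codes (A=0 .. W=4)."""
        return np.argmax(self.predict_proba(X), axis=1)

    def score(self, X, y) -> float:
        return float(np.mean(self.predict_codes(X) == encode_labels(y)))

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write weights (.npz) plus a JSON sidecar with backbone, config
        hash and class order."""
        check_is_fitted(self, "net_")
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.net_.state_dict())
        cfg = dataclasses.asdict(self.config_)
        sidecar = {
            "backbone": self.backbone,
            "input_size": self.input_size_,
            "classes": list(self.classes_),
            "config": cfg,
            "config_hash": hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "BlastoidClassifier":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg = sidecar["config"]
        est = cls(
            backbone=sidecar["backbone"],
            input_size=sidecar["input_size"],
            epochs=cfg["epochs"],
            learning_rate=cfg["learning_rate"],
            weight_decay=cfg["weight_decay"],
            batch_size=cfg["batch_size"],
            random_state=cfg["seed"],
        )
        builder, _ = BACKBONES[sidecar["backbone"]]
        rng = np.random.default_rng(cfg["seed"])
        net, _head = builder(sidecar["input_size"], rng)
        state = dict(np.load(path.with_suffix(".npz")))
        net.load_state_dict(state)
        net.eval()
        est.net_ = net
        est.classes_ = np.array(sidecar["classes"])
        est.input_size_ = sidecar["input_size"]
        est.training_log_ = TrainingLog()
        est.config_ = TrainConfig(**{**cfg, "scale_range": tuple(cfg["scale_range"]), "jitter_factor_range": tuple(cfg["jitter_factor_range"])})
        return est


# ---------------------------------------------------------------------------
# functional wrappers


def train(
    X, y, config: TrainConfig | None = None, X_val=None, y_val=None
) -> tuple[BlastoidClassifier, TrainingLog]:
    """Train a classifier from a TrainConfig; thin wrapper over the estimator."""
    cfg = config or TrainConfig()
    est = BlastoidClassifier(
        backbone=cfg.backbone,
        epochs=cfg.epochs,
        learning_rate=cfg.learning_rate,
        weight_decay=cfg.weight_decay,
        batch_size=cfg.batch_size,
        grad_clip_max_norm=cfg.grad_clip_max_norm,
        head_lr_multiplier=cfg.head_lr_multiplier,
        input_size=cfg.input_size,
        hflip=cfg.hflip,
        vflip=cfg.vflip,
        jitter=cfg.jitter,
        scaling=cfg.scaling,
        erasing=cfg.erasing,
        random_state=cfg.seed,
    )
    est.fit(X, y, X_val=X_val, y_val=y_val)
    return est, est.training_log_


def predict_proba(model: BlastoidClassifier, images) -> np.ndarray:
    """Probability vectors for a batch of images (wrapper)."""
    return model.predict_proba(images)


_ABLATIONS = [
    ("full", {}),
    ("w/o hflip", {"hflip": False}),
    ("w/o vflip", {"vflip": False}),
    ("w/o jitter", {"jitter": False}),
    ("w/o scaling", {"scaling": False}),
    ("w/o erasing", {"erasing": False}),
    ("none", {"hflip": False, "vflip": False, "jitter": False, "scaling": False, "erasing": False}),
]


def ablate_augmentations(
    X_train, y_train, X_val, y_val, base_config: TrainConfig | None = None
) -> pd.DataFrame:
    """Retrain with each augmentation knocked out and report validation
    macro F1 per configuration (rows: full, five single knockouts, none)."""
    from .evaluation import class_metrics, confusion_matrix

    cfg = base_config or TrainConfig()
    rows = []
    for name, overrides in _ABLATIONS:
        c = dataclasses.replace(cfg, **overrides)
        est, _ = train(X_train, y_train, c)
        preds = est.predict_codes(X_val)
        cm = confusion_matrix(encode_labels(y_val), preds)
        metrics = class_metrics(cm)
        rows.append({"ablation": name, "macro_f1": metrics["macro_f1"], "accuracy": metrics["accuracy"]})
    return pd.DataFrame(rows)
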