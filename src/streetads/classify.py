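"""Advertisement content classification.

The classifier seam is a contract — ``fit`` on a labelled crop set under a
training configuration, ``predict`` a category with a score — so deep
backbones can plug in. The default is a desk-scale model: fixed colour /
texture histogram features feeding a multinomial logistic regression. It
needs no GPU or pretrained weights and separates the synthetic procedural
textures cleanly; it is not expected to rival a deep network on real
photographs.

Class imbalance is handled by oversampling minority classes to the
majority count, and training samples receive random rotations within a
configurable limit, mirroring the usual augmentation for photographed
signage at varying camera roll.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from skimage.color import rgb2gray
from skimage.transform import resize, rotate
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_fscore_support

from .core import CATEGORIES


@dataclass
class TrainConfig:
    """Training schedule; defaults follow the transfer-learning recipe
    of the original workflow (five 100-step epochs, batch 32, 224-px
    inputs, 30-degree rotation augmentation)."""

    epochs: int = 5
    steps_per_epoch: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-4
    input_size: int = 224
    rotation_limit_deg: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("epochs", "steps_per_epoch", "batch_size", "learning_rate", "input_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.rotation_limit_deg <= 180:
            raise ValueError("rotation_limit_deg must be in [0, 180]")


@dataclass
class LabelledCropSet:
    crops: list[np.ndarray]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.crops) != len(self.labels):
            raise ValueError("crops and labels length mismatch")
        bad = set(self.labels) - set(CATEGORIES)
        if bad:
            raise ValueError(f"labels outside the category set: {sorted(bad)}")

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels:
            out[lab] = out.get(lab, 0) + 1
        return out


@runtime_checkable
class ClassifierContract(Protocol):
    def fit(self, data: LabelledCropSet, config: TrainConfig) -> None: ...

    def predict(self, crop: np.ndarray) -> tuple[str, float]: ...


def oversample(data: LabelledCropSet, seed: int = 0) -> LabelledCropSet:
    """Balance class counts by resampling minorities with replacement.

    Every class ends at the majority-class count; the original samples are
    always kept, so the input multiset is a subset of the output.
    """
    counts = data.class_counts()
    present = set(counts)
    missing = set(np.unique(data.labels)) - present
    if missing or not counts:
        raise ValueError("every class in the set must have at least one sample")
    rng = np.random.default_rng(seed)
    target = max(counts.values())
    crops = list(data.crops)
    labels = list(data.labels)
    for lab in sorted(counts):
        idx = [i for i, l in enumerate(data.labels) if l == lab]
        extra = target - len(idx)
        if extra > 0:
            for i in rng.choice(idx, size=extra, replace=True):
                crops.append(data.crops[int(i)])
                labels.append(lab)
    return LabelledCropSet(crops=crops, labels=labels)


def rotation_angle(limit_deg: float, seed: int) -> float:
    """The seeded augmentation angle: uniform on [-limit, +limit] degrees."""
    if limit_deg < 0:
        raise ValueError("limit_deg must be non-negative")
    if limit_deg == 0:
        return 0.0
    return float(np.random.default_rng(seed).uniform(-limit_deg, limit_deg))


def augment_rotate(crop: np.ndarray, limit_deg: float, seed: int) -> np.ndarray:
    """Rotate by a seeded uniform angle in [-limit, +limit]; size preserved.

    Corner fill is zero, matching the masked-crop convention.
    """
    angle = rotation_angle(limit_deg, seed)
    if angle == 0.0:
        return crop
    out = rotate(crop.astype(float), angle, resize=False, cval=0.0, order=1)
    return np.clip(np.round(out), 0, 255).astype(crop.dtype) if np.issubdtype(
        crop.dtype, np.integer
    ) else out


_FEATURE_SIZE = 48  # crops are downscaled to this square before featurisation


def crop_features(crop: np.ndarray) -> np.ndarray:
    """Fixed colour/texture feature vector for one crop.

    Per-channel 8-bin intensity histograms, channel means/standard
    deviations, and gradient-magnitude statistics on the grayscale image.
    Deterministic; no training involved.
    """
    img = resize(crop.astype(float) / 255.0, (_FEATURE_SIZE, _FEATURE_SIZE), anti_aliasing=True)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    feats = []
    for ch in range(3):
        hist, _ = np.histogram(img[..., ch], bins=8, range=(0, 1))
        feats.append(hist / img[..., ch].size)
        feats.append([img[..., ch].mean(), img[..., ch].std()])
    gray = rgb2gray(img)
    gy, gx = np.gradient(gray)
    mag = np.hypot(gx, gy)
    ghist, _ = np.histogram(mag, bins=6, range=(0, 0.5))
    feats.append(ghist / mag.size)
    feats.append([mag.mean(), mag.std()])
    return np.concatenate([np.asarray(f, dtype=float).ravel() for f in feats])


class DeskClassifier:
    """Histogram features + multinomial logistic regression.

    ``fit`` honours the schedule by drawing ``epochs * steps_per_epoch``
    batches of ``batch_size`` rotation-augmented samples from the
    oversampled training set and fitting the convex model on the pooled
    draws (the learning rate only applies to gradient-trained plug-ins).
    """

    def __init__(self) -> None:
        self._model: LogisticRegression | None = None
        self._classes: list[str] = []

    def fit(self, data: LabelledCropSet, config: TrainConfig | None = None) -> None:
        config = config or TrainConfig()
        balanced = oversample(data, seed=config.seed)
        rng = np.random.default_rng(config.seed + 1)
        small = [resize(c.astype(float), (_FEATURE_SIZE, _FEATURE_SIZE), anti_aliasing=True) * 255
                 for c in balanced.crops]
        n_draws = config.epochs * config.steps_per_epoch * config.batch_size
        idx = rng.integers(0, len(small), size=n_draws)
        x, y = [], []
        for j, i in enumerate(idx):
            crop = augment_rotate(small[int(i)], config.rotation_limit_deg, seed=int(rng.integers(1 << 31)))
            x.append(crop_features(crop))
            y.append(balanced.labels[int(i)])
        self._model = LogisticRegression(max_iter=300)
        self._model.fit(np.asarray(x), y)
        self._classes = list(self._model.classes_)

    def predict(self, crop: np.ndarray) -> tuple[str, float]:
        if self._model is None:
            raise RuntimeError("classifier is not fitted")
        probs = self._model.predict_proba(crop_features(crop)[None, :])[0]
        k = int(np.argmax(probs))
        return self._classes[k], float(probs[k])

    def predict_many(self, crops: Sequence[np.ndarray]) -> list[tuple[str, float]]:
        if self._model is None:
            raise RuntimeError("classifier is not fitted")
        x = np.asarray([crop_features(c) for c in crops])
        probs = self._model.predict_proba(x)
        ks = probs.argmax(axis=1)
        return [(self._classes[int(k)], float(p[int(k)])) for k, p in zip(ks, probs)]


@dataclass
class PRF:
    precision: float
    recall: float
    f1: float


def weighted_prf(predictions: Sequence[str], truths: Sequence[str]) -> PRF:
    """Support-weighted precision, recall and F1.

    Per-class metrics come from the confusion matrix; the aggregate weights
    each class by its share of the true labels. Classes with a zero
    denominator contribute 0 and emit a warning.
    """
    if len(predictions) == 0:
        raise ValueError("empty prediction set")
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths length mismatch")
    labels = sorted(set(truths) | set(predictions))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        p, r, f, _ = precision_recall_fscore_support(
            truths, predictions, labels=labels, average="weighted", zero_division=0
        )
    for c in caught:
        warnings.warn(str(c.message), stacklevel=2)
    return PRF(precision=float(p), recall=float(r), f1=float(f))


def per_class_prf(predictions: Sequence[str], truths: Sequence[str], labels: Sequence[str] | None = None) -> dict[str, PRF]:
    if len(predictions) == 0:
        raise ValueError("empty prediction set")
    labels = sorted(set(truths) | set(predictions)) if labels is None else list(labels)
    p, r, f, _ = precision_recall_fscore_support(
        truths, predictions, labels=labels, average=None, zero_division=0
    )
    return {lab: PRF(float(pi), float(ri), float(fi)) for lab, pi, ri, fi in zip(labels, p, r, f)}


def balanced_subset_eval(
    model: ClassifierContract,
    data: LabelledCropSet,
    minority_class: str,
    pool_class: str,
    k_subsets: int = 5,
    seed: int = 0,
) -> dict[str, PRF]:
    """Evaluate on k balanced two-class subsets and average per-class metrics.

    Each subset pairs every minority-class sample with an equal-size random
    draw (without replacement within the subset) from the pool class; the
    per-class precision/recall/F1 are averaged over subsets. This is the
    usual remedy when one class dwarfs the other and a single pooled score
    would be dominated by it.
    """
    minority_idx = [i for i, l in enumerate(data.labels) if l == minority_class]
    pool_idx = [i for i, l in enumerate(data.labels) if l == pool_class]
    if not minority_idx:
        raise ValueError(f"no samples of minority class {minority_class!r}")
    if len(pool_idx) < len(minority_idx):
        raise ValueError("pool class smaller than minority class")
    rng = np.random.default_rng(seed)
    sums = {minority_class: np.zeros(3), pool_class: np.zeros(3)}
    for _ in range(k_subsets):
        chosen = rng.choice(pool_idx, size=len(minority_idx), replace=False)
        idx = minority_idx + [int(i) for i in chosen]
        preds = [model.predict(data.crops[i])[0] for i in idx]
        truths = [data.labels[i] for i in idx]
        scores = per_class_prf(preds, truths, labels=[minority_class, pool_class])
        for lab in sums:
            s = scores[lab]
            sums[lab] += np.array([s.precision, s.recall, s.f1])
    return {lab: PRF(*(v / k_subsets)) for lab, v in sums.items()}
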