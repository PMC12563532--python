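"""Synthetic long-tailed image classification data.

Each class is assigned a fixed smooth random spatial pattern (its
*prototype*); a sample is its class prototype (or, in multi-label mode, the
superposition of two prototypes) plus per-pixel Gaussian noise, clipped to
[0, 1]. Class sizes follow a geometric law ``n_c = head_count * ratio^c``
floored at ``min_count``, spanning ISIC-like head:tail ratios. The ratio of
prototype contrast to noise standard deviation is the difficulty dial: with
no noise a linear probe on raw pixels is essentially perfect, with large
noise it approaches chance.

Datasets round-trip through an on-disk layout of PNG images plus a
delimited label table; real data laid out the same way loads through the
same reader.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .capr import ClassStats

__all__ = [
    "SyntheticDatasetSpec",
    "Dataset",
    "LabeledSplit",
    "PerturbProfile",
    "class_counts",
    "generate_dataset",
    "split_labeled",
    "perturb",
    "save_dataset",
    "load_dataset",
]


@dataclass
class SyntheticDatasetSpec:
    """Recipe for one synthetic long-tailed dataset.

    ``contrast`` is the peak amplitude of the class prototype around the 0.5
    gray level; ``noise_sigma`` the per-pixel additive noise std. Defaults
    give a task where a linear pixel probe trained on all data does well but
    a small labeled subset leaves clear headroom. ``counts`` overrides the
    geometric law with explicit per-class sizes (e.g. real dataset counts).
    """

    n_classes: int = 5
    head_count: int = 400
    imbalance_ratio: float = 0.5
    min_count: int = 10
    image_size: int = 32
    label_mode: str = "single"  # or "multi"
    multi_label_overlap: float = 0.3
    contrast: float = 0.3
    noise_sigma: float = 0.45
    test_per_class: int = 100
    seed: int = 0
    counts: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.label_mode not in ("single", "multi"):
            raise ValueError("label_mode must be 'single' or 'multi'")
        if self.head_count < self.min_count:
            raise ValueError("head_count must be >= min_count")
        if not 0.0 < self.imbalance_ratio <= 1.0:
            raise ValueError("imbalance_ratio must be in (0, 1]")


@dataclass
class Dataset:
    """In-memory dataset: images in [0,1], multi-hot labels, class stats."""

    X: np.ndarray  # n x H x W
    Y: np.ndarray  # n x C, binary
    X_test: np.ndarray
    Y_test: np.ndarray
    class_stats: ClassStats
    label_mode: str = "single"
    spec: SyntheticDatasetSpec | None = None

    @property
    def n_classes(self) -> int:
        return self.Y.shape[1]

    @property
    def image_shape(self) -> tuple[int, ...]:
        return self.X.shape[1:]


@dataclass
class LabeledSplit:
    """Stratified partition of training indices into labeled and unlabeled."""

    labeled: np.ndarray
    unlabeled: np.ndarray
    label_fraction: float


def class_counts(spec: SyntheticDatasetSpec) -> np.ndarray:
    """Geometric class-size law, floored at ``min_count``, nonincreasing."""
    if spec.counts is not None:
        counts = np.asarray(spec.counts, dtype=int)
        if counts.size != spec.n_classes or np.any(counts < 1):
            raise ValueError("explicit counts must give a positive size per class")
        return counts
    ranks = np.arange(spec.n_classes)
    raw = np.round(spec.head_count * spec.imbalance_ratio**ranks).astype(int)
    return np.maximum(raw, spec.min_count)


def _prototypes(spec: SyntheticDatasetSpec, rng: np.random.Generator) -> np.ndarray:
    """One smooth zero-mean pattern per class, peak amplitude 1."""
    size = spec.image_size
    protos = np.empty((spec.n_classes, size, size))
    for c in range(spec.n_classes):
        raw = rng.normal(size=(size, size))
        smooth = gaussian_filter(raw, sigma=size / 8.0, mode="reflect")
        smooth -= smooth.mean()
        protos[c] = smooth / np.abs(smooth).max()
    return protos


def _render(protos, labels, spec, rng) -> np.ndarray:
    """labels: n x C multi-hot -> images = 0.5 + contrast * mean(protos) + noise."""
    signal = labels @ protos.reshape(spec.n_classes, -1)
    signal /= np.maximum(labels.sum(axis=1, keepdims=True), 1)
    imgs = 0.5 + spec.contrast * signal.reshape(-1, spec.image_size, spec.image_size)
    imgs += rng.normal(0.0, spec.noise_sigma, size=imgs.shape)
    return np.clip(imgs, 0.0, 1.0)


def _make_labels(primary: np.ndarray, spec: SyntheticDatasetSpec,
                 rng: np.random.Generator) -> np.ndarray:
    n = primary.size
    Y = np.zeros((n, spec.n_classes), dtype=int)
    Y[np.arange(n), primary] = 1
    if spec.label_mode == "multi":
        extra = rng.random(n) < spec.multi_label_overlap
        shift = rng.integers(1, spec.n_classes, size=n)
        second = (primary + shift) % spec.n_classes
        Y[np.arange(n)[extra], second[extra]] = 1
    return Y


def generate_dataset(spec: SyntheticDatasetSpec) -> Dataset:
    """Sample a full dataset (long-tailed train set + balanced test set)."""
    rng = np.random.default_rng(spec.seed)
    protos = _prototypes(spec, rng)
    counts = class_counts(spec)

    primary = np.repeat(np.arange(spec.n_classes), counts)
    Y = _make_labels(primary, spec, rng)
    X = _render(protos, Y, spec, rng)

    primary_test = np.repeat(np.arange(spec.n_classes), spec.test_per_class)
    Y_test = _make_labels(primary_test, spec, rng)
    X_test = _render(protos, Y_test, spec, rng)

    return Dataset(X=X, Y=Y, X_test=X_test, Y_test=Y_test,
                   class_stats=ClassStats(counts), label_mode=spec.label_mode,
                   spec=spec)


def split_labeled(dataset: Dataset, fraction: float, seed: int = 0) -> LabeledSplit:
    """Stratified labeled/unlabeled split of the training set.

    Each class contributes ``round(fraction * n_c)`` labeled samples, at
    least one. ``fraction=1`` labels everything.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    primary = dataset.Y.argmax(axis=1)
    labeled: list[np.ndarray] = []
    unlabeled: list[np.ndarray] = []
    for c in range(dataset.n_classes):
        idx = np.flatnonzero(primary == c)
        idx = rng.permutation(idx)
        n_lab = idx.size if fraction == 1.0 else max(1, round(fraction * idx.size))
        labeled.append(idx[:n_lab])
        unlabeled.append(idx[n_lab:])
    return LabeledSplit(
        labeled=np.sort(np.concatenate(labeled)),
        unlabeled=np.sort(np.concatenate(unlabeled)) if any(
            u.size for u in unlabeled) else np.array([], dtype=int),
        label_fraction=fraction,
    )


@dataclass
class PerturbProfile:
    """Strengths of the stochastic input perturbations.

    crop: max fraction of each side removed before resizing back;
    flip_prob: horizontal flip probability; brightness / contrast_jitter:
    half-widths of uniform additive / multiplicative intensity jitter;
    blur_max: upper bound of the Gaussian-blur sigma (pixels).
    """

    crop: float = 0.15
    flip_prob: float = 0.5
    brightness: float = 0.1
    contrast_jitter: float = 0.1
    blur_max: float = 0.8

    def is_zero(self) -> bool:
        return (self.crop == 0 and self.flip_prob == 0 and self.brightness == 0
                and self.contrast_jitter == 0 and self.blur_max == 0)

    @classmethod
    def zero(cls) -> "PerturbProfile":
        return cls(crop=0.0, flip_prob=0.0, brightness=0.0,
                   contrast_jitter=0.0, blur_max=0.0)


def _resize_bilinear(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    h, w = img.shape
    if (h, w) == (out_h, out_w):
        return img
    rows = np.linspace(0, h - 1, out_h)
    cols = np.linspace(0, w - 1, out_w)
    r0 = np.clip(rows.astype(int), 0, h - 2)
    c0 = np.clip(cols.astype(int), 0, w - 2)
    fr = (rows - r0)[:, None]
    fc = (cols - c0)[None, :]
    a = img[np.ix_(r0, c0)]
    b = img[np.ix_(r0, c0 + 1)]
    c = img[np.ix_(r0 + 1, c0)]
    d = img[np.ix_(r0 + 1, c0 + 1)]
    return (a * (1 - fr) * (1 - fc) + b * (1 - fr) * fc
            + c * fr * (1 - fc) + d * fr * fc)


def perturb(image: np.ndarray, profile: PerturbProfile,
            rng: np.random.Generator | int) -> np.ndarray:
    """Random crop-and-resize, flip, intensity jitter and blur; seedable."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    img = np.asarray(image, dtype=float)
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("image values must lie in [0, 1]")
    if profile.is_zero():
        return img.copy()
    h, w = img.shape
    if profile.crop > 0:
        keep = 1.0 - rng.uniform(0.0, profile.crop)
        ch, cw = max(2, round(h * keep)), max(2, round(w * keep))
        r = rng.integers(0, h - ch + 1)
        c = rng.integers(0, w - cw + 1)
        img = _resize_bilinear(img[r:r + ch, c:c + cw], h, w)
    if profile.flip_prob > 0 and rng.random() < profile.flip_prob:
        img = img[:, ::-1]
    if profile.brightness > 0:
        img = img + rng.uniform(-profile.brightness, profile.brightness)
    if profile.contrast_jitter > 0:
        gain = 1.0 + rng.uniform(-profile.contrast_jitter, profile.contrast_jitter)
        img = 0.5 + (img - 0.5) * gain
    if profile.blur_max > 0:
        sigma = rng.uniform(0.0, profile.blur_max)
        if sigma > 1e-3:
            img = gaussian_filter(img, sigma=sigma, mode="reflect")
    return np.clip(img, 0.0, 1.0)


def perturb_batch(images: np.ndarray, profile: PerturbProfile,
                  rng: np.random.Generator) -> np.ndarray:
    return np.stack([perturb(im, profile, rng) for im in images])


# ---------------------------------------------------------------------------
# on-disk layout: <dir>/images/*.png + <dir>/labels.csv
# ---------------------------------------------------------------------------

def save_dataset(dataset: Dataset, out_dir: str) -> None:
    """Write images as 8-bit PNG plus a labels table with a train/test split
    column."""
    import imageio.v3 as iio

    img_dir = os.path.join(out_dir, "images")
    os.makedirs(img_dir, exist_ok=True)
    rows = []
    stacks = [("train", dataset.X, dataset.Y), ("test", dataset.X_test, dataset.Y_test)]
    i = 0
    for split, X, Y in stacks:
        for x, y in zip(X, Y):
            fname = f"img_{i:06d}.png"
            iio.imwrite(os.path.join(img_dir, fname),
                        np.round(x * 255).astype(np.uint8))
            rows.append({"filename": fname, "split": split,
                         **{f"class_{c}": int(v) for c, v in enumerate(y)}})
            i += 1
    table = pd.DataFrame(rows)
    table.to_csv(os.path.join(out_dir, "labels.csv"), index=False)


def load_dataset(in_dir: str, label_mode: str = "single") -> Dataset:
    """Read a directory-of-images + label-table dataset (synthetic or real)."""
    import imageio.v3 as iio

    table = pd.read_csv(os.path.join(in_dir, "labels.csv"))
    class_cols = [c for c in table.columns if c.startswith("class_")]
    if not class_cols:
        raise ValueError("labels.csv has no class_<i> columns")
    parts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for split, sub in table.groupby(table.get("split", "train")):
        X = np.stack([
            iio.imread(os.path.join(in_dir, "images", f)).astype(float) / 255.0
            for f in sub["filename"]
        ])
        parts[str(split)] = (X, sub[class_cols].to_numpy(dtype=int))
    X, Y = parts.get("train", next(iter(parts.values())))
    X_test, Y_test = parts.get("test", (X[:0], Y[:0]))
    counts = np.maximum(np.bincount(Y.argmax(axis=1), minlength=len(class_cols)), 1)
    return Dataset(X=X, Y=Y, X_test=X_test, Y_test=Y_test,
                   class_stats=ClassStats(counts), label_mode=label_mode)
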