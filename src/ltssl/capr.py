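"""Class-adaptive pseudo-label refinement (CAPR).

Pseudo-labels from the teacher network are filtered with a per-class
confidence threshold that (a) ramps up over the early epochs, so noisy
early-training predictions are admitted conservatively, and (b) is higher
for head classes than for tail classes, so the abundant classes do not
dominate the pseudo-label pool. Surviving entries are weighted by
``1 - H(p')`` where H is the binary entropy of the teacher probability, and
scored with a focal loss against the student prediction.

All probabilities are treated per class, one-vs-rest — the same formulation
serves single-label (softmax column) and multi-label (sigmoid) heads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = [
    "ClassStats",
    "ThresholdSchedule",
    "PseudoLabelBatch",
    "FocalConfig",
    "class_weights",
    "threshold_at",
    "thresholds_at",
    "make_pseudo_labels",
    "entropy_weights",
    "pseudo_label_loss",
    "pseudo_label_loss_tensor",
]

PROB_EPS = 1e-7


def class_weights(counts) -> np.ndarray:
    """Inverse-frequency class weights ``v_c = (1/D_c) / sum_k (1/D_k)``.

    Rarer classes receive larger weight; the vector sums to one.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 1:
        raise ValueError("counts must be a nonempty vector")
    if np.any(counts <= 0):
        raise ValueError("all class counts must be positive")
    inv = 1.0 / counts
    return inv / inv.sum()


@dataclass
class ClassStats:
    """Per-class training-set sizes and the derived inverse-frequency weights."""

    counts: np.ndarray
    weights: np.ndarray = field(init=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.weights = class_weights(self.counts)

    @property
    def n_classes(self) -> int:
        return self.counts.size


@dataclass
class ThresholdSchedule:
    """Per-class pseudo-label threshold ramping from eps_min toward eps_max.

    At epoch t the class-c threshold is

        eps_c(t) = eps_min + (eps_max - eps_min) * min(t/ramp_epochs, 1)
                   * [1 + 0.1 * (1 - v_c)]

    clipped to [eps_min, clip_hi]. The bracket makes head classes (small
    v_c) face a stricter threshold than tail classes. ``literal_max``
    replaces min by max — the degenerate form that pins the ramp at its
    ceiling from epoch 0 — for fidelity experiments only.
    """

    class_stats: ClassStats
    eps_min: float = 0.6
    eps_max: float = 0.95
    ramp_epochs: int = 30
    clip_hi: float = 0.99
    literal_max: bool = False

    def __post_init__(self):
        if not (0.0 < self.eps_min <= self.eps_max < 1.0):
            raise ValueError("need 0 < eps_min <= eps_max < 1")
        if self.eps_max > self.clip_hi or self.clip_hi >= 1.0:
            raise ValueError("need eps_max <= clip_hi < 1")
        if self.ramp_epochs < 1:
            raise ValueError("ramp_epochs must be >= 1")

    @classmethod
    def fixed(cls, threshold: float, n_classes: int) -> "ThresholdSchedule":
        """A non-adaptive schedule: every class, every epoch uses `threshold`."""
        stats = ClassStats(np.ones(n_classes, dtype=int))
        return cls(class_stats=stats, eps_min=threshold, eps_max=threshold,
                   clip_hi=max(threshold, 0.99))


def thresholds_at(schedule: ThresholdSchedule, epoch: int) -> np.ndarray:
    """Vector of per-class thresholds at the given epoch."""
    if epoch < 0:
        raise ValueError("epoch must be nonnegative")
    frac = epoch / schedule.ramp_epochs
    frac = max(frac, 1.0) if schedule.literal_max else min(frac, 1.0)
    v = schedule.class_stats.weights
    eps = schedule.eps_min + (schedule.eps_max - schedule.eps_min) * frac * (
        1.0 + 0.1 * (1.0 - v)
    )
    return np.clip(eps, schedule.eps_min, schedule.clip_hi)


def threshold_at(schedule: ThresholdSchedule, epoch: int, class_index: int) -> float:
    thresholds = thresholds_at(schedule, epoch)
    if not 0 <= class_index < thresholds.size:
        raise IndexError(f"class index {class_index} out of range")
    return float(thresholds[class_index])


def entropy_weights(teacher_probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Binary entropy ``H`` (base 2, so H in [0,1]) and confidence weight
    ``1 - H`` for each teacher probability."""
    p = np.clip(np.asarray(teacher_probs, dtype=float), PROB_EPS, 1.0 - PROB_EPS)
    H = -(p * np.log2(p) + (1.0 - p) * np.log2(1.0 - p))
    H = np.clip(H, 0.0, 1.0)
    return H, 1.0 - H


@dataclass
class PseudoLabelBatch:
    """Teacher-derived pseudo-label targets for U unlabeled samples x C classes.

    ``hard_labels[i,c] = 1`` where the teacher probability clears the class
    threshold; ``confidence_mask`` additionally admits confident negatives
    (probability below ``1 - eps_c``); ``weights = 1 - entropy``.
    """

    teacher_probs: np.ndarray
    hard_labels: np.ndarray
    confidence_mask: np.ndarray
    entropy: np.ndarray
    weights: np.ndarray
    thresholds: np.ndarray

    @property
    def n_confident(self) -> int:
        return int(self.confidence_mask.sum())


def make_pseudo_labels(
    teacher_probs: np.ndarray, schedule: ThresholdSchedule, epoch: int
) -> PseudoLabelBatch:
    """Threshold teacher probabilities into pseudo-labels + confidence mask."""
    p = np.asarray(teacher_probs, dtype=float)
    if p.ndim != 2:
        raise ValueError("teacher_probs must be U x C")
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    eps = thresholds_at(schedule, epoch)
    if eps.size != p.shape[1]:
        raise ValueError("schedule class count does not match probability columns")
    hard = (p > eps).astype(float)
    mask = ((p > eps) | (p < 1.0 - eps)).astype(float)
    H, w = entropy_weights(p)
    return PseudoLabelBatch(
        teacher_probs=p, hard_labels=hard, confidence_mask=mask,
        entropy=H, weights=w, thresholds=eps,
    )


@dataclass
class FocalConfig:
    """Focal-loss modulation: ``-alpha * (1 - p_t)^gamma * ln(p_t)``."""

    alpha: float = 0.25
    gamma: float = 2.0
    reduction: str = "sum"  # bare sum, or "mean" over mask-passing entries

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if self.reduction not in ("mean", "sum"):
            raise ValueError("reduction must be 'mean' or 'sum'")


def pseudo_label_loss_tensor(
    student_probs: Tensor, batch: PseudoLabelBatch, focal: FocalConfig
) -> Tensor:
    """Differentiable entropy-weighted focal loss against pseudo-labels.

    ``p_t`` is the student probability of the pseudo-label event: p where the
    hard label is 1, 1-p where it is 0. Entries failing the confidence mask
    contribute nothing; the default reduction divides by their count.
    """
    p = as_tensor(student_probs)
    q = batch.hard_labels
    mask = batch.confidence_mask
    w = batch.weights
    n_conf = mask.sum()
    if n_conf == 0:
        return Tensor(0.0) * p.sum()
    p = p.clip(PROB_EPS, 1.0 - PROB_EPS)
    p_t = p * Tensor(q) + (1.0 - p) * Tensor(1.0 - q)
    focal_term = -focal.alpha * (1.0 - p_t) ** focal.gamma * p_t.log()
    total = (focal_term * Tensor(w * mask)).sum()
    if focal.reduction == "mean":
        return total / n_conf
    return total


def pseudo_label_loss(
    student_probs: np.ndarray, batch: PseudoLabelBatch, focal: FocalConfig
) -> float:
    """See :func:`pseudo_label_loss_tensor`; NumPy-in, float-out."""
    p = np.asarray(student_probs, dtype=float)
    if p.shape != batch.teacher_probs.shape:
        raise ValueError("student and teacher probability shapes differ")
    return float(pseudo_label_loss_tensor(Tensor(p), batch, focal).data)
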