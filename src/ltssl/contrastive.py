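"""Semantic discrimination enhancement: supervised contrastive loss on labeled
embeddings.

A batch of N labeled images is passed through the student and the teacher
network under independent perturbations, yielding two embedding matrices.
The two are stacked into a 2N x d feature matrix Z; the label rows are
duplicated accordingly. Pairs of rows sharing a class are *positives* and
their similarity ``S_ij = z_i . z_j`` is pulled up relative to all other
rows, via a temperature-scaled log-softmax over similarities. Anchors with
no positive partner in the batch are skipped.

The loss carries a ``tau / tau0`` prefactor in addition to the usual
``1/tau`` inside the exponentials; both temperatures are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = [
    "ContrastiveConfig",
    "EmbeddingBatch",
    "PositivePairMask",
    "build_feature_matrix",
    "build_positive_mask",
    "similarity_matrix",
    "supervised_contrastive_loss",
    "scl_loss_tensor",
    "normalize_rows",
]

_NORM_EPS = 1e-12


@dataclass
class ContrastiveConfig:
    """Temperatures and embedding handling for the contrastive loss.

    tau scales similarities inside the exponentials; tau0 enters only through
    the global ``tau/tau0`` prefactor. ``binarize_mask`` clamps multi-label
    overlap counts to {0,1} instead of using the overlap as a pair weight.
    """

    tau: float = 0.1
    tau0: float = 0.07
    normalize_embeddings: bool = True
    binarize_mask: bool = False

    def __post_init__(self):
        if self.tau <= 0 or self.tau0 <= 0:
            raise ValueError("temperatures must be positive")


@dataclass
class EmbeddingBatch:
    """Student/teacher embeddings of the same N labeled images (N x d each)."""

    student: np.ndarray
    teacher: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.student = np.asarray(self.student, dtype=float)
        self.teacher = np.asarray(self.teacher, dtype=float)
        if self.student.shape != self.teacher.shape:
            raise ValueError(
                f"student/teacher shape mismatch: "
                f"{self.student.shape} vs {self.teacher.shape}"
            )
        if self.student.ndim != 2 or min(self.student.shape) < 1:
            raise ValueError("embeddings must be a nonempty N x d matrix")
        if self.normalized:
            for mat in (self.student, self.teacher):
                norms = np.linalg.norm(mat, axis=1)
                if not np.allclose(norms, 1.0, atol=1e-6):
                    raise ValueError("normalized flag set but rows are not unit norm")


@dataclass
class PositivePairMask:
    """Pre-subtraction label-overlap matrix ``mask = Y Y^T`` and the
    positive-pair matrix ``m = mask - I`` with the diagonal removed."""

    mask: np.ndarray
    m: np.ndarray


def normalize_rows(x, eps: float = _NORM_EPS):
    """Scale each row to unit Euclidean norm (NumPy array or Tensor)."""
    if isinstance(x, Tensor):
        norms_sq = (x * x).sum(axis=1, keepdims=True)
        if np.any(norms_sq.data < eps**2):
            raise ValueError("cannot normalize a (near-)zero embedding row")
        return x / norms_sq.sqrt()
    x = np.asarray(x, dtype=float)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    if np.any(norms < eps):
        raise ValueError("cannot normalize a (near-)zero embedding row")
    return x / norms


def build_feature_matrix(batch: EmbeddingBatch, config: ContrastiveConfig) -> np.ndarray:
    """Stack student then teacher embeddings into the 2N x d matrix Z."""
    student, teacher = batch.student, batch.teacher
    if config.normalize_embeddings and not batch.normalized:
        student = normalize_rows(student)
        teacher = normalize_rows(teacher)
    return np.concatenate([student, teacher], axis=0)


def _validate_labels(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y)
    if not np.isin(Y, (0, 1)).all():
        raise ValueError("label matrix must be binary")
    if np.any(Y.sum(axis=1) < 1):
        raise ValueError("every label row needs at least one positive class")
    return Y.astype(float)


def build_positive_mask(Y: np.ndarray, binarize: bool = False) -> PositivePairMask:
    """Label-overlap mask ``Y Y^T`` and its diagonal-free counterpart.

    Rows i and N+i of Y duplicate the same ground-truth label, so student and
    teacher views of one image are always a positive pair. For multi-label
    data the off-diagonal entries count overlapping classes unless
    ``binarize`` clamps them to {0,1}.
    """
    Y = _validate_labels(Y)
    mask = Y @ Y.T
    if binarize:
        mask = (mask > 0).astype(float)
    m = mask.copy()
    np.fill_diagonal(m, 0.0)
    return PositivePairMask(mask=mask, m=m)


def similarity_matrix(Z: np.ndarray) -> np.ndarray:
    """Pairwise inner products ``S = Z Z^T``."""
    Z = np.asarray(Z, dtype=float)
    if not np.isfinite(Z).all():
        raise ValueError("feature matrix contains non-finite entries")
    return Z @ Z.T


def scl_loss_tensor(Z: Tensor, Y: np.ndarray, config: ContrastiveConfig) -> Tensor:
    """Differentiable supervised contrastive loss on a stacked 2N x d matrix.

    For each anchor i with at least one positive j (``M_ij > 0``):

        -(tau/tau0) * (1/2N) * (1/sum_j M_ij) *
            sum_j M_ij * log[ exp(S_ij/tau) / sum_{k != i} exp(S_ik/tau) ]

    Anchors without positives contribute zero. Self-similarity is excluded
    from the denominator via a masked log-sum-exp.
    """
    Z = as_tensor(Z)
    n2 = Z.shape[0]
    if n2 < 2 or n2 % 2 != 0:
        raise ValueError("feature matrix must stack student and teacher rows (2N >= 2)")
    pos = build_positive_mask(Y, binarize=config.binarize_mask)
    M = pos.m
    S = Z @ Z.T
    logits = S / config.tau
    # exclude k == i from the denominator (log-sum-exp with -inf on diagonal)
    shift = logits.data.max(axis=1, keepdims=True)
    exp_off = (logits - Tensor(shift)).exp() * Tensor(1.0 - np.eye(n2))
    log_denom = exp_off.sum(axis=1, keepdims=True).log() + Tensor(shift)
    log_prob = logits - log_denom  # 2N x 2N

    row_pos = M.sum(axis=1)
    anchor_ok = row_pos > 0
    if not anchor_ok.any():
        return Tensor(0.0) * Z.sum()  # keeps the graph connected, value 0
    inv_pos = np.where(anchor_ok, 1.0 / np.where(anchor_ok, row_pos, 1.0), 0.0)
    weights = M * inv_pos[:, None]  # rows sum to 1 where the anchor has positives
    per_anchor = (log_prob * Tensor(weights)).sum(axis=1)
    return -(config.tau / config.tau0) * per_anchor.sum() / n2


def supervised_contrastive_loss(
    Z: np.ndarray, Y: np.ndarray, config: ContrastiveConfig
) -> float:
    """Supervised contrastive loss on a prebuilt feature matrix (see
    :func:`scl_loss_tensor`)."""
    Z = np.asarray(Z, dtype=float)
    Y = np.asarray(Y)
    if Z.shape[0] != Y.shape[0]:
        raise ValueError("feature matrix and label matrix disagree on 2N")
    return float(scl_loss_tensor(Tensor(Z), Y, config).data)
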