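"""Mean-teacher training engine.

A *student* network is trained by gradient descent; a *teacher* network —
the exponential moving average of the student's parameters — provides
consistency targets, contrastive partner embeddings, and pseudo-labels.
Each step draws a fixed-composition batch (labeled + unlabeled), applies
independent stochastic perturbations for the two networks, and minimizes

    L = L_sup + lambda(t) * L_cs + beta * L_scl + zeta * L_pl

where L_sup is cross-entropy on labeled samples, L_cs the mean squared
distance between student and teacher probabilities over the whole batch,
L_scl the supervised contrastive loss on labeled embeddings, and L_pl the
class-adaptive pseudo-label loss, activated only in the later phase of
training. lambda(t) follows a Gaussian ramp so early, unreliable
consistency targets cannot dominate.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concatenate
from .capr import (ClassStats, FocalConfig, ThresholdSchedule, make_pseudo_labels,
                   pseudo_label_loss_tensor, thresholds_at, PROB_EPS)
from .contrastive import ContrastiveConfig, normalize_rows, scl_loss_tensor
from .data import Dataset, LabeledSplit, PerturbProfile, perturb_batch
from .metrics import MetricsReport, compute_metrics
from .nn import Adam, MLPBackbone, ema_update as _ema_params

__all__ = [
    "TrainConfig",
    "ModelPair",
    "LossBundle",
    "TrainResult",
    "TwoStreamSampler",
    "ema_update",
    "supervised_loss",
    "consistency_loss",
    "rampup_weight",
    "total_loss",
    "build_model",
    "predict_probs",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    The reference protocol uses batches of 48 (12 labeled + 36 unlabeled),
    Adam with exponential learning-rate decay (x0.9 per epoch), EMA decay
    0.99, a consistency ramp over ``ramp_epochs`` and pseudo-labeling from
    ``capr_start_epoch`` on (defaulting to the end of the ramp). The
    ablation switches map onto the framework's components: consistency
    regularization, the contrastive module and the pseudo-label module; with
    all three off, training degenerates to supervised learning on the
    labeled subset.
    """

    epochs: int = 30
    ramp_epochs: int = 10
    capr_start_epoch: int | None = None
    batch_size: int = 48
    labeled_per_batch: int = 12
    learning_rate: float = 1e-3
    lr_decay: float = 0.9
    ema_decay: float = 0.99
    beta: float = 0.5
    zeta: float = 0.25
    use_consistency: bool = True
    use_sde: bool = True
    use_capr: bool = True
    # CAPR threshold schedule
    eps_min: float = 0.6
    eps_max: float = 0.95
    clip_hi: float = 0.99
    literal_max_ramp: bool = False
    fixed_threshold: float | None = None
    focal: FocalConfig = field(default_factory=FocalConfig)
    contrastive: ContrastiveConfig = field(default_factory=ContrastiveConfig)
    perturb: PerturbProfile = field(default_factory=PerturbProfile)
    hidden: tuple[int, ...] = (256, 128)
    proj_dim: int = 64
    independent_teacher_init: bool = False
    eval_every: int = 0  # 0: evaluate only after the final epoch
    eval_model: str = "student"
    seed: int = 0

    def __post_init__(self):
        if self.labeled_per_batch >= self.batch_size and (
                self.use_consistency or self.use_capr):
            raise ValueError("labeled_per_batch must be < batch_size")
        if self.capr_start_epoch is not None and self.capr_start_epoch > self.epochs:
            raise ValueError("capr_start_epoch must be <= epochs")
        if self.eval_model not in ("student", "teacher"):
            raise ValueError("eval_model must be 'student' or 'teacher'")

    @property
    def unlabeled_per_batch(self) -> int:
        return self.batch_size - self.labeled_per_batch

    @property
    def capr_start(self) -> int:
        return self.ramp_epochs if self.capr_start_epoch is None else self.capr_start_epoch


@dataclass
class ModelPair:
    """Student network plus its EMA teacher."""

    student: MLPBackbone
    teacher: MLPBackbone
    ema_decay: float = 0.99


def ema_update(pair: ModelPair) -> ModelPair:
    """One EMA step: teacher <- decay*teacher + (1-decay)*student."""
    _ema_params(pair.student, pair.teacher, pair.ema_decay)
    return pair


@dataclass
class LossBundle:
    """The four loss components, their weights, and the composite total."""

    l_sup: float
    l_cs: float
    l_scl: float
    l_pl: float
    lambda_t: float
    beta: float
    zeta: float
    total: float


def total_loss(l_sup: float, l_cs: float, l_scl: float, l_pl: float,
               lambda_t: float, beta: float, zeta: float) -> LossBundle:
    """Compose the weighted objective; pseudo-label gating (zeroing l_pl
    before the activation epoch) happens upstream."""
    if min(lambda_t, beta, zeta) < 0:
        raise ValueError("loss weights must be nonnegative")
    total = l_sup + lambda_t * l_cs + beta * l_scl + zeta * l_pl
    return LossBundle(l_sup=l_sup, l_cs=l_cs, l_scl=l_scl, l_pl=l_pl,
                      lambda_t=lambda_t, beta=beta, zeta=zeta, total=total)


def rampup_weight(epoch: int, ramp: int) -> float:
    """Gaussian ramp ``exp(-5 (1 - t/T)^2)``, fixed at 1 from epoch T on."""
    if epoch < 0:
        raise ValueError("epoch must be nonnegative")
    if ramp < 1:
        raise ValueError("ramp length must be >= 1")
    if epoch >= ramp:
        return 1.0
    return float(np.exp(-5.0 * (1.0 - epoch / ramp) ** 2))


def _ce_tensor(probs: Tensor, labels: np.ndarray, label_mode: str) -> Tensor:
    p = probs.clip(PROB_EPS, 1.0 - PROB_EPS)
    Y = np.asarray(labels, dtype=float)
    if label_mode == "single":
        return -(Tensor(Y) * p.log()).sum(axis=1).mean()
    bce = -(Tensor(Y) * p.log() + Tensor(1.0 - Y) * (1.0 - p).log())
    return bce.mean()


def supervised_loss(student_probs: np.ndarray, labels: np.ndarray,
                    label_mode: str = "single") -> float:
    """Mean cross-entropy (single-label) or per-class BCE (multi-label)."""
    p = np.asarray(student_probs, dtype=float)
    if p.shape != np.shape(labels):
        raise ValueError("probability and label shapes differ")
    return float(_ce_tensor(Tensor(p), labels, label_mode).data)


def _cs_tensor(student_probs: Tensor, teacher_probs: np.ndarray) -> Tensor:
    diff = student_probs - Tensor(np.asarray(teacher_probs, dtype=float))
    return (diff * diff).sum(axis=1).mean()


def consistency_loss(student_probs: np.ndarray, teacher_probs: np.ndarray) -> float:
    """Mean squared Euclidean distance between probability rows."""
    p = np.asarray(student_probs, dtype=float)
    q = np.asarray(teacher_probs, dtype=float)
    if p.shape != q.shape:
        raise ValueError("probability shapes differ")
    return float(_cs_tensor(Tensor(p), q).data)


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------

class TwoStreamSampler:
    """Fixed-composition batches: l labeled + u unlabeled indices per step.

    Unlabeled indices are covered once per epoch (shuffled, remainder
    dropped); labeled indices cycle through reshuffled permutations so every
    labeled sample recurs across steps. Without unlabeled usage, the epoch
    iterates shuffled labeled-only batches instead.
    """

    def __init__(self, labeled: np.ndarray, unlabeled: np.ndarray,
                 labeled_per_batch: int, unlabeled_per_batch: int,
                 rng: np.random.Generator, use_unlabeled: bool = True):
        if labeled.size == 0:
            raise ValueError("labeled set is empty")
        self.labeled = np.asarray(labeled)
        self.unlabeled = np.asarray(unlabeled)
        self.l_per = min(labeled_per_batch, self.labeled.size)
        self.u_per = unlabeled_per_batch
        self.rng = rng
        self.use_unlabeled = use_unlabeled and self.unlabeled.size > 0
        self._cycle = self.rng.permutation(self.labeled)
        self._ptr = 0

    def _next_labeled(self, n: int) -> np.ndarray:
        out = []
        while n > 0:
            if self._ptr >= self._cycle.size:
                self._cycle = self.rng.permutation(self.labeled)
                self._ptr = 0
            take = min(n, self._cycle.size - self._ptr)
            out.append(self._cycle[self._ptr:self._ptr + take])
            self._ptr += take
            n -= take
        return np.concatenate(out)

    def epoch_batches(self):
        if self.use_unlabeled:
            u_perm = self.rng.permutation(self.unlabeled)
            steps = max(1, u_perm.size // self.u_per)
            for s in range(steps):
                u_batch = u_perm[s * self.u_per:(s + 1) * self.u_per]
                yield self._next_labeled(self.l_per), u_batch
        else:
            steps = max(1, self.labeled.size // self.l_per)
            for _ in range(steps):
                yield self._next_labeled(self.l_per), np.array([], dtype=int)


# ---------------------------------------------------------------------------
# model plumbing
# ---------------------------------------------------------------------------

def _probs(logits: Tensor, label_mode: str) -> Tensor:
    return logits.softmax() if label_mode == "single" else logits.sigmoid()


def build_model(input_dim: int, n_classes: int, config: TrainConfig,
                seed: int) -> MLPBackbone:
    return MLPBackbone(input_dim, n_classes, hidden=tuple(config.hidden),
                       proj_dim=config.proj_dim, seed=seed)


def _freeze(net: MLPBackbone) -> MLPBackbone:
    for p in net.parameters():
        p.requires_grad = False
    return net


def predict_probs(net: MLPBackbone, X: np.ndarray,
                  label_mode: str = "single") -> np.ndarray:
    x = Tensor(X.reshape(len(X), -1))
    logits, _ = net.forward(x)
    return _probs(logits, label_mode).data


@dataclass
class TrainResult:
    pair: ModelPair
    history: list[dict]
    step_log: list[dict]
    config: TrainConfig
    final_metrics: MetricsReport | None = None


def _check_finite(value: float, epoch: int, step: int) -> None:
    if not np.isfinite(value):
        raise RuntimeError(
            f"non-finite loss at epoch {epoch}, step {step}: {value!r}; "
            "lower the learning rate or check the input data")


def train(dataset: Dataset, split: LabeledSplit, config: TrainConfig) -> TrainResult:
    """Run the full training loop and return networks plus a metrics log.

    Deterministic given ``config.seed`` (independent RNG streams for
    initialization, batch sampling and the two perturbation pipelines).
    The final classifier is the student network; the teacher is returned
    alongside it.
    """
    label_mode = dataset.label_mode
    n_classes = dataset.n_classes
    input_dim = int(np.prod(dataset.image_shape))

    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(4) % (2**31)
    rng_sample = np.random.default_rng(int(seeds[1]))
    rng_s_aug = np.random.default_rng(int(seeds[2]))
    rng_t_aug = np.random.default_rng(int(seeds[3]))

    student = build_model(input_dim, n_classes, config, seed=int(seeds[0]))
    if config.independent_teacher_init:
        teacher = build_model(input_dim, n_classes, config, seed=int(seeds[0]) + 1)
    else:
        teacher = student.clone()
    _freeze(teacher)
    pair = ModelPair(student=student, teacher=teacher, ema_decay=config.ema_decay)

    optimizer = Adam(student.parameters(), lr=config.learning_rate)

    if config.fixed_threshold is not None:
        schedule = ThresholdSchedule.fixed(config.fixed_threshold, n_classes)
    else:
        schedule = ThresholdSchedule(
            class_stats=dataset.class_stats, eps_min=config.eps_min,
            eps_max=config.eps_max, ramp_epochs=config.ramp_epochs,
            clip_hi=config.clip_hi, literal_max=config.literal_max_ramp)

    use_unlabeled = config.use_consistency or config.use_capr
    sampler = TwoStreamSampler(
        split.labeled, split.unlabeled, config.labeled_per_batch,
        config.unlabeled_per_batch, rng_sample, use_unlabeled=use_unlabeled)

    history: list[dict] = []
    step_log: list[dict] = []

    for epoch in range(config.epochs):
        optimizer.lr = config.learning_rate * config.lr_decay**epoch
        lam = rampup_weight(epoch, config.ramp_epochs) if config.use_consistency else 0.0
        beta = config.beta if config.use_sde else 0.0
        capr_on = (config.use_capr and config.zeta > 0
                   and epoch >= config.capr_start and split.unlabeled.size > 0)
        zeta = config.zeta if capr_on else 0.0
        eps_vec = thresholds_at(schedule, epoch)

        epoch_bundles: list[LossBundle] = []
        for step, (lab_idx, unlab_idx) in enumerate(sampler.epoch_batches()):
            n_lab = lab_idx.size
            idx = np.concatenate([lab_idx, unlab_idx])
            y_lab = dataset.Y[lab_idx]

            raw = dataset.X[idx]
            x_student = perturb_batch(raw, config.perturb, rng_s_aug)
            x_teacher = perturb_batch(raw, config.perturb, rng_t_aug)

            logits_s, emb_s = student.forward(
                Tensor(x_student.reshape(len(idx), -1)))
            probs_s = _probs(logits_s, label_mode)
            logits_t, emb_t = teacher.forward(
                Tensor(x_teacher.reshape(len(idx), -1)))
            probs_t = _probs(logits_t, label_mode).data

            loss = _ce_tensor(probs_s[:n_lab], y_lab, label_mode)
            l_sup = float(loss.data)

            l_cs = 0.0
            if lam > 0.0:
                cs = _cs_tensor(probs_s, probs_t)
                l_cs = float(cs.data)
                loss = loss + lam * cs

            l_scl = 0.0
            if beta > 0.0:
                z_s = emb_s[:n_lab]
                z_t = np.asarray(emb_t.data[:n_lab])
                if config.contrastive.normalize_embeddings:
                    z_s = normalize_rows(z_s)
                    z_t = normalize_rows(z_t)
                Z = concatenate([z_s, Tensor(z_t)], axis=0)
                Y2 = np.concatenate([y_lab, y_lab], axis=0)
                scl = scl_loss_tensor(Z, Y2, config.contrastive)
                l_scl = float(scl.data)
                loss = loss + beta * scl

            l_pl = 0.0
            if zeta > 0.0 and unlab_idx.size > 0:
                pl_batch = make_pseudo_labels(probs_t[n_lab:], schedule, epoch)
                pl = pseudo_label_loss_tensor(probs_s[n_lab:], pl_batch, config.focal)
                l_pl = float(pl.data)
                loss = loss + zeta * pl

            bundle = total_loss(l_sup, l_cs, l_scl, l_pl, lam, beta, zeta)
            _check_finite(bundle.total, epoch, step)

            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            ema_update(pair)

            epoch_bundles.append(bundle)
            step_log.append({"epoch": epoch, "step": step, **asdict(bundle)})

        record = {
            "epoch": epoch,
            "lr": optimizer.lr,
            "lambda": lam,
            "capr_active": bool(capr_on),
            "thresholds": eps_vec.tolist(),
            "l_sup": float(np.mean([b.l_sup for b in epoch_bundles])),
            "l_cs": float(np.mean([b.l_cs for b in epoch_bundles])),
            "l_scl": float(np.mean([b.l_scl for b in epoch_bundles])),
            "l_pl": float(np.mean([b.l_pl for b in epoch_bundles])),
            "total": float(np.mean([b.total for b in epoch_bundles])),
        }
        do_eval = (config.eval_every > 0 and (epoch + 1) % config.eval_every == 0)
        if do_eval and len(dataset.X_test):
            rep = _evaluate(pair, dataset, config)
            record["macro_f1"] = rep.macro["f1"]
            record["macro_auc"] = rep.macro["auc"]
        history.append(record)

    final = _evaluate(pair, dataset, config) if len(dataset.X_test) else None
    return TrainResult(pair=pair, history=history, step_log=step_log,
                       config=config, final_metrics=final)


def _evaluate(pair: ModelPair, dataset: Dataset, config: TrainConfig) -> MetricsReport:
    net = pair.student if config.eval_model == "student" else pair.teacher
    scores = predict_probs(net, dataset.X_test, dataset.label_mode)
    return compute_metrics(scores, dataset.Y_test, dataset.label_mode)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(result: TrainResult, path: str) -> None:
    """Parameter snapshot (student + teacher) with config and epoch count."""
    import yaml

    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    arrays = {}
    for tag, net in (("student", result.pair.student), ("teacher", result.pair.teacher)):
        for i, w in enumerate(net.get_weights()):
            arrays[f"{tag}_{i}"] = w
    np.savez(path, **arrays)
    meta = {"epochs_run": len(result.history), "config": _config_dict(result.config)}
    with open(path + ".yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def _config_dict(config: TrainConfig) -> dict:
    d = asdict(config)
    d["hidden"] = list(config.hidden)
    return d


def load_checkpoint(path: str, input_dim: int, n_classes: int) -> ModelPair:
    import yaml

    with open(path + ".yaml") as fh:
        meta = yaml.safe_load(fh)
    cfg_d = meta["config"]
    cfg_d["hidden"] = tuple(cfg_d["hidden"])
    for key, cls in (("focal", FocalConfig), ("contrastive", ContrastiveConfig),
                     ("perturb", PerturbProfile)):
        cfg_d[key] = cls(**cfg_d[key])
    config = TrainConfig(**cfg_d)
    data = np.load(path if path.endswith(".npz") else path + ".npz")
    student = build_model(input_dim, n_classes, config, seed=0)
    teacher = build_model(input_dim, n_classes, config, seed=0)
    for tag, net in (("student", student), ("teacher", teacher)):
        n = len(net.get_weights())
        net.set_weights([data[f"{tag}_{i}"] for i in range(n)])
    _freeze(teacher)
    return ModelPair(student=student, teacher=teacher, ema_decay=config.ema_decay)
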