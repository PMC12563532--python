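"""Small neural-network building blocks on the autodiff engine.

The default backbone is a fully-connected encoder over flattened pixels with
two heads: a linear classifier producing logits and a linear projection
producing the embedding used by the contrastive loss. Any object exposing
``forward(x) -> (logits, embedding)`` and ``parameters()`` can stand in as a
backbone for the trainer.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Linear", "MLPBackbone", "Adam", "ema_update", "copy_params"]


class Linear:
    """Dense layer ``x W + b`` with He-normal initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class MLPBackbone:
    """Fully-connected encoder with classifier and projection heads.

    Images are flattened; hidden layers use ReLU. The projection head taps
    the penultimate activation (the last hidden layer), which is where the
    contrastive loss sees the network.
    """

    def __init__(
        self,
        input_dim: int,
        n_classes: int,
        hidden: tuple[int, ...] = (256, 128),
        proj_dim: int = 64,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.input_dim = input_dim
        self.n_classes = n_classes
        self.hidden = tuple(hidden)
        self.proj_dim = proj_dim
        dims = [input_dim, *hidden]
        self.encoder = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.classifier = Linear(dims[-1], n_classes, rng)
        self.projector = Linear(dims[-1], proj_dim, rng)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = x
        if h.ndim > 2:
            h = h.reshape(h.shape[0], -1)
        for layer in self.encoder:
            h = layer(h).relu()
        return self.classifier(h), self.projector(h)

    __call__ = forward

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for layer in [*self.encoder, self.classifier, self.projector]:
            params.extend(layer.parameters())
        return params

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(params, weights):
            if p.data.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.data[...] = w

    def clone(self) -> "MLPBackbone":
        other = MLPBackbone(
            self.input_dim, self.n_classes, self.hidden, self.proj_dim
        )
        other.set_weights(self.get_weights())
        return other


class Adam:
    """Adam optimizer with a settable learning rate (for per-epoch decay)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def copy_params(src, dst) -> None:
    """Copy parameter values from one network into a shape-congruent other."""
    dst.set_weights(src.get_weights())


def ema_update(student, teacher, decay: float) -> None:
    """Teacher <- decay * teacher + (1 - decay) * student, parameterwise."""
    if not 0.0 <= decay <= 1.0:
        raise ValueError("EMA decay must lie in [0, 1]")
    s_params, t_params = student.parameters(), teacher.parameters()
    if len(s_params) != len(t_params):
        raise ValueError("student/teacher parameter count mismatch")
    for s, t in zip(s_params, t_params):
        if s.data.shape != t.data.shape:
            raise ValueError("student/teacher parameter shape mismatch")
        t.data *= decay
        t.data += (1.0 - decay) * s.data
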