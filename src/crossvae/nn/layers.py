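"""Fully connected building blocks and the Adam optimiser."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Linear", "LayerNorm", "BatchNorm", "MLP", "GaussianHead", "Adam"]


class Linear:
    """Affine layer with He-style initialisation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class LayerNorm:
    """Per-sample feature normalisation with trainable gain and bias."""

    def __init__(self, n_features: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n_features), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta

    @property
    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]


class BatchNorm:
    """Per-feature minibatch normalisation with running statistics.

    In training mode features are normalised with minibatch mean/variance
    (gradients flow through the statistics); running averages are kept for
    evaluation mode. Minibatch statistics pool cells from all systems in
    the batch, which stabilises optimisation against per-system activation
    drift.
    """

    def __init__(self, n_features: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(n_features), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features), requires_grad=True)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.eps = eps
        self.momentum = momentum
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=0, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            return centered / (var + self.eps).sqrt() * self.gamma + self.beta
        xhat = (x - Tensor(self.running_mean)) * Tensor(
            1.0 / np.sqrt(self.running_var + self.eps)
        )
        return xhat * self.gamma + self.beta

    @property
    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]


class MLP:
    """Stack of Linear(+BatchNorm)+ReLU blocks and a linear output layer."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        n_hidden: int,
        n_layers: int,
        rng: np.random.Generator,
        batch_norm: bool = False,
    ):
        dims = [n_in] + [n_hidden] * n_layers
        self.hidden = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.norms = [BatchNorm(b) if batch_norm else None for b in dims[1:]]
        self.out = Linear(dims[-1], n_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        for layer, norm in zip(self.hidden, self.norms):
            x = layer(x)
            if norm is not None:
                x = norm(x)
            x = x.relu()
        return self.out(x)

    @property
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for layer, norm in zip(self.hidden, self.norms):
            params.extend(layer.parameters)
            if norm is not None:
                params.extend(norm.parameters)
        params.extend(self.out.parameters)
        return params


class GaussianHead:
    """MLP trunk with separate mean and log-variance output heads.

    The log-variance is clipped to a wide fixed range so early training
    cannot produce degenerate densities.
    """

    LOGVAR_RANGE = (-10.0, 10.0)

    def __init__(
        self,
        n_in: int,
        n_out: int,
        n_hidden: int,
        n_layers: int,
        rng: np.random.Generator,
        batch_norm: bool = False,
    ):
        dims = [n_in] + [n_hidden] * n_layers
        self.hidden = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.norms = [BatchNorm(b) if batch_norm else None for b in dims[1:]]
        self.mu = Linear(dims[-1], n_out, rng)
        self.logvar = Linear(dims[-1], n_out, rng)

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        for layer, norm in zip(self.hidden, self.norms):
            x = layer(x)
            if norm is not None:
                x = norm(x)
            x = x.relu()
        return self.mu(x), self.logvar(x).clip(*self.LOGVAR_RANGE)

    @property
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for layer, norm in zip(self.hidden, self.norms):
            params.extend(layer.parameters)
            if norm is not None:
                params.extend(norm.parameters)
        params.extend(self.mu.parameters)
        params.extend(self.logvar.parameters)
        return params


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
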