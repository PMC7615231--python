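"""Minimal neural-network building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor

__all__ = ["Module", "Linear", "BatchNorm1d", "AdamW"]


class Module:
    """Parameter container with pytorch-like traversal semantics."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                params.append(p)
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out.append((full, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(prefix=full + "."))
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Parameter):
                        out.append((f"{full}.{i}", v))
                    elif isinstance(v, Module):
                        out.extend(v.named_parameters(prefix=f"{full}.{i}."))
            elif isinstance(value, dict):
                for k, v in value.items():
                    if isinstance(v, Parameter):
                        out.append((f"{full}.{k}", v))
                    elif isinstance(v, Module):
                        out.extend(v.named_parameters(prefix=f"{full}.{k}."))
        return out

    def modules(self) -> list["Module"]:
        mods = [self]
        for value in vars(self).values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        mods.extend(v.modules())
            elif isinstance(value, dict):
                for v in value.values():
                    if isinstance(v, Module):
                        mods.extend(v.modules())
        return mods

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm1d):
                state[f"__bn{i}.running_mean"] = m.running_mean.copy()
                state[f"__bn{i}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data[...] = state[name]
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm1d):
                m.running_mean[...] = state[f"__bn{i}.running_mean"]
                m.running_var[...] = state[f"__bn{i}.running_var"]

    training: bool = True


class Linear(Module):
    """Affine map ``x @ W + b`` with Glorot-uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        bound = np.sqrt(6.0 / (n_in + n_out))
        self.W = Parameter(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class BatchNorm1d(Module):
    """Per-feature batch normalization over the leading (batch) axis.

    Training mode normalizes by batch statistics and updates running
    statistics; evaluation mode uses the frozen running statistics, so
    single-sequence inference is deterministic.
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(n_features))
        self.beta = Parameter(np.zeros(n_features))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training and x.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered**2).mean(axis=0, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            n = x.shape[0]
            unbiased = var.data.ravel() * n / max(n - 1, 1)
            self.running_var = (1 - m) * self.running_var + m * unbiased
            xhat = centered * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - self.running_mean) * Tensor((self.running_var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class AdamW(Module):
    """Adam with decoupled weight decay and an optional stepwise lr schedule."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-2,
    ):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g**2
            mhat = m / (1 - b1**self._t)
            vhat = v / (1 - b2**self._t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
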