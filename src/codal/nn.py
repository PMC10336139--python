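"""Neural-network layers and optimizers on top of the autodiff core.

Layers follow the conventions of the widely used deep-learning toolkits:
``BatchNorm1d`` keeps exponential running statistics for evaluation mode,
``Dropout`` uses inverted scaling by 1/(1-p), and ``AdamW`` applies
decoupled weight decay.
"""
from __future__ import annotations

import numpy as np

from ._autodiff import Tensor

__all__ = ["Module", "Parameter", "Linear", "BatchNorm1d", "Dropout",
           "Adam", "AdamW"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: recursive parameter discovery and train/eval switching."""

    def __init__(self):
        self.training = True

    def parameters(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Parameter):
                        out.append(item)
                    elif isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def modules(self):
        out = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict:
        state = {}

        def walk(mod, prefix):
            for k, v in mod.__dict__.items():
                key = f"{prefix}{k}"
                if isinstance(v, Parameter):
                    state[key] = v.data.copy()
                elif isinstance(v, np.ndarray):
                    state[key] = v.copy()
                elif isinstance(v, Module):
                    walk(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")
                        elif isinstance(item, Parameter):
                            state[f"{key}.{i}"] = item.data.copy()

        walk(self, "")
        return state

    def load_state_dict(self, state: dict):
        def walk(mod, prefix):
            for k, v in mod.__dict__.items():
                key = f"{prefix}{k}"
                if isinstance(v, Parameter):
                    v.data = state[key].copy()
                elif isinstance(v, np.ndarray) and key in state:
                    setattr(mod, k, state[key].copy())
                elif isinstance(v, Module):
                    walk(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")
                        elif isinstance(item, Parameter):
                            item.data = state[f"{key}.{i}"].copy()

        walk(self, "")


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        # Kaiming-style fan-in scaling
        scale = np.sqrt(2.0 / n_in)
        self.weight = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm1d(Module):
    """Per-feature standardization with affine rescale.

    Training mode uses minibatch statistics and updates exponential running
    averages (momentum 0.1); evaluation mode uses the running statistics.
    """

    def __init__(self, n_features: int, momentum: float = 0.1,
                 eps: float = 1e-5, affine: bool = True):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.affine = affine
        if affine:
            self.gamma = Parameter(np.ones(n_features))
            self.beta = Parameter(np.zeros(n_features))
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.n_updates = 0

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            m = x.shape[0]
            unbiased = var.data[0] * (m / max(m - 1, 1))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data[0])
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased)
            self.n_updates += 1
            xhat = (x - mu) / (var + self.eps).sqrt()
        else:
            if self.n_updates == 0:
                raise RuntimeError(
                    "BatchNorm1d used in eval mode before any training "
                    "update initialized its running statistics")
            xhat = ((x - Tensor(self.running_mean))
                    / Tensor(np.sqrt(self.running_var + self.eps)))
        if self.affine:
            xhat = xhat * self.gamma + self.beta
        return xhat


class Dropout(Module):
    def __init__(self, p: float):
        super().__init__()
        self.p = float(p)

    def __call__(self, x: Tensor, rng: np.random.Generator) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Adam:
    """Adam optimizer; ``weight_decay`` > 0 gives decoupled AdamW behavior."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.betas = list(betas)
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            if self.weight_decay:
                p.data = p.data * (1 - self.lr * self.weight_decay)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def clip_grad_norm(self, max_norm: float) -> float:
        total = np.sqrt(sum(float((p.grad**2).sum())
                            for p in self.params if p.grad is not None))
        if total > max_norm:
            scale = max_norm / (total + 1e-12)
            for p in self.params:
                if p.grad is not None:
                    p.grad = p.grad * scale
        return total


class AdamW(Adam):
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        super().__init__(params, lr=lr, betas=betas, eps=eps,
                         weight_decay=weight_decay)
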