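"""Neural building blocks: linear layers, highway gates, Adam."""

from __future__ import annotations

import numpy as np

from .._autodiff import Tensor

__all__ = ["Module", "Linear", "Highway", "HighwayStack", "MLP", "Adam",
           "bce_loss"]

_EPS = 1e-12


class Module:
    """Base class holding named parameters (possibly nested)."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"parameter count mismatch: have {len(params)}, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias_init: float = 0.0):
        self.W = Tensor(_glorot(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.full(d_out, bias_init, dtype=float), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Highway(Module):
    """Gated residual layer y = T(x) * H(x) + (1 - T(x)) * x.

    T is a sigmoid gate, H a tanh transform; the carry path mitigates
    vanishing gradients in the stacked aggregation nodes.  The gate bias
    starts negative so early training favours the carry path.
    """

    def __init__(self, d: int, rng: np.random.Generator):
        self.transform = Linear(d, d, rng)
        self.gate = Linear(d, d, rng, bias_init=-1.0)

    def __call__(self, x: Tensor) -> Tensor:
        t = self.gate(x).sigmoid()
        h = self.transform(x).tanh()
        return t * h + (1.0 - t) * x


class HighwayStack(Module):
    def __init__(self, d: int, depth: int, rng: np.random.Generator):
        self.layers = [Highway(d, rng) for _ in range(depth)]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class MLP(Module):
    """Fully connected stack with ReLU hidden activations."""

    def __init__(self, dims: list[int], rng: np.random.Generator,
                 out_sigmoid: bool = False):
        self.layers = [Linear(dims[i], dims[i + 1], rng)
                       for i in range(len(dims) - 1)]
        self.out_sigmoid = out_sigmoid

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        if self.out_sigmoid:
            x = x.sigmoid()
        return x


def bce_loss(prob: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy; probabilities clamped away from {0,1}."""
    t = np.asarray(target, dtype=float)
    p = prob * (1 - 2 * _EPS) + _EPS
    loss = -(Tensor(t) * p.log() + Tensor(1.0 - t) * (1.0 - p).log())
    return loss.mean()


class Adam:
    """Adaptive-moment first-order optimizer."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

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
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
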