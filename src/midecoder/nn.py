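"""Minimal module/layer/optimiser layer on top of :mod:`midecoder.autodiff`.

Mirrors the familiar Module idiom: layers own :class:`Parameter` leaves,
``parameters()`` walks the tree, ``train()``/``eval()`` toggle dropout and
batch-norm behaviour, and ``state_dict``/``load_state_dict`` give cheap
checkpointing for early-stopping weight restores.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import DTYPE, Tensor


class Parameter(Tensor):
    """A trainable tensor leaf."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Base class: parameter discovery, mode switching, state dicts."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- tree walks ---------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=key + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{i}", item

    def parameters(self):
        seen: set[int] = set()
        out = []
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        return out

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    # -- modes --------------------------------------------------------------
    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- persistence ---------------------------------------------------------
    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                state[f"{name}.running_mean"] = m.running_mean.copy()
                state[f"{name}.running_var"] = m.running_var.copy()
        return state

    def _named_modules(self, prefix: str = ""):
        yield prefix.rstrip("."), self
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield from value._named_modules(prefix=f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._named_modules(prefix=f"{prefix}{name}.{i}.")

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = np.asarray(state[name], dtype=DTYPE).copy()
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(state[f"{name}.running_mean"], dtype=DTYPE).copy()
                m.running_var = np.asarray(state[f"{name}.running_var"], dtype=DTYPE).copy()

    def count_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


# ---------------------------------------------------------------------------
# initialisers
# ---------------------------------------------------------------------------

def uniform_fan_in(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


def orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    """Orthogonal n x n matrix from the QR decomposition of a Gaussian draw."""
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))  # fix sign ambiguity for determinism across BLAS
    return q.astype(DTYPE)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv2d(Module):
    """Grouped stride-1 2-D convolution without bias (bias is redundant in
    front of the affine batch-norm that always follows it here)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: tuple,
                 padding=((0, 0), (0, 0)), groups: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        kh, kw = kernel_size
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must divide groups")
        rng = rng or np.random.default_rng(0)
        fan_in = (in_channels // groups) * kh * kw
        self.weight = Parameter(uniform_fan_in(rng, (out_channels, in_channels // groups, kh, kw), fan_in))
        self.padding = padding
        self.groups = groups

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, padding=self.padding, groups=self.groups)


def same_padding(k: int) -> tuple[int, int]:
    """Length-preserving zero padding for a stride-1 kernel of width k.
    Even kernels pad one more sample on the left."""
    return (k - (k + 1) // 2, (k + 1) // 2 - 1) if k % 2 == 0 else (k // 2, k // 2)


class BatchNorm2d(Module):
    """Per-channel batch normalisation over [B, C, H, W] with running stats."""

    def __init__(self, num_features: int, eps: float = 1e-3, momentum: float = 0.01):
        super().__init__()
        self.gamma = Parameter(np.ones((1, num_features, 1, 1)))
        self.beta = Parameter(np.zeros((1, num_features, 1, 1)))
        self.running_mean = np.zeros((1, num_features, 1, 1), dtype=DTYPE)
        self.running_var = np.ones((1, num_features, 1, 1), dtype=DTYPE)
        self.eps = float(eps)
        self.momentum = float(momentum)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            axes = (0, 2, 3)
            mean = x.data.mean(axis=axes, keepdims=True)
            var = x.data.var(axis=axes, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
            return ad.batchnorm(x, self.gamma, self.beta, mean, var, self.eps, axes)
        return ad.batchnorm_eval(x, self.gamma, self.beta,
                                 self.running_mean, self.running_var, self.eps)


class ELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ad.elu(x)


class MaxPoolW(Module):
    def __init__(self, k: int = 3):
        super().__init__()
        self.k = k

    def forward(self, x: Tensor) -> Tensor:
        return ad.maxpool_w(x, self.k)


class AvgPoolW(Module):
    def __init__(self, k: int = 3):
        super().__init__()
        self.k = k

    def forward(self, x: Tensor) -> Tensor:
        return ad.avgpool_w(x, self.k)


class Dropout(Module):
    """Inverted dropout; inactive in eval mode.  The mask generator is shared
    across the whole model (assigned by the owner) so one seed fixes a run."""

    def __init__(self, p: float):
        super().__init__()
        self.p = float(p)
        self.rng: np.random.Generator | None = None

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        if self.rng is None:
            self.rng = np.random.default_rng(0)
        return ad.dropout(x, self.p, self.rng)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(uniform_fan_in(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the standard decay constants (beta1 0.9, beta2 0.999)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
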