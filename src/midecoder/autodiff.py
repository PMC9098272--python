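"""A small reverse-mode automatic-differentiation engine on numpy arrays.

The network in this package needs a fixed, modest vocabulary of differentiable
operations: grouped 2-D convolution (stride 1), batch normalisation, ELU /
sigmoid / tanh, width-wise max/mean pooling, dropout, dense products, a 1-D
"same" convolution along a feature axis, softmax and cross-entropy.  Rather
than depend on a large framework, this module implements exactly that
vocabulary as a tape: every op returns a :class:`Tensor` holding the forward
value and a closure that accumulates gradients into its parents.

All arithmetic is float32.  Backward passes are exercised against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Tensor:
    """An ndarray plus the bookkeeping needed for reverse-mode differentiation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(_as_tensor(other)))

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __getitem__(self, key):
        return take(self, key)

    # -- backprop ----------------------------------------------------------
    def backward(self, grad=None) -> None:
        """Backpropagate from this node.  Scalar outputs default to grad 1."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative topological sort (graphs can be deep through time)
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and (p.requires_grad or p._parents):
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_grad(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if not (t.requires_grad or t._parents):
        return
    g = g.astype(DTYPE, copy=False)
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a broadcast gradient back down to the original operand shape."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, (gs, s) in enumerate(zip(g.shape, shape)):
        if s == 1 and gs != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference only)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _make(data, parents, backward) -> Tensor:
    if _GRAD_ENABLED and _needs_grad(*parents):
        return Tensor(data, parents=parents, backward=backward)
    return Tensor(data)


# ---------------------------------------------------------------------------
# elementwise / linear algebra
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.shape))
        _accumulate(b, _unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g * b.data, a.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def neg(a: Tensor) -> Tensor:
    def backward(g):
        _accumulate(a, -g)

    return _make(-a.data, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product; `a` may have leading batch dims, `b` must be 2-D."""
    out_data = a.data @ b.data

    def backward(g):
        _accumulate(a, g @ b.data.T)
        ga = a.data.reshape(-1, a.shape[-1])
        gg = g.reshape(-1, g.shape[-1])
        _accumulate(b, ga.T @ gg)

    return _make(out_data, (a, b), backward)


def reshape(a: Tensor, shape) -> Tensor:
    orig = a.shape

    def backward(g):
        _accumulate(a, g.reshape(orig))

    return _make(a.data.reshape(shape), (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    inverse = np.argsort(axes)

    def backward(g):
        _accumulate(a, g.transpose(inverse))

    return _make(a.data.transpose(axes), (a,), backward)


def take(a: Tensor, key) -> Tensor:
    """Basic (slice/index) subscripting with scatter-add backward."""

    def backward(g):
        full = np.zeros(a.shape, dtype=DTYPE)
        np.add.at(full, key, g)
        _accumulate(a, full)

    return _make(a.data[key], (a,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accumulate(t, g[tuple(sl)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            _accumulate(a, np.broadcast_to(g, a.shape).astype(DTYPE))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accumulate(a, np.broadcast_to(g, a.shape).astype(DTYPE))

    return _make(out_data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    axes = tuple(range(a.ndim)) if axis is None else (
        (axis,) if isinstance(axis, int) else tuple(axis))
    count = int(np.prod([a.shape[ax] for ax in axes]))
    s = tsum(a, axis=axis, keepdims=keepdims)
    return mul(s, Tensor(np.asarray(1.0 / count, dtype=DTYPE)))


# ---------------------------------------------------------------------------
# nonlinearities
# ---------------------------------------------------------------------------

def sigmoid(a: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-a.data.astype(np.float64)))
    y = y.astype(DTYPE)

    def backward(g):
        _accumulate(a, g * y * (1.0 - y))

    return _make(y, (a,), backward)


def tanh(a: Tensor) -> Tensor:
    y = np.tanh(a.data)

    def backward(g):
        _accumulate(a, g * (1.0 - y * y))

    return _make(y, (a,), backward)


def elu(a: Tensor) -> Tensor:
    pos = a.data > 0
    y = np.where(pos, a.data, np.expm1(a.data))

    def backward(g):
        _accumulate(a, g * np.where(pos, 1.0, y + 1.0).astype(DTYPE))

    return _make(y, (a,), backward)


def tlog(a: Tensor) -> Tensor:
    def backward(g):
        _accumulate(a, g / a.data)

    return _make(np.log(a.data), (a,), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        _accumulate(a, y * (g - dot))

    return _make(y, (a,), backward)


# ---------------------------------------------------------------------------
# convolution / pooling / normalisation
# ---------------------------------------------------------------------------

def _windows(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Sliding windows over the trailing two axes -> [..., Ho, Wo, kh, kw]."""
    return np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(-2, -1))


def _conv_rows_gemm(x: Tensor, w: Tensor, pl: int, pr: int) -> Tensor:
    """Fast path for kh == 1, groups == 1: row-wise 1-D correlation along the
    last axis as a single GEMM (this covers the wide temporal convolution and
    all pointwise (1,1) convolutions, which dominate the runtime)."""
    B, Cin, H, W = x.shape
    Cout, _, _, kw = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (0, 0), (pl, pr)))
    win = np.lib.stride_tricks.sliding_window_view(xp, kw, axis=3)  # [B,Cin,H,Wo,kw]
    Wo = win.shape[3]
    x2 = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4)).reshape(-1, Cin * kw)
    w2 = w.data.reshape(Cout, Cin * kw).T
    out_data = (x2 @ w2).reshape(B, H, Wo, Cout).transpose(0, 3, 1, 2)

    def backward(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, Cout)
        if w.requires_grad or w._parents:
            _accumulate(w, (x2.T @ g2).T.reshape(Cout, Cin, 1, kw))
        if x.requires_grad or x._parents:
            gp = np.pad(g, ((0, 0), (0, 0), (0, 0), (kw - 1, kw - 1)))
            gwin = np.lib.stride_tricks.sliding_window_view(gp, kw, axis=3)
            g3 = np.ascontiguousarray(gwin.transpose(0, 2, 3, 1, 4)).reshape(-1, Cout * kw)
            # flipped-kernel matrix: rows (o, k) -> column i, entry w[o, i, kw-1-k]
            wf = w.data[:, :, 0, ::-1].transpose(0, 2, 1).reshape(Cout * kw, Cin)
            dxp = (g3 @ wf).reshape(B, H, W + pl + pr, Cin).transpose(0, 3, 1, 2)
            _accumulate(x, dxp[:, :, :, pl:pl + W])

    return _make(np.ascontiguousarray(out_data), (x, w), backward)


def _conv_full_height(x: Tensor, w: Tensor, groups: int) -> Tensor:
    """Fast path for the spatial filter: kw == 1, kernel spanning the whole
    height (valid convolution collapsing the electrode axis to extent 1)."""
    B, Cin, H, W = x.shape
    Cout, Cg, kh, _ = w.shape
    G = groups
    xg = x.data.reshape(B, G, Cg, H, W)
    wg = w.data.reshape(G, Cout // G, Cg, kh)
    out = np.einsum("bgihw,goih->bgow", xg, wg, optimize=True)
    out_data = out.reshape(B, Cout, 1, W)

    def backward(g):
        gg = g.reshape(B, G, Cout // G, W)
        if w.requires_grad or w._parents:
            dw = np.einsum("bgihw,bgow->goih", xg, gg, optimize=True)
            _accumulate(w, dw.reshape(Cout, Cg, kh, 1))
        if x.requires_grad or x._parents:
            dx = np.einsum("bgow,goih->bgihw", gg, wg, optimize=True)
            _accumulate(x, dx.reshape(B, Cin, H, W))

    return _make(out_data, (x, w), backward)


def _conv_depthwise_rows(x: Tensor, w: Tensor, pl: int, pr: int) -> Tensor:
    """Fast path for depthwise temporal convolution: kh == 1 and one kernel
    per channel (groups == Cin == Cout)."""
    B, C, H, W = x.shape
    kw = w.shape[3]
    xp = np.pad(x.data, ((0, 0), (0, 0), (0, 0), (pl, pr)))
    win = np.lib.stride_tricks.sliding_window_view(xp, kw, axis=3)  # [B,C,H,Wo,kw]
    wk = w.data.reshape(C, kw)
    out_data = np.einsum("bchwk,ck->bchw", win, wk, optimize=True)

    def backward(g):
        if w.requires_grad or w._parents:
            dw = np.einsum("bchwk,bchw->ck", win, g, optimize=True)
            _accumulate(w, dw.reshape(C, 1, 1, kw))
        if x.requires_grad or x._parents:
            gp = np.pad(g, ((0, 0), (0, 0), (0, 0), (kw - 1, kw - 1)))
            gwin = np.lib.stride_tricks.sliding_window_view(gp, kw, axis=3)
            dxp = np.einsum("bchwk,ck->bchw", gwin, wk[:, ::-1], optimize=True)
            _accumulate(x, dxp[:, :, :, pl:pl + W])

    return _make(out_data, (x, w), backward)


def conv2d(x: Tensor, w: Tensor, padding=((0, 0), (0, 0)), groups: int = 1) -> Tensor:
    """Grouped stride-1 cross-correlation.

    x: [B, Cin, H, W]; w: [Cout, Cin // groups, kh, kw];
    padding: ((top, bottom), (left, right)).
    """
    (pt, pb), (pl, pr) = padding
    if pt == 0 and pb == 0 and w.shape[2] == 1:
        if groups == 1:
            return _conv_rows_gemm(x, w, pl, pr)
        if groups == x.shape[1] == w.shape[0]:
            return _conv_depthwise_rows(x, w, pl, pr)
    if (pt, pb, pl, pr) == (0, 0, 0, 0) and w.shape[3] == 1 and w.shape[2] == x.shape[2]:
        return _conv_full_height(x, w, groups)
    B, Cin, H, W = x.shape
    Cout, Cg, kh, kw = w.shape
    G = groups
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    win = _windows(xp, kh, kw)                       # [B, Cin, Ho, Wo, kh, kw]
    Ho, Wo = win.shape[2], win.shape[3]
    win_g = win.reshape(B, G, Cg, Ho, Wo, kh, kw)
    w_g = w.data.reshape(G, Cout // G, Cg, kh, kw)
    out = np.einsum("bgihwkl,goikl->bgohw", win_g, w_g, optimize=True)
    out_data = out.reshape(B, Cout, Ho, Wo).astype(DTYPE)

    def backward(g):
        g_g = g.reshape(B, G, Cout // G, Ho, Wo)
        if w.requires_grad or w._parents:
            dw = np.einsum("bgihwkl,bgohw->goikl", win_g, g_g, optimize=True)
            _accumulate(w, dw.reshape(Cout, Cg, kh, kw))
        if x.requires_grad or x._parents:
            gp = np.pad(g_g, ((0, 0), (0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
            gwin = _windows(gp, kh, kw)              # [B, G, Cout/G, Hp, Wp, kh, kw]
            wf = w_g[:, :, :, ::-1, ::-1]
            dxp = np.einsum("bgohwkl,goikl->bgihw", gwin, wf, optimize=True)
            dxp = dxp.reshape(B, Cin, H + pt + pb, W + pl + pr)
            _accumulate(x, dxp[:, :, pt:pt + H, pl:pl + W])

    return _make(out_data, (x, w), backward)


def conv1d_feature(x: Tensor, kernel: Tensor) -> Tensor:
    """Length-preserving 1-D correlation of each row of x [B, n] with an
    odd-width kernel [K] (symmetric zero padding along the feature axis)."""
    K = kernel.shape[0]
    p = K // 2
    B, n = x.shape
    xp = np.pad(x.data, ((0, 0), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)  # [B, n, K]
    out_data = (win @ kernel.data).astype(DTYPE)

    def backward(g):
        if kernel.requires_grad or kernel._parents:
            _accumulate(kernel, np.einsum("bnk,bn->k", win, g, optimize=True))
        if x.requires_grad or x._parents:
            gp = np.pad(g, ((0, 0), (p, p)))
            gwin = np.lib.stride_tricks.sliding_window_view(gp, K, axis=1)
            _accumulate(x, gwin @ kernel.data[::-1])

    return _make(out_data, (x, kernel), backward)


def maxpool_w(x: Tensor, k: int = 3) -> Tensor:
    """Max pooling of width k, stride k, along the last axis (trailing
    remainder samples are dropped, i.e. floor division of the length)."""
    *lead, W = x.shape
    Wo = W // k
    xr = x.data[..., : Wo * k].reshape(*lead, Wo, k)
    idx = xr.argmax(axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        full = np.zeros((*lead, Wo, k), dtype=DTYPE)
        np.put_along_axis(full, idx[..., None], g[..., None], axis=-1)
        dx = np.zeros(x.shape, dtype=DTYPE)
        dx[..., : Wo * k] = full.reshape(*lead, Wo * k)
        _accumulate(x, dx)

    return _make(out_data, (x,), backward)


def avgpool_w(x: Tensor, k: int = 3) -> Tensor:
    """Mean pooling of width k, stride k, along the last axis."""
    *lead, W = x.shape
    Wo = W // k
    xr = x.data[..., : Wo * k].reshape(*lead, Wo, k)
    out_data = xr.mean(axis=-1)

    def backward(g):
        dx = np.zeros(x.shape, dtype=DTYPE)
        dx[..., : Wo * k] = np.repeat(g / k, k, axis=-1)
        _accumulate(x, dx)

    return _make(out_data, (x,), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only in training mode."""
    if p <= 0.0:
        return x
    keep = (rng.random(x.shape) >= p).astype(DTYPE) / (1.0 - p)

    def backward(g):
        _accumulate(x, g * keep)

    return _make(x.data * keep, (x,), backward)


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, mean: np.ndarray,
              var: np.ndarray, eps: float, axes: tuple) -> Tensor:
    """Normalise x with the given per-channel mean/var (broadcastable to x),
    then apply the affine pair.  `axes` are the reduction axes used when the
    statistics came from the batch (needed for the training backward)."""
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv
    out_data = (gamma.data * xhat + beta.data).astype(DTYPE)

    def backward(g):
        _accumulate(gamma, _unbroadcast(g * xhat, gamma.shape))
        _accumulate(beta, _unbroadcast(g, beta.shape))
        if x.requires_grad or x._parents:
            gmean = g.mean(axis=axes, keepdims=True)
            gxhat = (g * xhat).mean(axis=axes, keepdims=True)
            _accumulate(x, (gamma.data * inv) * (g - gmean - xhat * gxhat))

    return _make(out_data, (x, gamma, beta), backward)


def batchnorm_eval(x: Tensor, gamma: Tensor, beta: Tensor, mean: np.ndarray,
                   var: np.ndarray, eps: float) -> Tensor:
    """Batch-norm with frozen statistics (evaluation mode)."""
    inv = (1.0 / np.sqrt(var + eps)).astype(DTYPE)
    xhat = (x.data - mean) * inv
    out_data = (gamma.data * xhat + beta.data).astype(DTYPE)

    def backward(g):
        _accumulate(gamma, _unbroadcast(g * xhat, gamma.shape))
        _accumulate(beta, _unbroadcast(g, beta.shape))
        _accumulate(x, g * (gamma.data * inv))

    return _make(out_data, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over rows of `logits` [N, K]."""
    labels = np.asarray(labels)
    z = logits.data.astype(np.float64)
    z = z - z.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = logits.shape[0]
    loss = -logp[np.arange(n), labels].mean()
    probs = np.exp(logp)

    def backward(g):
        d = probs.copy()
        d[np.arange(n), labels] -= 1.0
        _accumulate(logits, (g * d / n).astype(DTYPE))

    return _make(np.asarray(loss, dtype=DTYPE), (logits,), backward)


def nll_of_mean_probs(probs: Tensor, labels: np.ndarray, eps: float = 1e-12) -> Tensor:
    """Mean negative log of probs[i, labels[i]]; used by the averaged-probability
    loss mode where window softmax outputs are averaged per trial first."""
    labels = np.asarray(labels)
    n = probs.shape[0]
    picked = probs.data[np.arange(n), labels]

    def backward(g):
        d = np.zeros(probs.shape, dtype=DTYPE)
        d[np.arange(n), labels] = -g / (np.maximum(picked, eps) * n)
        _accumulate(probs, d)

    loss = -np.log(np.maximum(picked, eps)).mean()
    return _make(np.asarray(loss, dtype=DTYPE), (probs,), backward)
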