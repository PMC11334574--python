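"""Minimal reverse-mode autodiff and neural-network layers on NumPy.

The package's networks are small enough that a compact tape-based autodiff
over ``numpy.ndarray`` is sufficient: every operation records its parents and
a closure that accumulates gradients, and :meth:`Tensor.backward` walks the
tape in reverse topological order.  All layers used by the counting network
live here: 2-D convolution (stride 1, zero padding, via im2col), 2x2 max
pooling, linear layers, layer normalisation, dropout, and the pointwise
nonlinearities.  Gradients of every op are verified against central finite
differences in the test suite.

Arrays are float32 by default; shapes follow the (N, C, H, W) image and
(N, tokens, dim) token conventions.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "no_grad",
    "Module",
    "Linear",
    "Conv2d",
    "MaxPool2x2",
    "LayerNorm",
    "Dropout",
    "relu",
    "sigmoid",
    "concat",
    "global_avg_pool",
    "global_max_pool",
    "channel_avg_pool",
    "channel_max_pool",
    "SGD",
    "MultiStepLR",
]

DTYPE = np.float32

_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables tape construction (saves memory in eval)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "retains_grad")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (), backward: Callable | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        if not _GRAD_ENABLED:
            parents, backward, requires_grad = (), None, False
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None
        self.retains_grad = False

    # -- bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def retain_grad(self) -> "Tensor":
        """Keep the gradient on this (possibly non-leaf) tensor after backward."""
        self.retains_grad = True
        return self

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar")
            grad = np.ones_like(self.data)
        # reverse topological order over the tape
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): _as_array(grad)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None or not node._parents:
                node.grad = g if node.grad is None else node.grad + g
                continue
            if node.retains_grad:
                node.grad = g if node.grad is None else node.grad + g
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg

    # -- arithmetic --------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other),
                     backward=lambda g: (_unbroadcast(g, self.shape),
                                         _unbroadcast(g, other.shape)))
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward=lambda g: (-g,))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return Tensor(self.data - other.data, parents=(self, other),
                      backward=lambda g: (_unbroadcast(g, self.shape),
                                          _unbroadcast(-g, other.shape)))

    def __rsub__(self, other):
        return Tensor(other).__sub__(self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return Tensor(self.data * other.data, parents=(self, other),
                      backward=lambda g: (_unbroadcast(g * other.data, self.shape),
                                          _unbroadcast(g * self.data, other.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return Tensor(self.data / other.data, parents=(self, other),
                      backward=lambda g: (
                          _unbroadcast(g / other.data, self.shape),
                          _unbroadcast(-g * self.data / other.data ** 2, other.shape)))

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def back(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        return Tensor(self.data @ other.data, parents=(self, other), backward=back)

    # -- shape ops ---------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape
        return Tensor(self.data.reshape(*shape), parents=(self,),
                      backward=lambda g: (g.reshape(orig),))

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor(self.data.transpose(*axes), parents=(self,),
                      backward=lambda g: (g.transpose(*inv),))

    def swapaxes(self, a, b):
        return Tensor(np.swapaxes(self.data, a, b), parents=(self,),
                      backward=lambda g: (np.swapaxes(g, a, b),))

    # -- reductions --------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).astype(DTYPE),)
            g2 = g
            if not keepdims:
                g2 = np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).astype(DTYPE),)

        return Tensor(out_data, parents=(self,), backward=back)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def abs(self):
        s = np.sign(self.data)
        return Tensor(np.abs(self.data), parents=(self,), backward=lambda g: (g * s,))


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# pointwise and pooling functionals
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0.0)
    return Tensor(out, parents=(x,),
                  backward=lambda g: (g * (out > 0),))


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor(s, parents=(x,), backward=lambda g: (g * s * (1.0 - s),))


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward=back)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C): spatial average."""
    return x.mean(axis=(2, 3))


def global_max_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C): spatial maximum."""
    n, c, h, w = x.shape
    flat = x.data.reshape(n, c, h * w)
    idx = flat.argmax(axis=2)
    out = np.take_along_axis(flat, idx[..., None], axis=2)[..., 0]

    def back(g):
        gx = np.zeros_like(flat)
        np.put_along_axis(gx, idx[..., None], g[..., None], axis=2)
        return (gx.reshape(x.shape),)

    return Tensor(out, parents=(x,), backward=back)


def channel_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, 1, H, W): average over channels."""
    return x.mean(axis=1, keepdims=True)


def channel_max_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, 1, H, W): maximum over channels."""
    idx = x.data.argmax(axis=1)[:, None]
    out = np.take_along_axis(x.data, idx, axis=1)

    def back(g):
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, idx, g, axis=1)
        return (gx,)

    return Tensor(out, parents=(x,), backward=back)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Base class: parameter discovery and train/eval mode propagation."""

    def __init__(self):
        self.training = False

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(f"state has {len(state)} arrays, model has {len(params)}")
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)], dtype=DTYPE)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    out = rng.standard_normal(shape, dtype=DTYPE)
    out *= np.sqrt(2.0 / fan_in)
    return out


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(he_init(rng, (in_dim, out_dim), in_dim))
        self.bias = Parameter(np.zeros(out_dim, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    """Stride-1 2-D convolution (cross-correlation) with zero padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, padding: int | None = None):
        super().__init__()
        self.kernel = kernel
        self.padding = kernel // 2 if padding is None else padding
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.padding)


def _columns(x: np.ndarray, k: int, pad: int) -> tuple[np.ndarray, int, int]:
    """(N, C, H, W) -> (N, C*k*k, Hout*Wout) column matrix built by k*k
    contiguous shifted-slice copies (fast compared to a gather)."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad,) * 2, (pad,) * 2))
    n, c = x.shape[:2]
    ho, wo = xp.shape[2] - k + 1, xp.shape[3] - k + 1
    cols = np.empty((n, c, k * k, ho, wo), dtype=DTYPE)
    for di in range(k):
        for dj in range(k):
            cols[:, :, di * k + dj] = xp[:, :, di:di + ho, dj:dj + wo]
    return cols.reshape(n, c * k * k, ho * wo), ho, wo


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, padding: int) -> Tensor:
    from . import _convkernels as ck

    k = weight.shape[2]
    n, cin, cout = x.shape[0], weight.shape[1], weight.shape[0]
    ho = x.shape[2] + 2 * padding - k + 1
    wo = x.shape[3] + 2 * padding - k + 1
    use_kernels = ck.HAVE_NUMBA and ho * wo >= ck.MIN_GRID
    bias_data = (np.zeros(cout, dtype=DTYPE) if bias is None else bias.data)

    if use_kernels:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2))
        out = np.empty((n, cout, ho, wo), dtype=DTYPE)
        ck.conv_forward(xp, weight.data, bias_data, out)
        cols = None
    else:
        cols, ho, wo = _columns(x.data, k, padding)
        wflat = weight.data.reshape(cout, -1)                  # (Cout, Cin*k*k)
        out = wflat @ cols                                     # (N, Cout, HW)
        out = (out + bias_data[:, None]).reshape(n, cout, ho, wo)
        xp = None

    def back(g):
        gb = None if bias is None else g.sum(axis=(0, 2, 3)).astype(DTYPE)
        gw = np.zeros(weight.shape, dtype=DTYPE)
        # input gradient: full correlation of g with the flipped kernel
        wback = np.ascontiguousarray(
            weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
        if use_kernels:
            gc = np.ascontiguousarray(g)
            ck.conv_grad_weight(xp, gc, gw)
            gp = np.pad(gc, ((0, 0), (0, 0), (k - 1 - padding,) * 2,
                             (k - 1 - padding,) * 2))
            gx = np.empty((n, cin) + x.shape[2:], dtype=DTYPE)
            ck.conv_forward(gp, wback, np.zeros(cin, dtype=DTYPE), gx)
        else:
            gf = g.reshape(n, cout, ho * wo)
            gw = np.einsum("nch,nkh->ck", gf, cols).reshape(
                weight.shape).astype(DTYPE)
            gcols, hi, wi = _columns(gf.reshape(g.shape), k, k - 1 - padding)
            gx = (wback.reshape(cin, -1) @ gcols).reshape(
                n, cin, hi, wi).astype(DTYPE)
        if bias is None:
            return gx, gw
        return gx, gw, gb

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(out, parents=parents, backward=back)


class MaxPool2x2(Module):
    """2x2 stride-2 max pooling; spatial sides must be even."""

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max pool needs even sides, got {h}x{w}")
        blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
        flat = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=4)
        out = np.take_along_axis(flat, idx[..., None], axis=4)[..., 0]

        def back(g):
            gx = np.zeros_like(flat)
            np.put_along_axis(gx, idx[..., None], g[..., None], axis=4)
            gx = gx.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            return (gx.reshape(x.shape),)

        return Tensor(out, parents=(x,), backward=back)


class LayerNorm(Module):
    """Normalisation over the last axis with learned scale and shift."""

    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.gamma = Parameter(np.ones(dim, dtype=DTYPE))
        self.beta = Parameter(np.zeros(dim, dtype=DTYPE))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.data.mean(axis=-1, keepdims=True)
        var = x.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv
        out = xhat * self.gamma.data + self.beta.data
        gamma, beta = self.gamma, self.beta

        def back(g):
            d = x.shape[-1]
            gxhat = g * gamma.data
            gx = inv / d * (d * gxhat - gxhat.sum(axis=-1, keepdims=True)
                            - xhat * (gxhat * xhat).sum(axis=-1, keepdims=True))
            ggamma = (g * xhat).reshape(-1, d).sum(axis=0).astype(DTYPE)
            gbeta = g.reshape(-1, d).sum(axis=0).astype(DTYPE)
            return gx.astype(DTYPE), ggamma, gbeta

        return Tensor(out, parents=(x, gamma, beta), backward=back)


class Dropout(Module):
    """Inverted dropout; identity when not in training mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return Tensor(x.data * mask, parents=(x,), backward=lambda g: (g * mask,))


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------

class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: Iterable[Parameter], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        if lr <= 0:
            raise ValueError("lr must be positive")
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v


class MultiStepLR:
    """Decay the optimiser lr by `gamma` at each milestone epoch."""

    def __init__(self, optimizer: SGD, milestones: Sequence[int], gamma: float = 0.1):
        if list(milestones) != sorted(set(milestones)):
            raise ValueError("milestones must be strictly increasing")
        self.optimizer = optimizer
        self.milestones = list(milestones)
        self.gamma = gamma
        self.base_lr = optimizer.lr
        self.epoch = 0

    def step(self) -> None:
        """Advance one epoch and update the optimiser's lr."""
        self.epoch += 1
        n = sum(1 for m in self.milestones if m <= self.epoch)
        self.optimizer.lr = self.base_lr * self.gamma ** n
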