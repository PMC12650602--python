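"""Minimal reverse-mode automatic differentiation and neural-network layers.

The engine records a tape of operations on :class:`Tensor` objects wrapping
numpy arrays and replays it backwards to accumulate gradients.  It implements
exactly the operations the beat classifier needs (dense/conv layers, batch and
layer normalisation, multi-head attention building blocks, dropout,
cross-entropy) and nothing else.  Gradients are verified against central finite
differences in the test suite.

Float32 is the working precision for training throughput on CPU; gradient
checks run the same code in float64.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import expit

DEFAULT_DTYPE = np.float32

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


# ---------------------------------------------------------------------------
# Tensor and tape
# ---------------------------------------------------------------------------

class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd -----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of this tensor w.r.t. every reachable leaf."""
        if not self.requires_grad:
            raise ValueError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise ValueError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free the consumed pieces of the tape as backprop proceeds:
                # the node's grad, closure and captured temporaries are dead
                # once its backward has run (leaves keep their grads)
                node._backward = None
                node._parents = ()
                node.grad = None

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)


def as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _pair(a, b) -> tuple[Tensor, Tensor]:
    """Coerce the operands of a binary op, keeping scalar dtype in check.

    A bare python scalar adopts the other operand's dtype so float32 graphs
    are not silently promoted to float64.
    """
    a_t, b_t = isinstance(a, Tensor), isinstance(b, Tensor)
    if a_t and not b_t and np.ndim(b) == 0:
        b = Tensor(np.asarray(b, dtype=a.data.dtype))
    elif b_t and not a_t and np.ndim(a) == 0:
        a = Tensor(np.asarray(a, dtype=b.data.dtype))
    return as_tensor(a), as_tensor(b)


def _accumulate(t: Tensor, g: np.ndarray, own: bool = False) -> None:
    """Add `g` into t.grad; `own=True` promises `g` is a fresh array the
    caller will not reuse, letting the first accumulation skip a copy."""
    if not t.requires_grad:
        return
    g = g.astype(t.data.dtype, copy=False)
    if t.grad is None:
        t.grad = g if own and g.flags.writeable and g.base is None else g.copy()
    else:
        t.grad += g


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _pair(a, b)
    out_data = a.data + b.data
    req = _GRAD_ENABLED and (a.requires_grad or b.requires_grad)
    if not req:
        return Tensor(out_data)

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return Tensor(out_data, True, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _pair(a, b)
    out_data = a.data * b.data
    req = _GRAD_ENABLED and (a.requires_grad or b.requires_grad)
    if not req:
        return Tensor(out_data)

    def backward(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape), own=True)
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape), own=True)

    return Tensor(out_data, True, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = _pair(a, b)
    out_data = a.data / b.data
    req = _GRAD_ENABLED and (a.requires_grad or b.requires_grad)
    if not req:
        return Tensor(out_data)

    def backward(g):
        _accumulate(a, _unbroadcast(g / b.data, a.data.shape))
        _accumulate(b, _unbroadcast(-g * out_data / b.data, b.data.shape))

    return Tensor(out_data, True, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = np.matmul(a.data, b.data)
    req = _GRAD_ENABLED and (a.requires_grad or b.requires_grad)
    if not req:
        return Tensor(out_data)

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        _accumulate(a, _unbroadcast(ga, a.data.shape), own=True)
        _accumulate(b, _unbroadcast(gb, b.data.shape), own=True)

    return Tensor(out_data, True, (a, b), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.maximum(a.data, 0)
    if not (_GRAD_ENABLED and a.requires_grad):
        return Tensor(out_data)

    def backward(g):
        _accumulate(a, g * (a.data > 0), own=True)

    return Tensor(out_data, True, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out_data = expit(a.data)
    if not (_GRAD_ENABLED and a.requires_grad):
        return Tensor(out_data)

    def backward(g):
        _accumulate(a, g * out_data * (1.0 - out_data), own=True)

    return Tensor(out_data, True, (a,), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)
    if not (_GRAD_ENABLED and a.requires_grad):
        return Tensor(out_data)

    def backward(g):
        _accumulate(a, g * out_data)

    return Tensor(out_data, True, (a,), backward)


def sqrt(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.sqrt(a.data)
    if not (_GRAD_ENABLED and a.requires_grad):
        return Tensor(out_data)

    def backward(g):
        _accumulate(a, g * 0.5 / out_data)

    return Tensor(out_data, True, (a,), backward)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)
    if not (_GRAD_ENABLED and a.requires_grad):
        return Tensor(out_data)

    def backward(g):
        if axis is None:
            _accumulate(a, np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accumulate(a, np.broadcast_to(g, a.data.shape).copy())

    return Tensor(out_data, True, (a,), backward)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.reshape(shape)
    if not (_GRAD_ENABLED and a.requires_grad):
        return Tensor(out_data)

    def backward(g):
        _accumulate(a, g.reshape(a.data.shape))

    return Tensor(out_data, True, (a,), backward)


def transpose(a, axes: Sequence[int]) -> Tensor:
    a = as_tensor(a)
    axes = tuple(axes)
    out_data = a.data.transpose(axes)
    if not (_GRAD_ENABLED and a.requires_grad):
        return Tensor(out_data)
    inv = tuple(np.argsort(axes))

    def backward(g):
        _accumulate(a, g.transpose(inv))

    return Tensor(out_data, True, (a,), backward)


def concat(tensors: Sequence, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    req = _GRAD_ENABLED and any(t.requires_grad for t in tensors)
    if not req:
        return Tensor(out_data)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accumulate(t, piece)

    return Tensor(out_data, True, tuple(tensors), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)
    if not (_GRAD_ENABLED and a.requires_grad):
        return Tensor(out_data)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        _accumulate(a, out_data * (g - dot), own=True)

    return Tensor(out_data, True, (a,), backward)


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over a batch of integer class targets."""
    logits = as_tensor(logits)
    targets = np.asarray(targets)
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    loss_val = (lse - z[np.arange(n), targets]).mean()
    out_data = np.asarray(loss_val, dtype=logits.data.dtype)
    if not (_GRAD_ENABLED and logits.requires_grad):
        return Tensor(out_data)

    def backward(g):
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        p[np.arange(n), targets] -= 1.0
        _accumulate(logits, (g / n) * p)

    return Tensor(out_data, True, (logits,), backward)


def dropout(a, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout: scales by 1/(1-p) at train time, identity at eval."""
    a = as_tensor(a)
    if not training or p <= 0.0:
        return a
    keep = rng.random(a.data.shape, dtype=np.float32) >= p   # bool mask
    scale = 1.0 / (1.0 - p)
    out_data = a.data * keep
    out_data *= scale
    if not (_GRAD_ENABLED and a.requires_grad):
        return Tensor(out_data)

    def backward(g):
        ga = g * keep
        ga *= scale
        _accumulate(a, ga, own=True)

    return Tensor(out_data, True, (a,), backward)


def linear_op(x, w, b=None) -> Tensor:
    """Fused affine map ``x @ w + b`` for x [..., in] and w [in, out].

    One output tensor instead of the matmul+add pair, and a 2-D gemm for the
    weight gradient regardless of batch shape.
    """
    x, w = as_tensor(x), as_tensor(w)
    out_data = np.matmul(x.data, w.data)
    if b is not None:
        b = as_tensor(b)
        out_data += b.data
    req = _GRAD_ENABLED and (x.requires_grad or w.requires_grad
                              or (b is not None and b.requires_grad))
    if not req:
        return Tensor(out_data)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if b is not None:
            _accumulate(b, g.reshape(-1, g.shape[-1]).sum(axis=0), own=True)
        x2 = x.data.reshape(-1, x.data.shape[-1])
        g2 = g.reshape(-1, g.shape[-1])
        _accumulate(w, x2.T @ g2, own=True)
        if x.requires_grad:
            _accumulate(x, np.matmul(g, w.data.T), own=True)

    return Tensor(out_data, True, parents, backward)


def attention_core(q, k, v, drop_p: float = 0.0,
                   rng: np.random.Generator | None = None,
                   training: bool = False) -> Tensor:
    """Fused scaled dot-product attention: softmax(q k^T / sqrt(d_k)) v.

    The T x S score matrix is a transient; only the softmax weights (and an
    optional boolean dropout mask over them) are retained for backward.
    """
    q, k, v = as_tensor(q), as_tensor(k), as_tensor(v)
    if q.data.ndim == 2:   # promote unbatched instances
        return reshape(attention_core(reshape(q, (1,) + q.shape),
                                      reshape(k, (1,) + k.shape),
                                      reshape(v, (1,) + v.shape),
                                      drop_p, rng, training),
                       (q.shape[0], v.shape[-1]))
    d_k = q.data.shape[-1]
    scale = 1.0 / np.sqrt(d_k)
    N, T = q.data.shape[0], q.data.shape[-2]
    S, d_v = v.data.shape[-2], v.data.shape[-1]
    inv_keep = 1.0 / (1.0 - drop_p)
    use_drop = training and drop_p > 0.0 and rng is not None
    dtype = q.data.dtype
    weights = np.empty((N, T, S), dtype=dtype)
    keep = np.empty((N, T, S), dtype=bool) if use_drop else None
    out_data = np.empty((N, T, d_v), dtype=dtype)
    # chunk the batch axis so every intermediate pass stays cache-resident
    C = max(1, (4 << 20) // max(T * S * 4, 1))
    for i in range(0, N, C):
        s = slice(i, min(i + C, N))
        sc = np.matmul(q.data[s] * scale, np.swapaxes(k.data[s], -1, -2))
        sc -= sc.max(axis=-1, keepdims=True)
        np.exp(sc, out=sc)
        sc /= sc.sum(axis=-1, keepdims=True)
        weights[s] = sc
        if use_drop:
            keep[s] = rng.random(sc.shape, dtype=np.float32) >= drop_p
            sc *= keep[s]
            sc *= inv_keep
        np.matmul(sc, v.data[s], out=out_data[s])
    req = _GRAD_ENABLED and (q.requires_grad or k.requires_grad
                              or v.requires_grad)
    if not req:
        return Tensor(out_data)

    def backward(g):
        gq = np.empty_like(q.data)
        gk = np.empty_like(k.data)
        gv = np.empty_like(v.data)
        for i in range(0, N, C):
            s = slice(i, min(i + C, N))
            w = weights[s]
            if use_drop:
                applied = w * keep[s]
                applied *= inv_keep
            else:
                applied = w
            np.matmul(np.swapaxes(applied, -1, -2), g[s], out=gv[s])
            gw = np.matmul(g[s], np.swapaxes(v.data[s], -1, -2))
            if use_drop:
                gw *= keep[s]
                gw *= inv_keep
            dot = np.sum(gw * w, axis=-1, keepdims=True)
            gw -= dot
            gw *= w
            gw *= scale
            np.matmul(gw, k.data[s], out=gq[s])
            np.matmul(np.swapaxes(gw, -1, -2), q.data[s], out=gk[s])
        _accumulate(q, gq, own=True)
        _accumulate(k, gk, own=True)
        _accumulate(v, gv, own=True)

    return Tensor(out_data, True, (q, k, v), backward)


def conv1d(x, w, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """1-D cross-correlation of `x` [B, C_in, T] with kernels `w` [C_out, C_in, K]."""
    x, w = as_tensor(x), as_tensor(w)
    B, C_in, T = x.data.shape
    C_out, C_in_w, K = w.data.shape
    if C_in != C_in_w:
        raise ValueError(f"conv1d channel mismatch: input has {C_in}, kernel expects {C_in_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding)))
    T_out = (T + 2 * padding - K) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)
    cols = windows[:, :, ::stride, :][:, :, :T_out, :]          # [B, C_in, T_out, K]
    out_data = np.tensordot(cols, w.data, axes=([1, 3], [1, 2]))  # [B, T_out, C_out]
    out_data = np.ascontiguousarray(out_data.transpose(0, 2, 1))
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data[None, :, None]
    req = _GRAD_ENABLED and (x.requires_grad or w.requires_grad
                              or (b is not None and b.requires_grad))
    if not req:
        return Tensor(out_data)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):  # g: [B, C_out, T_out]
        if b is not None:
            _accumulate(b, g.sum(axis=(0, 2)))
        gw = np.tensordot(g, cols, axes=([0, 2], [0, 2]))        # [C_out, C_in, K]
        _accumulate(w, gw)
        if x.requires_grad:
            # scatter g back through each kernel tap
            g2 = np.tensordot(g, w.data, axes=([1], [0]))        # [B, T_out, C_in, K]
            g2 = g2.transpose(0, 2, 1, 3)                        # [B, C_in, T_out, K]
            gxp = np.zeros_like(xp)
            for k in range(K):
                gxp[:, :, k::stride][:, :, :T_out] += g2[:, :, :, k]
            gx = gxp[:, :, padding:padding + T] if padding else gxp
            _accumulate(x, gx)

    return Tensor(out_data, True, parents, backward)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Module:
    """Base class: parameter discovery by attribute introspection."""

    training: bool = True

    def modules(self) -> Iterable["Module"]:
        for v in vars(self).values():
            if isinstance(v, Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterable[tuple[str, Tensor]]:
        for name, v in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                yield full, v
            elif isinstance(v, Module):
                yield from v.named_parameters(full + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def train(self) -> "Module":
        self.training = True
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        self.training = False
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- checkpointing ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = "") -> Iterable[tuple[str, np.ndarray]]:
        for name, v in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(v, Module):
                yield from v.named_buffers(full + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")
            elif isinstance(v, np.ndarray) and name.startswith("running_"):
                yield full, v

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {}
        self._collect_buffer_owners(buffers, "")
        for name, value in state.items():
            if name in params:
                params[name].data = value.copy()
            elif name in buffers:
                owner, attr = buffers[name]
                setattr(owner, attr, value.copy())
            else:
                raise KeyError(f"unknown state entry {name!r}")

    def _collect_buffer_owners(self, out: dict, prefix: str) -> None:
        for name, v in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(v, Module):
                v._collect_buffer_owners(out, full + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item._collect_buffer_owners(out, f"{full}.{i}.")
            elif isinstance(v, np.ndarray) and name.startswith("running_"):
                out[full] = (self, name)


def _uniform_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    bound = 1.0 / math.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Linear(Module):
    """Affine map y = x W + b with W of shape [in_features, out_features]."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True,
                 dtype=DEFAULT_DTYPE):
        self.weight = Tensor(_uniform_init(rng, (in_features, out_features),
                                           in_features, dtype), requires_grad=True)
        self.bias = (Tensor(_uniform_init(rng, (out_features,), in_features, dtype),
                            requires_grad=True) if bias else None)

    def __call__(self, x) -> Tensor:
        return linear_op(x, self.weight, self.bias)


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 bias: bool = True, dtype=DEFAULT_DTYPE):
        fan_in = in_channels * kernel_size
        self.weight = Tensor(_uniform_init(rng, (out_channels, in_channels, kernel_size),
                                           fan_in, dtype), requires_grad=True)
        self.bias = (Tensor(_uniform_init(rng, (out_channels,), fan_in, dtype),
                            requires_grad=True) if bias else None)
        self.stride = stride
        self.padding = padding

    def __call__(self, x) -> Tensor:
        return conv1d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding)


def batch_norm_train(x, gamma: Tensor, beta: Tensor, eps: float
                     ) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused training-mode batch norm over [B, C, T] (stats over B and T).

    Returns the normalised tensor plus the batch mean and (population)
    variance so the caller can maintain running statistics.
    """
    x = as_tensor(x)
    mean = x.data.mean(axis=(0, 2))
    xc = x.data - mean[None, :, None]
    var = np.mean(xc * xc, axis=(0, 2))
    inv = (1.0 / np.sqrt(var + eps)).astype(x.dtype)
    xhat = xc * inv[None, :, None]
    out_data = xhat * gamma.data[None, :, None] + beta.data[None, :, None]
    req = _GRAD_ENABLED and (x.requires_grad or gamma.requires_grad
                              or beta.requires_grad)
    if not req:
        return Tensor(out_data), mean, var
    n = x.data.shape[0] * x.data.shape[2]

    def backward(g):
        ggamma = np.sum(g * xhat, axis=(0, 2))
        gbeta = np.sum(g, axis=(0, 2))
        _accumulate(gamma, ggamma, own=True)
        _accumulate(beta, gbeta, own=True)
        if x.requires_grad:
            coef = (gamma.data * inv / n)[None, :, None]
            gx = (n * g - gbeta[None, :, None]
                  - xhat * ggamma[None, :, None]) * coef
            _accumulate(x, gx, own=True)

    return Tensor(out_data, True, (x, gamma, beta), backward), mean, var


class BatchNorm1d(Module):
    """Batch normalisation over [B, C, T]; running stats used in eval mode."""

    def __init__(self, num_features: int, momentum: float = 0.1,
                 eps: float = 1e-5, dtype=DEFAULT_DTYPE):
        self.gamma = Tensor(np.ones(num_features, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x) -> Tensor:
        x = as_tensor(x)
        if self.training:
            out, mean, var = batch_norm_train(x, self.gamma, self.beta,
                                              self.eps)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mean).astype(self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var
                                + m * var).astype(self.running_var.dtype)
            return out
        mean = self.running_mean[None, :, None]
        inv = 1.0 / np.sqrt(self.running_var[None, :, None] + self.eps)
        xhat = mul(add(x, Tensor(-mean)), Tensor(inv.astype(x.dtype)))
        return add(mul(xhat, reshape(self.gamma, (1, -1, 1))),
                   reshape(self.beta, (1, -1, 1)))


def layer_norm(x, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Fused layer normalisation over the last axis (hand-written backward).

    Composing this from primitives costs ~15 full-size passes per call; the
    transformer applies it four times per layer, so it is fused.
    """
    x = as_tensor(x)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = np.mean(xc * xc, axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gamma.data + beta.data
    req = _GRAD_ENABLED and (x.requires_grad or gamma.requires_grad
                              or beta.requires_grad)
    if not req:
        return Tensor(out_data)

    def backward(g):
        _accumulate(gamma, (g * xhat).sum(axis=tuple(range(g.ndim - 1))),
                    own=True)
        _accumulate(beta, g.sum(axis=tuple(range(g.ndim - 1))), own=True)
        if x.requires_grad:
            gx = g * gamma.data
            n = x.data.shape[-1]
            s1 = gx.sum(axis=-1, keepdims=True)
            s2 = (gx * xhat).sum(axis=-1, keepdims=True)
            _accumulate(x, (gx - s1 / n - xhat * (s2 / n)) * inv, own=True)

    return Tensor(out_data, True, (x, gamma, beta), backward)


class LayerNorm(Module):
    """Layer normalisation over the last axis."""

    def __init__(self, dim: int, eps: float = 1e-5, dtype=DEFAULT_DTYPE):
        self.gamma = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)
        self.eps = eps

    def __call__(self, x) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def __call__(self, x) -> Tensor:
        return dropout(x, self.p, self.rng, self.training)


def global_avg_pool(x) -> Tensor:
    """Adaptive average pooling to length 1: mean over the trailing time axis."""
    return tmean(x, axis=-1)
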