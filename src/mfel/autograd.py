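"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine is deliberately small: a :class:`Tensor` wraps a float64/float32
numpy array and records the operations applied to it; :meth:`Tensor.backward`
runs the reverse sweep over the recorded tape. Only the operations needed by
the segmentation/reconstruction network are provided (elementwise arithmetic,
matmul, stride-1 convolution via im2col, bilinear 2x upsampling, reductions,
softmax, and the usual activations). Everything is deterministic: identical
inputs and weights give bit-identical outputs on one platform.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "stack", "use_dtype", "default_dtype"]

_DTYPE = np.float64


def default_dtype():
    return _DTYPE


@contextmanager
def use_dtype(dtype):
    """Temporarily set the dtype new tensors are created with.

    float64 is the default (analysis ops, tight tolerances); network
    training runs under float32, the standard precision for this kind of
    model, which roughly halves memory traffic.
    """
    global _DTYPE
    prev = _DTYPE
    _DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        _DTYPE = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- basic protocol ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- graph bookkeeping ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray, own: bool = False):
        # `own=True` promises the array is not handed to any other tensor,
        # so it can be adopted without a defensive copy; otherwise copy on
        # first write because a later in-place += must not alias siblings
        if self.grad is None:
            self.grad = grad if own else np.array(grad)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs can be deep: SSM scans)
        topo: list[Tensor] = []
        visiting: list[tuple[Tensor, bool]] = [(self, False)]
        seen: set[int] = set()
        while visiting:
            node, processed = visiting.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            visiting.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    visiting.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        return self

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g, own=True)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape), own=True)
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape), own=True)

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape), own=True)
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data * other.data), other.data.shape),
                    own=True,
                )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1), own=True)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape), own=True)
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape), own=True)

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise functions ---------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data, own=True)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data, own=True)

        return Tensor._make(out_data, (self,), backward)

    def abs(self):
        out_data = np.abs(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * np.sign(self.data), own=True)

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask, own=True)

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data), own=True)

        return Tensor._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data * out_data), own=True)

        return Tensor._make(out_data, (self,), backward)

    def softplus(self):
        # numerically stable log(1 + e^x)
        out_data = np.logaddexp(0.0, self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / (1.0 + np.exp(-self.data)), own=True)

        return Tensor._make(out_data, (self,), backward)

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * s

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (s * (1.0 + self.data * (1.0 - s))), own=True)

        return Tensor._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only inside the range."""
        mask = (self.data >= lo) & (self.data <= hi)
        out_data = np.clip(self.data, lo, hi)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy(), own=True)
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape).copy(), own=True)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        src_shape = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(src_shape), own=True)

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv), own=True)

        return Tensor._make(out_data, (self,), backward)

    @property
    def T(self):
        return self.transpose(tuple(range(self.data.ndim))[::-1])

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[idx] = g
                self._accumulate(full, own=True)

        return Tensor._make(out_data, (self,), backward)

    # -- fused numerical ops --------------------------------------------------
    def softmax(self):
        """Softmax over the last axis (numerically stabilized)."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        np.exp(z, out=z)
        z /= z.sum(axis=-1, keepdims=True)
        out_data = z

        def backward(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=-1, keepdims=True)
                self._accumulate(out_data * (g - dot), own=True)

        return Tensor._make(out_data, (self,), backward)

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None, padding: int = 0):
        """Stride-1 2-D cross-correlation of a [C_in,H,W] map.

        weight: [C_out, C_in, k, k]; output [C_out, H', W'] with
        H' = H + 2*padding - k + 1. Implemented as im2col + BLAS matmul;
        the input gradient is computed as a transposed convolution (again a
        matmul) so no scatter-adds are needed.
        """
        x = self.data
        w = weight.data
        c_out, c_in, k, _ = w.shape
        if x.shape[0] != c_in:
            raise ValueError(f"conv2d channel mismatch: input {x.shape[0]}, weight {c_in}")
        cols, out_hw = _im2col(x, k, padding)  # [c_in*k*k, H'*W']
        w2 = w.reshape(c_out, c_in * k * k)
        out = w2 @ cols
        if bias is not None:
            out = out + bias.data.reshape(c_out, 1)
        out_data = out.reshape(c_out, *out_hw)

        def backward(g):
            g2 = g.reshape(c_out, -1)
            if weight.requires_grad:
                gw = (g2 @ cols.T).reshape(w.shape)
                weight._accumulate(gw, own=True)
            if bias is not None and bias.requires_grad:
                bias._accumulate(g2.sum(axis=1), own=True)
            if self.requires_grad:
                # dX = full correlation of g with spatially-flipped, channel-swapped w
                w_flip = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # [c_in, c_out, k, k]
                gcols, _ = _im2col(g, k, k - 1 - padding)
                gx = (w_flip.reshape(c_in, c_out * k * k) @ gcols).reshape(x.shape)
                self._accumulate(gx, own=True)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._make(out_data, parents, backward)

    def avg_pool2x(self):
        """2x2 average pooling with stride 2 on a [C,H,W] map (H, W even)."""
        c, h, w = self.data.shape
        r = self.data.reshape(c, h // 2, 2, w // 2, 2)
        out_data = r.mean(axis=(2, 4))

        def backward(g):
            if self.requires_grad:
                gx = np.repeat(np.repeat(g, 2, axis=1), 2, axis=2) * 0.25
                self._accumulate(gx, own=True)

        return Tensor._make(out_data, (self,), backward)

    def upsample_bilinear2x(self):
        """Bilinear 2x upsampling of a [C,H,W] map (align_corners=False)."""
        c, h, w = self.data.shape
        U = _interp_matrix(h).astype(self.data.dtype, copy=False)
        V = _interp_matrix(w).astype(self.data.dtype, copy=False)
        out_data = U @ self.data @ V.T

        def backward(g):
            if self.requires_grad:
                self._accumulate(U.T @ g @ V, own=True)

        return Tensor._make(out_data, (self,), backward)


_INTERP_CACHE: dict[int, np.ndarray] = {}


def _interp_matrix(n: int) -> np.ndarray:
    """Dense [2n, n] matrix performing 1-D bilinear 2x upsampling."""
    M = _INTERP_CACHE.get(n)
    if M is None:
        M = np.zeros((2 * n, n))
        for o in range(2 * n):
            src = (o + 0.5) / 2.0 - 0.5
            i0 = int(np.floor(src))
            frac = src - i0
            i0c = min(max(i0, 0), n - 1)
            i1c = min(max(i0 + 1, 0), n - 1)
            M[o, i0c] += 1.0 - frac
            M[o, i1c] += frac
        _INTERP_CACHE[n] = M
    return M


def _im2col(x: np.ndarray, k: int, padding: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Unfold [C,H,W] into [C*k*k, H'*W'] patches (stride 1)."""
    c, h, w = x.shape
    ho = h + 2 * padding - k + 1
    wo = w + 2 * padding - k + 1
    if k == 1 and padding == 0:
        return x.reshape(c, h * w), (ho, wo)
    if padding:
        x = np.pad(x, ((0, 0), (padding, padding), (padding, padding)))
    # k*k contiguous slice copies beat a strided gather by a wide margin
    cols = np.empty((c, k * k, ho * wo), dtype=x.dtype)
    for ki in range(k):
        for kj in range(k):
            cols[:, ki * k + kj, :] = x[:, ki:ki + ho, kj:kj + wo].reshape(c, ho * wo)
    return cols.reshape(c * k * k, ho * wo), (ho, wo)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)], own=True)

    return Tensor._make(out_data, tuple(tensors), backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis), own=True)

    return Tensor._make(out_data, tuple(tensors), backward)
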