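"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the segmentation network and its hybrid loss
need: broadcasting arithmetic, elementwise nonlinearities, reductions, slicing,
channel concatenation, 2-D convolution (with dilation), 2x max pooling and 2x
bilinear upsampling.  Tensors form a DAG; :meth:`Tensor.backward` runs a
topological sweep accumulating gradients into every node with
``requires_grad=True``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "maxpool2x", "upsample2x"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if not t._parents:  # leaf
                t.grad = g if t.grad is None else t.grad + g
                continue
            for parent, pg in t._backward(g):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg

    # -- arithmetic ------------------------------------------------------
    def _lift(self, x) -> "Tensor":
        if isinstance(x, Tensor):
            return x
        # python scalars adopt this tensor's dtype so float32 graphs stay float32
        return Tensor(np.asarray(x, dtype=self.data.dtype if np.isscalar(x) else np.float64))

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        out._backward = lambda g: (
            (self, _unbroadcast(g, self.data.shape)),
            (other, _unbroadcast(g, other.data.shape)),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: ((self, -g),)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        out._backward = lambda g: (
            (self, _unbroadcast(g * other.data, self.data.shape)),
            (other, _unbroadcast(g * self.data, other.data.shape)),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        out._backward = lambda g: (
            (self, _unbroadcast(g / other.data, self.data.shape)),
            (other, _unbroadcast(-g * self.data / other.data**2, other.data.shape)),
        )
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))
        out._backward = lambda g: ((self, g * exponent * self.data ** (exponent - 1)),)
        return out

    # -- elementwise -----------------------------------------------------
    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: ((self, g / self.data),)
        return out

    def exp(self):
        od = np.exp(self.data)
        out = Tensor(od, parents=(self,))
        out._backward = lambda g: ((self, g * od),)
        return out

    def sqrt(self):
        od = np.sqrt(self.data)
        out = Tensor(od, parents=(self,))
        out._backward = lambda g: ((self, g * 0.5 / od),)
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0), parents=(self,))
        out._backward = lambda g: ((self, g * (self.data > 0)),)
        return out

    def sigmoid(self):
        od = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(od, parents=(self,))
        out._backward = lambda g: ((self, g * od * (1.0 - od)),)
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through unclamped entries."""
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))
        mask = (self.data > lo) & (self.data < hi)
        out._backward = lambda g: ((self, g * mask),)
        return out

    # -- reductions / shaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def back(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g, self.data.shape).copy()),)

        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: ((self, g.reshape(self.data.shape)),)
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def back(g):
            full = np.zeros_like(self.data)
            parts = idx if isinstance(idx, tuple) else (idx,)
            if all(isinstance(p, (slice, int)) for p in parts):
                full[idx] += g  # slices never alias, so in-place add is exact
            else:
                np.add.at(full, idx, g)
            return ((self, full),)

        out._backward = back
        return out

    def broadcast_hw(self, h: int, w: int):
        """Tile a (N,C,1,1) map to (N,C,h,w); gradient sums over the plane."""
        out = Tensor(np.broadcast_to(self.data, self.data.shape[:2] + (h, w)).copy(),
                     parents=(self,))
        out._backward = lambda g: ((self, g.sum(axis=(2, 3), keepdims=True)),)
        return out


def concat(tensors, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    out._backward = back
    return out


def conv2d(x: Tensor, w: Tensor, dilation: int = 1) -> Tensor:
    """Same-padded 2-D convolution: x (N,C,H,W), w (O,C,kh,kw).

    Implemented as im2col + one GEMM; the column matrix is kept for the
    backward pass (dW and dX are each a single GEMM plus a scatter).
    """
    N, C, H, W = x.data.shape
    O, C2, kh, kw = w.data.shape
    if C != C2:
        raise ValueError(f"channel mismatch: input {C}, kernel {C2}")
    if kh == 1 and kw == 1:  # pointwise: pure channel mixing
        xmat = x.data.transpose(0, 2, 3, 1).reshape(-1, C)
        wmat = w.data.reshape(O, C)
        out_data = (xmat @ wmat.T).reshape(N, H, W, O).transpose(0, 3, 1, 2)
        out = Tensor(np.ascontiguousarray(out_data), parents=(x, w))

        def back1(g):
            gmat = g.transpose(0, 2, 3, 1).reshape(-1, O)
            gw = (gmat.T @ xmat).reshape(O, C, 1, 1)
            gx = (gmat @ wmat).reshape(N, H, W, C).transpose(0, 3, 1, 2)
            return ((x, np.ascontiguousarray(gx)), (w, gw))

        out._backward = back1
        return out

    out_data, cols = _corr2d(x.data, w.data, dilation)
    out = Tensor(out_data, parents=(x, w))

    def back(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * H * W, O)
        gw = (gmat.T @ cols).reshape(O, C, kh, kw)
        # dX is the same-padded correlation of g with the spatially flipped
        # kernel, channels transposed (valid for stride 1 / odd kernels).
        w_flip = np.ascontiguousarray(
            w.data.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
        gx, _ = _corr2d(g, w_flip, dilation)
        return ((x, gx), (w, gw))

    out._backward = back
    return out


def _corr2d(data: np.ndarray, kernel: np.ndarray, dilation: int):
    """Same-padded correlation via im2col + GEMM; returns (out, col matrix)."""
    N, C, H, W = data.shape
    O, _, kh, kw = kernel.shape
    ph, pw = dilation * (kh // 2), dilation * (kw // 2)
    xp = np.pad(data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(
        xp, (dilation * (kh - 1) + 1, dilation * (kw - 1) + 1), axis=(2, 3)
    )[:, :, :, :, ::dilation, ::dilation]  # (N,C,H,W,kh,kw) view
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N * H * W, C * kh * kw)
    out = (cols @ kernel.reshape(O, -1).T).reshape(N, H, W, O).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(out), cols


def maxpool2x(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2x requires even spatial dims")
    xr = x.data.reshape(N, C, H // 2, 2, W // 2, 2)
    out_data = xr.max(axis=(3, 5))
    out = Tensor(out_data, parents=(x,))

    def back(g):
        mask = xr == out_data[:, :, :, None, :, None]
        cnt = mask.sum(axis=(3, 5), keepdims=True)
        gx = mask * (g[:, :, :, None, :, None] / cnt)
        return ((x, gx.reshape(N, C, H, W)),)

    out._backward = back
    return out


_BILINEAR_K = np.array([[0.25, 0.5, 0.25], [0.5, 1.0, 0.5], [0.25, 0.5, 0.25]])


def _depthwise3(x: np.ndarray, k: np.ndarray) -> np.ndarray:
    """3x3 same-padded depthwise convolution with one shared kernel."""
    N, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.zeros_like(x)
    for i in range(3):
        for j in range(3):
            if k[i, j]:
                out += k[i, j] * xp[:, :, i:i + H, j:j + W]
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Factor-2 bilinear upsampling (zero-stuffing + fixed smoothing kernel)."""
    N, C, H, W = x.data.shape
    stuffed = np.zeros((N, C, 2 * H, 2 * W), dtype=x.data.dtype)
    stuffed[:, :, ::2, ::2] = x.data
    out = Tensor(_depthwise3(stuffed, _BILINEAR_K), parents=(x,))

    def back(g):
        return ((x, _depthwise3(g, _BILINEAR_K)[:, :, ::2, ::2]),)

    out._backward = back
    return out
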