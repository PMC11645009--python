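"""A small reverse-mode automatic-differentiation engine on NumPy arrays.

This is the numerical core that the dual-pathway video network and the loss
family are built on.  It implements exactly the primitives those components
need — elementwise arithmetic, matmul, stable sigmoid/softplus, reductions,
reshape/concat/slicing, 3-D convolution and region-of-interest average
pooling — with define-by-run graph construction and a topological backward
pass.  Gradients accumulate into ``Tensor.grad`` for leaves created with
``requires_grad=True``.

Arrays are kept in whatever float dtype they arrive in (float32 for training,
float64 in gradient-check tests).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "no_grad", "conv3d", "instance_norm", "roi_pool",
           "concatenate", "Adam"]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _as_array(data) -> np.ndarray:
    arr = np.asarray(data)
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
    return arr


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- graph plumbing ---------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- introspection ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _coerce_like(self, other) -> "Tensor":
        """Coerce, keeping this tensor's dtype for bare Python scalars so a
        float32 graph is not silently promoted to float64."""
        if isinstance(other, Tensor):
            return other
        if isinstance(other, (int, float)):
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return Tensor(other)

    def __add__(self, other):
        other = self._coerce_like(other)
        out_data = self.data + other.data

        def backward(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce_like(other))

    def __rsub__(self, other):
        return self._coerce_like(other) + (-self)

    def __mul__(self, other):
        other = self._coerce_like(other)
        out_data = self.data * other.data

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce_like(other)
        out_data = self.data / other.data

        def backward(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._coerce_like(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        out_data = self.data**e

        def backward(g):
            self._accumulate(g * e * self.data ** (e - 1.0))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)
        out_data = self.data @ other.data

        def backward(g):
            self._accumulate(g @ other.data.swapaxes(-1, -2))
            other._accumulate(self.data.swapaxes(-1, -2) @ g)

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities ---------------------------------------

    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        x = self.data
        out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                            np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

        def backward(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def softplus(self):
        """log(1 + exp(x)), computed stably; derivative is sigmoid(x)."""
        x = self.data
        out_data = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))

        def backward(g):
            sig = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                           np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
            self._accumulate(g * sig)

        return Tensor._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            self._accumulate(g / self.data)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions and shape ops -----------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g_arr = np.asarray(g)
            if axis is not None and not keepdims:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                g_arr = np.expand_dims(g_arr, axes)
            self._accumulate(np.broadcast_to(g_arr, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            self._accumulate(g.reshape(orig))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, axes: Sequence[int]):
        axes = tuple(axes)
        inverse = tuple(np.argsort(axes))
        out_data = self.data.transpose(axes)

        def backward(g):
            self._accumulate(g.transpose(inverse))

        return Tensor._make(out_data, (self,), backward)

    def __getitem__(self, index):
        out_data = self.data[index]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, index, g)
            self._accumulate(full)

        return Tensor._make(out_data, (self,), backward)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, stop)
            t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tensors, backward)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: tuple[int, int, int] = (1, 1, 1),
           padding: tuple[int, int, int] = (0, 0, 0)) -> Tensor:
    """3-D convolution over (N, C, T, H, W) input with an (O, C, kt, kh, kw) kernel.

    Lowered to an im2col matrix product (one GEMM forward, two backward); the
    column buffer is kept for the backward pass and the input gradient is
    scattered back with one strided add per kernel offset.
    """
    x = Tensor._coerce(x)
    w = Tensor._coerce(w)
    st, sh, sw = stride
    pt, ph, pw = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
    n, c, t, h, wd = xp.shape
    co, ci, kt, kh, kw = w.shape
    if ci != c:
        raise ValueError(f"conv3d channel mismatch: input {c}, kernel {ci}")
    to = (t - kt) // st + 1
    ho = (h - kh) // sh + 1
    wo = (wd - kw) // sw + 1
    if min(to, ho, wo) < 1:
        raise ValueError(f"conv3d output would be empty for input {x.shape}")

    view = np.lib.stride_tricks.sliding_window_view(xp, (kt, kh, kw), axis=(2, 3, 4))
    view = view[:, :, ::st, ::sh, ::sw]  # (N, C, To, Ho, Wo, kt, kh, kw)
    cols = np.ascontiguousarray(view.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
        n * to * ho * wo, c * kt * kh * kw
    )
    wmat = w.data.reshape(co, -1)
    out_mat = cols @ wmat.T  # (M, Co)
    out_data = out_mat.reshape(n, to, ho, wo, co).transpose(0, 4, 1, 2, 3)
    if b is not None:
        out_data += b.data.reshape(1, co, 1, 1, 1)
    out_data = np.ascontiguousarray(out_data)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g_mat = g.transpose(0, 2, 3, 4, 1).reshape(-1, co)
        if w.requires_grad:
            w._accumulate((g_mat.T @ cols).reshape(w.shape))
        if x.requires_grad:
            dcols = (g_mat @ wmat).reshape(n, to, ho, wo, c, kt, kh, kw)
            dcols = dcols.transpose(0, 4, 1, 2, 3, 5, 6, 7)
            dxp = np.zeros_like(xp)
            for a in range(kt):
                for bb in range(kh):
                    for cc in range(kw):
                        dxp[:, :, a:a + st * to:st, bb:bb + sh * ho:sh,
                            cc:cc + sw * wo:sw] += dcols[..., a, bb, cc]
            x._accumulate(dxp[:, :, pt:t - pt or None, ph:h - ph or None,
                              pw:wd - pw or None])
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))

    return Tensor._make(out_data, parents, backward)


def instance_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize each (sample, channel) slice over its remaining axes to zero
    mean and unit variance.  Batch-free, so train and inference agree."""
    x = Tensor._coerce(x)
    axes = tuple(range(2, x.ndim))
    m = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = (x.data - m) * inv

    def backward(g):
        gm = g.mean(axis=axes, keepdims=True)
        gym = (g * y).mean(axis=axes, keepdims=True)
        x._accumulate(inv * (g - gm - y * gym))

    return Tensor._make(y, (x,), backward)


def roi_pool(features: Tensor, rois: Sequence[tuple[int, float, float, float, float]]) -> Tensor:
    """Average-pool a normalized box region (over time and space) per ROI.

    ``rois`` is a sequence of ``(batch_index, x1, y1, x2, y2)`` with box
    coordinates in [0, 1]; the result has shape (len(rois), C).  The region
    is snapped outward to the feature grid so it always covers at least one
    cell.
    """
    features = Tensor._coerce(features)
    n, c, t, h, w = features.shape
    regions = []
    for bi, x1, y1, x2, y2 in rois:
        ix1 = int(np.clip(np.floor(x1 * w), 0, w - 1))
        ix2 = int(np.clip(np.ceil(x2 * w), ix1 + 1, w))
        iy1 = int(np.clip(np.floor(y1 * h), 0, h - 1))
        iy2 = int(np.clip(np.ceil(y2 * h), iy1 + 1, h))
        regions.append((int(bi), iy1, iy2, ix1, ix2))

    out_data = np.empty((len(regions), c), dtype=features.data.dtype)
    for i, (bi, iy1, iy2, ix1, ix2) in enumerate(regions):
        out_data[i] = features.data[bi, :, :, iy1:iy2, ix1:ix2].mean(axis=(1, 2, 3))

    def backward(g):
        dx = np.zeros_like(features.data)
        for i, (bi, iy1, iy2, ix1, ix2) in enumerate(regions):
            count = t * (iy2 - iy1) * (ix2 - ix1)
            dx[bi, :, :, iy1:iy2, ix1:ix2] += (g[i] / count)[:, None, None, None]
        features._accumulate(dx)

    return Tensor._make(out_data, (features,), backward)


class Adam:
    """Adam optimizer over a name → Tensor parameter mapping."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-2,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.step_count = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def step(self) -> None:
        self.step_count += 1
        t = self.step_count
        for key, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            m = self._m[key]
            v = self._v[key]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            m_hat = m / (1 - self.beta1**t)
            v_hat = v / (1 - self.beta2**t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
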