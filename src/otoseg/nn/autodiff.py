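"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine is deliberately small: a :class:`Tensor` wrapping a float32
``ndarray`` plus the closed set of primitives the volumetric encoder-decoder
network needs (elementwise arithmetic, a few nonlinearities, reductions,
channel concatenation, 3D convolutions and the stride-2 up/down kernels,
instance/batch normalization). Gradients are accumulated by walking the tape
in reverse topological order. Everything is CPU-deterministic: the same
inputs and parameters produce bitwise-identical outputs and gradients.

Array layout is channel-leading ``(C, D, H, W)`` with an implicit batch of
one; the training loop realizes larger effective batches through gradient
accumulation instead.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv3d",
    "conv3d_k1",
    "conv3d_down2",
    "conv_transpose3d_up2",
    "instance_norm",
]

_F32 = np.float32


def _as_array(x) -> np.ndarray:
    """Coerce to a floating ndarray; float64 is preserved (gradient checks),
    everything else becomes float32 (network default)."""
    a = np.asarray(x)
    if not np.issubdtype(a.dtype, np.floating):
        a = a.astype(_F32)
    elif a.dtype == np.float16:
        a = a.astype(_F32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # -- construction -----------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -------------------------------------------------------

    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor._make(self.data + other.data, (self, other), None)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._make(-self.data, (self,), None)
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        other = self._coerce(other)
        out = Tensor._make(self.data - other.data, (self, other), None)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(-g, other.shape))

        out._backward = backward
        return out

    def __rsub__(self, other):
        return self._coerce(other) - self

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor._make(self.data * other.data, (self, other), None)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor._make(self.data / other.data, (self, other), None)

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / (other.data * other.data), other.shape),
            )

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        out = Tensor._make(self.data ** p, (self,), None)
        out._backward = lambda g: (g * p * self.data ** (p - 1),)
        return out

    # -- elementwise nonlinearities --------------------------------------

    def exp(self):
        e = np.exp(self.data)
        out = Tensor._make(e, (self,), None)
        out._backward = lambda g: (g * e,)
        return out

    def log(self):
        out = Tensor._make(np.log(self.data), (self,), None)
        out._backward = lambda g: (g / self.data,)
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor._make(t, (self,), None)
        out._backward = lambda g: (g * (1.0 - t * t),)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor._make(s, (self,), None)
        out._backward = lambda g: (g * s * (1.0 - s),)
        return out

    def softplus(self):
        # log(1 + e^x), evaluated stably; derivative is the sigmoid
        sp = np.logaddexp(0.0, self.data).astype(self.data.dtype)
        out = Tensor._make(sp, (self,), None)
        out._backward = lambda g: (g / (1.0 + np.exp(-self.data)),)
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor._make(self.data * mask, (self,), None)
        out._backward = lambda g: (g * mask,)
        return out

    def leaky_relu(self, slope: float = 0.025):
        pos = self.data > 0
        out = Tensor._make(np.where(pos, self.data, slope * self.data), (self,), None)
        out._backward = lambda g: (np.where(pos, g, _F32(slope) * g),)
        return out

    def clip(self, lo: float, hi: float):
        inside = (self.data > lo) & (self.data < hi)
        out = Tensor._make(np.clip(self.data, lo, hi), (self,), None)
        out._backward = lambda g: (g * inside,)
        return out

    # -- reductions / reshaping ------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), None
        )

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).astype(g.dtype),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.shape
        out = Tensor._make(self.data.reshape(*shape), (self,), None)
        out._backward = lambda g: (g.reshape(old),)
        return out

    def item(self) -> float:
        return float(self.data)

    # -- backward pass ----------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(node):
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    topo.append(n)
                    continue
                if id(n) in seen or not n.requires_grad:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    stack.append((p, False))

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): _as_array(grad)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in zip(node._parents, node._backward(g)):
                    if not parent.requires_grad or pg is None:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg
            if not node._parents:  # leaf (parameter or input)
                node.grad = g if node.grad is None else node.grad + g

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={'yes' if self.requires_grad else 'no'})"


# -- structural ops -------------------------------------------------------


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(data, tuple(tensors), backward)


# -- convolutions ---------------------------------------------------------


def _shift_view(padded: np.ndarray, off, shape):
    dz, dy, dx = off
    d, h, w = shape
    return padded[:, dz : dz + d, dy : dy + h, dx : dx + w]


# slab size cap for the im2col scratch matrix, in bytes
_COL_BYTES_CAP = 192 * 1024 * 1024

_OFFSETS3 = [(dz, dy, dx) for dz in range(3) for dy in range(3) for dx in range(3)]


def _slab_ranges(d: int, cin: int, h: int, wd: int, itemsize: int):
    """Partition the depth axis so each im2col slab stays under the cap."""
    bytes_per_slice = cin * 27 * h * wd * itemsize
    step = max(1, min(d, _COL_BYTES_CAP // max(1, bytes_per_slice)))
    return [(z0, min(z0 + step, d)) for z0 in range(0, d, step)]


def _im2col_slab(padded: np.ndarray, z0: int, z1: int, h: int, wd: int,
                 col: np.ndarray):
    """Fill ``col`` (Cin*27, (z1-z0)*H*W) from the padded input."""
    cin = padded.shape[0]
    nz = z1 - z0
    c3 = col.reshape(cin, 27, nz * h * wd)
    for k, (dz, dy, dx) in enumerate(_OFFSETS3):
        view = padded[:, z0 + dz : z0 + dz + nz, dy : dy + h, dx : dx + wd]
        c3[:, k, :] = view.reshape(cin, -1)
    return col


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """3x3x3 convolution, stride 1, zero padding 1 ('same' shape).

    ``x``: (Cin, D, H, W); ``w``: (Cout, Cin, 3, 3, 3); ``b``: (Cout,).
    Uses slab-wise im2col (one GEMM per depth slab) so peak scratch memory
    stays bounded while the GEMMs remain large enough to run at full BLAS
    throughput.
    """
    cin, d, h, wd = x.shape
    cout = w.shape[0]
    dtype = np.result_type(x.data, w.data)
    padded = np.pad(x.data, ((0, 0), (1, 1), (1, 1), (1, 1)))
    wmat = w.data.reshape(cout, cin * 27)
    out = np.empty((cout, d, h, wd), dtype=dtype)
    slabs = _slab_ranges(d, cin, h, wd, dtype.itemsize)
    col = np.empty((cin * 27, (slabs[0][1] - slabs[0][0]) * h * wd), dtype=dtype)
    for z0, z1 in slabs:
        n = (z1 - z0) * h * wd
        c = col[:, :n] if n != col.shape[1] else col
        _im2col_slab(padded, z0, z1, h, wd, c)
        out[:, z0:z1] = (wmat @ c).reshape(cout, z1 - z0, h, wd)
    if b is not None:
        out += b.data[:, None, None, None].astype(dtype)

    parents = (x, w) if b is None else (x, w, b)
    # single-slab training case: keep the im2col matrix for the weight grad
    cached_col = col if (len(slabs) == 1 and w.requires_grad) else None

    def backward(g):
        gx = gw = gb = None
        need_x = x.requires_grad
        need_w = w.requires_grad
        if need_x:
            gpad = np.zeros_like(padded)
        if need_w:
            gwmat = np.zeros((cout, cin * 27), dtype=dtype)
        if need_x or need_w:
            gcol = np.empty((cin * 27, (slabs[0][1] - slabs[0][0]) * h * wd),
                            dtype=dtype)
            for z0, z1 in slabs:
                nz = z1 - z0
                n = nz * h * wd
                g2d = g[:, z0:z1].reshape(cout, n)
                if need_w:
                    if cached_col is not None:
                        c = cached_col
                    else:
                        c = gcol[:, :n] if n != gcol.shape[1] else gcol
                        _im2col_slab(padded, z0, z1, h, wd, c)
                    gwmat += g2d @ c.T
                if need_x:
                    gc = (gcol[:, :n] if n != gcol.shape[1] else gcol)
                    np.matmul(wmat.T, g2d, out=gc)
                    gc3 = gc.reshape(cin, 27, nz, h, wd)
                    for k, (dz, dy, dx) in enumerate(_OFFSETS3):
                        gpad[:, z0 + dz : z0 + dz + nz, dy : dy + h, dx : dx + wd] += gc3[:, k]
            if need_x:
                gx = gpad[:, 1:-1, 1:-1, 1:-1]
            if need_w:
                gw = gwmat.reshape(w.shape)
        if b is not None and b.requires_grad:
            gb = g.sum(axis=(1, 2, 3))
        return (gx, gw) if b is None else (gx, gw, gb)

    return Tensor._make(out, parents, backward)


def conv3d_k1(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """1x1x1 convolution (pure channel mixing). ``w``: (Cout, Cin)."""
    cin, d, h, wd = x.shape
    cout = w.shape[0]
    nvox = d * h * wd
    x2d = x.data.reshape(cin, nvox)
    out = (w.data @ x2d).reshape(cout, d, h, wd)
    if b is not None:
        out += b.data[:, None, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g2d = g.reshape(cout, nvox)
        gx = (w.data.T @ g2d).reshape(x.shape) if x.requires_grad else None
        gw = g2d @ x2d.T if w.requires_grad else None
        gb = g2d.sum(axis=1) if (b is not None and b.requires_grad) else None
        return (gx, gw) if b is None else (gx, gw, gb)

    return Tensor._make(out, parents, backward)


def _blockify(a: np.ndarray):
    """(C, D, H, W) -> (D/2*H/2*W/2, C*8) gathering 2x2x2 blocks."""
    c, d, h, w = a.shape
    v = a.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
    v = v.transpose(1, 3, 5, 0, 2, 4, 6)  # (d2, h2, w2, C, 2, 2, 2)
    return np.ascontiguousarray(v).reshape((d // 2) * (h // 2) * (w // 2), c * 8)


def _unblockify(m: np.ndarray, c: int, shape):
    d, h, w = shape
    v = m.reshape(d // 2, h // 2, w // 2, c, 2, 2, 2)
    v = v.transpose(3, 0, 4, 1, 5, 2, 6)
    return np.ascontiguousarray(v).reshape(c, d, h, w)


def conv3d_down2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2x2x2 convolution with stride 2 (downsampling). ``w``: (Cout, Cin, 2, 2, 2)."""
    cin, d, h, wd = x.shape
    cout = w.shape[0]
    if d % 2 or h % 2 or wd % 2:
        raise ValueError(f"spatial shape {x.shape[1:]} not divisible by 2")
    cols = _blockify(x.data)  # (Nout, Cin*8)
    wmat = w.data.reshape(cout, cin * 8)
    out2d = cols @ wmat.T  # (Nout, Cout)
    out = out2d.T.reshape(cout, d // 2, h // 2, wd // 2)
    if b is not None:
        out = out + b.data[:, None, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g2d = g.reshape(cout, -1).T  # (Nout, Cout)
        gx = gw = gb = None
        if x.requires_grad:
            gcols = g2d @ wmat  # (Nout, Cin*8)
            gx = _unblockify(gcols, cin, (d, h, wd))
        if w.requires_grad:
            gw = (g2d.T @ cols).reshape(w.shape)
        if b is not None and b.requires_grad:
            gb = g2d.sum(axis=0)
        return (gx, gw) if b is None else (gx, gw, gb)

    return Tensor._make(out, parents, backward)


def conv_transpose3d_up2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2x2x2 transposed convolution with stride 2 (upsampling).

    ``w``: (Cin, Cout, 2, 2, 2); output spatial shape doubles per axis.
    """
    cin, d, h, wd = x.shape
    cout = w.shape[1]
    x2d = x.data.reshape(cin, -1).T  # (Nin, Cin)
    wmat = w.data.reshape(cin, cout * 8)
    out_blocks = x2d @ wmat  # (Nin, Cout*8)
    out = _unblockify(out_blocks, cout, (2 * d, 2 * h, 2 * wd))
    if b is not None:
        out = out + b.data[:, None, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gcols = _blockify(g)  # (Nin, Cout*8)
        gx = gw = gb = None
        if x.requires_grad:
            gx = (gcols @ wmat.T).T.reshape(x.shape)
        if w.requires_grad:
            gw = (x2d.T @ gcols).reshape(w.shape)
        if b is not None and b.requires_grad:
            gb = g.sum(axis=(1, 2, 3))
        return (gx, gw) if b is None else (gx, gw, gb)

    return Tensor._make(out, parents, backward)


def instance_norm(
    x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5
) -> Tensor:
    """Per-channel normalization over the spatial axes with affine parameters.

    ``gamma``/``beta``: (C,). With the engine's implicit batch of one this is
    also the batch-norm training-mode computation; running statistics for
    evaluation mode live in the layer object.
    """
    c = x.shape[0]
    n = x.data[0].size
    ax = (1, 2, 3)
    mu = x.data.mean(axis=ax, keepdims=True)
    var = x.data.var(axis=ax, keepdims=True)
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * ivar
    out = gamma.data[:, None, None, None] * xhat + beta.data[:, None, None, None]

    def backward(g):
        gxh = g * gamma.data[:, None, None, None]
        gx = None
        if x.requires_grad:
            s1 = gxh.sum(axis=ax, keepdims=True)
            s2 = (gxh * xhat).sum(axis=ax, keepdims=True)
            gx = (ivar / n) * (n * gxh - s1 - xhat * s2)
        ggamma = (g * xhat).sum(axis=ax) if gamma.requires_grad else None
        gbeta = g.sum(axis=ax) if beta.requires_grad else None
        return (gx, ggamma, gbeta)

    return Tensor._make(out, (x, gamma, beta), backward)
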