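"""Minimal reverse-mode automatic differentiation core for image networks.

Tensors wrap NumPy arrays in NHWC layout (batch, height, width, channel),
which keeps the channel dimension contiguous so a 3x3 convolution lowers to
nine window copies and BLAS matmuls, one per kernel tap, accumulated into
the output. ``no_grad()`` disables tape construction for inference, and
``buffer_reuse()`` recycles batch-sized scratch between training steps,
which matters more than FLOPs when allocation is expensive.

The engine is deliberately small: only the operations needed by a residual
U-Net and its training objective are provided, each with a hand-written
adjoint that is checked against finite differences in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np
from scipy.linalg.blas import dgemm, sgemm

_grad_enabled = True
_GEMM = {np.dtype(np.float32): sgemm, np.dtype(np.float64): dgemm}


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph construction (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    """A NumPy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Reverse-mode sweep from a scalar output."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # small operator sugar for composing losses
    def __add__(self, other: "Tensor") -> "Tensor":
        return add(self, other)

    def __mul__(self, scalar: float) -> "Tensor":
        return scale(self, scalar)

    __rmul__ = __mul__


def _make(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward(out)
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    """Accumulate an exclusively owned gradient array into t.grad.

    Callers must pass arrays that no live node aliases (fresh allocations,
    or views of an already-consumed upstream gradient).
    """
    if t.grad is None:
        t.grad = g if g.dtype == t.data.dtype else g.astype(t.data.dtype)
    else:
        t.grad += g


# ---------------------------------------------------------------------------
# scratch-buffer pool
#
# Allocating batch-sized arrays is the dominant cost of a training step on
# machines where freed pages are returned to the OS (first-touch page faults
# outweigh BLAS time), so inside ``buffer_reuse()`` every large forward
# output, padded copy and gradient is drawn from a slot pool keyed by
# (role, shape, dtype). Checkout indices grow monotonically within a step,
# so two same-shaped tensors alive at once always get distinct slots;
# ``reset_slots()`` is called by the training/inference loops at points
# where every previously produced graph is garbage, after which the same
# sequence of checkouts reuses the same buffers. Outside the context every
# op allocates fresh arrays and nothing is shared.

_reuse = False
_slots: dict[tuple, list[np.ndarray]] = {}
_slot_idx: dict[tuple, int] = {}


@contextlib.contextmanager
def buffer_reuse():
    """Enable slot-pooled allocations for a fixed-structure loop."""
    global _reuse
    prev = _reuse
    _reuse = True
    try:
        yield
    finally:
        _reuse = prev


def reset_slots() -> None:
    """Mark a step boundary: all previously checked-out slots may be reused.

    Only call when no tensor from an earlier step will be read again.
    """
    for k in _slot_idx:
        _slot_idx[k] = 0


def clear_buffers() -> None:
    """Release all pooled scratch buffers."""
    _slots.clear()
    _slot_idx.clear()


def _out(role: str, shape: tuple, dtype) -> np.ndarray:
    if not _reuse:
        return np.empty(shape, dtype=dtype)
    key = (role, shape, np.dtype(dtype).str)
    i = _slot_idx.get(key, 0)
    _slot_idx[key] = i + 1
    lst = _slots.setdefault(key, [])
    if i < len(lst):
        return lst[i]
    a = np.empty(shape, dtype=dtype)
    lst.append(a)
    return a


# ---------------------------------------------------------------------------
# convolution (NHWC)


def _reflect_pad(x: np.ndarray, out: np.ndarray | None = None) -> np.ndarray:
    """Pad H and W by one pixel with reflection, row-contiguous fast path."""
    B, H, W, C = x.shape
    if out is None:
        out = np.empty((B, H + 2, W + 2, C), dtype=x.dtype)
    out[:, 1:-1, 1:-1] = x
    out[:, 0, 1:-1] = x[:, 1]
    out[:, -1, 1:-1] = x[:, -2]
    out[:, :, 0] = out[:, :, 2]
    out[:, :, -1] = out[:, :, -3]
    return out


def _reflect_pad_adjoint(dxp: np.ndarray, out: np.ndarray | None = None) -> np.ndarray:
    # adjoint of the reflect padding above: fold borders into the interior
    # (mutates dxp, which is transient scratch)
    dxp[:, :, 2] += dxp[:, :, 0]
    dxp[:, :, -3] += dxp[:, :, -1]
    if out is None:
        dx = dxp[:, 1:-1, 1:-1].copy()
    else:
        np.copyto(out, dxp[:, 1:-1, 1:-1])
        dx = out
    dx[:, 1] += dxp[:, 0, 1:-1]
    dx[:, -2] += dxp[:, -1, 1:-1]
    return dx


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-size 2-D convolution (k in {1, 3}); 3x3 uses reflect padding.

    ``w`` has shape (C_out, C_in, k, k), ``b`` shape (C_out,); ``x`` is NHWC.
    """
    B, H, W, C = x.data.shape
    Cout, Cin, k, _ = w.data.shape
    if Cin != C:
        raise ValueError(f"channel mismatch: input {C}, kernel {Cin}")
    if k not in (1, 3):
        raise NotImplementedError("kernel sizes 1 and 3 only")

    dt = x.data.dtype
    if k == 1:
        wmat = w.data.reshape(Cout, C).T.copy()  # (C, Cout)
        out_data = _out("conv1.out", (B, H, W, Cout), dt)
        out_flat = out_data.reshape(-1, Cout)
        np.matmul(x.data.reshape(-1, C), wmat, out=out_flat)
        out_flat += b.data

        def backward(out: Tensor):
            def _bw():
                dy = out.grad
                dyf = dy.reshape(-1, Cout)
                if b.requires_grad:
                    _accum(b, dy.sum(axis=(0, 1, 2)))
                if w.requires_grad:
                    _accum(w, (dyf.T @ x.data.reshape(-1, C)).reshape(w.data.shape))
                if x.requires_grad:
                    dx = _out("conv1.dx", (B, H, W, C), dt)
                    np.matmul(dyf, wmat.T, out=dx.reshape(-1, C))
                    _accum(x, dx)

            return _bw

        return _make(out_data, (x, w, b), backward)

    # per-tap lowering: for each of the nine kernel taps, one contiguous
    # window copy and one GEMM accumulated into the output; keeps every
    # array contiguous and peak scratch at one input-sized buffer
    pshape = (B, H + 2, W + 2, C)
    xp = _reflect_pad(x.data, out=_out("conv.xp", pshape, dt))
    taps = [w.data[:, :, i, j].T.copy() for i in range(3) for j in range(3)]  # (C, Cout)
    out_data = _out("conv.out", (B, H, W, Cout), dt)
    out_data[:] = b.data
    out_flat = out_data.reshape(-1, Cout)
    part = _out("conv.part", (B, H, W, C), dt)
    partf = part.reshape(-1, C)
    gemm = _GEMM.get(dt)
    tmp = None if gemm is not None else _out("conv.tmp", (B * H * W, Cout), dt)
    for i in range(3):
        for j in range(3):
            part[:] = xp[:, i : i + H, j : j + W, :]
            if gemm is not None:
                # accumulate via BLAS beta=1 on the transposed (F-order) views
                gemm(1.0, taps[3 * i + j].T, partf.T, beta=1.0, c=out_flat.T, overwrite_c=1)
            else:
                np.matmul(partf, taps[3 * i + j], out=tmp)
                out_flat += tmp

    def backward(out: Tensor):
        def _bw():
            dy = out.grad
            dyf = np.ascontiguousarray(dy).reshape(-1, Cout)
            if b.requires_grad:
                _accum(b, dyf.sum(axis=0))
            dw = np.empty_like(w.data) if w.requires_grad else None
            dxp = None
            dpart = None
            part = _out("conv.part", (B, H, W, C), dt)
            partf = part.reshape(-1, C)
            if x.requires_grad:
                dxp = _out("conv.dxp", pshape, dt)
                dxp.fill(0)
                dpart = _out("conv.dpart", (B * H * W, C), dt)
            for i in range(3):
                for j in range(3):
                    if dw is not None:
                        part[:] = xp[:, i : i + H, j : j + W, :]
                        dw[:, :, i, j] = dyf.T @ partf
                    if dxp is not None:
                        np.matmul(dyf, taps[3 * i + j].T, out=dpart)
                        dxp[:, i : i + H, j : j + W, :] += dpart.reshape(B, H, W, C)
            if dw is not None:
                _accum(w, dw)
            if dxp is not None:
                dx = _reflect_pad_adjoint(dxp, out=_out("conv.dx", (B, H, W, C), dt))
                _accum(x, dx)

        return _bw

    return _make(out_data, (x, w, b), backward)


# ---------------------------------------------------------------------------
# pointwise and structural ops


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    if not 0.0 <= slope <= 1.0:
        raise ValueError("leaky slope must lie in [0, 1]")
    shape, dt = x.data.shape, x.data.dtype
    y = _out("lrelu.out", shape, dt)
    np.multiply(x.data, slope, out=y)
    np.maximum(x.data, y, out=y)  # max(x, slope*x) == leaky ReLU for slope <= 1

    def backward(out: Tensor):
        def _bw():
            neg = _out("lrelu.mask", shape, bool)
            np.less(x.data, 0, out=neg)
            g = _out("lrelu.g", shape, dt)
            np.copyto(g, out.grad)
            np.multiply(g, dt.type(slope), out=g, where=neg)
            _accum(x, g)

        return _bw

    return _make(y, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    y = _out("tanh.out", x.data.shape, x.data.dtype)
    np.tanh(x.data, out=y)

    def backward(out: Tensor):
        def _bw():
            g = _out("tanh.g", y.shape, y.dtype)
            np.multiply(y, y, out=g)
            np.subtract(1.0, g, out=g)
            np.multiply(g, out.grad, out=g)
            _accum(x, g)

        return _bw

    return _make(y, (x,), backward)


def max_pool2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; spatial dims must be even."""
    B, H, W, C = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("max_pool2 needs even spatial dimensions")
    dt = x.data.dtype
    h2, w2 = H // 2, W // 2
    flat = _out("pool.flat", (B, h2, w2, 4, C), dt)
    np.copyto(
        flat.reshape(B, h2, w2, 2, 2, C),
        x.data.reshape(B, h2, 2, w2, 2, C).transpose(0, 1, 3, 2, 4, 5),
    )
    idx = _out("pool.idx", (B, h2, w2, C), np.intp)
    np.argmax(flat, axis=3, out=idx)
    y = _out("pool.out", (B, h2, w2, C), dt)
    np.max(flat, axis=3, out=y)

    def backward(out: Tensor):
        def _bw():
            dflat = _out("pool.dflat", (B, h2, w2, 4, C), dt)
            dflat.fill(0)
            np.put_along_axis(dflat, idx[:, :, :, None, :], out.grad[:, :, :, None, :], axis=3)
            dx = _out("pool.dx", (B, H, W, C), dt)
            np.copyto(
                dx.reshape(B, h2, 2, w2, 2, C),
                dflat.reshape(B, h2, w2, 2, 2, C).transpose(0, 1, 3, 2, 4, 5),
            )
            _accum(x, dx)

        return _bw

    return _make(y, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    B, H, W, C = x.data.shape
    y = _out("up.out", (B, 2 * H, 2 * W, C), x.data.dtype)
    y.reshape(B, H, 2, W, 2, C)[:] = x.data[:, :, None, :, None, :]

    def backward(out: Tensor):
        def _bw():
            dx = _out("up.dx", (B, H, W, C), x.data.dtype)
            np.sum(out.grad.reshape(B, H, 2, W, 2, C), axis=(2, 4), out=dx)
            _accum(x, dx)

        return _bw

    return _make(y, (x,), backward)


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Channel concatenation."""
    ca = a.data.shape[-1]
    shape = a.data.shape[:-1] + (ca + b.data.shape[-1],)
    y = _out("cat.out", shape, a.data.dtype)
    y[..., :ca] = a.data
    y[..., ca:] = b.data

    def backward(out: Tensor):
        def _bw():
            # disjoint views of out.grad; safe to hand off, the concat node
            # is dead once its backward has run
            if a.requires_grad:
                _accum(a, out.grad[..., :ca])
            if b.requires_grad:
                _accum(b, out.grad[..., ca:])

        return _bw

    return _make(y, (a, b), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    y = a.data + b.data

    def backward(out: Tensor):
        def _bw():
            if a.requires_grad and b.requires_grad:
                _accum(a, out.grad)
                _accum(b, out.grad.copy())
            elif a.requires_grad:
                _accum(a, out.grad)
            elif b.requires_grad:
                _accum(b, out.grad)

        return _bw

    return _make(y, (a, b), backward)


def scale(x: Tensor, c: float) -> Tensor:
    y = x.data * c

    def backward(out: Tensor):
        def _bw():
            _accum(x, out.grad * c)

        return _bw

    return _make(y, (x,), backward)


def spatial_dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Channel-wise (spatial) dropout with inverted scaling, always sampling."""
    B, _, _, C = x.data.shape
    keep = (rng.random((B, 1, 1, C)) >= p).astype(x.data.dtype) / (1.0 - p)
    y = _out("drop.out", x.data.shape, x.data.dtype)
    np.multiply(x.data, keep, out=y)

    def backward(out: Tensor):
        def _bw():
            g = _out("drop.g", x.data.shape, x.data.dtype)
            np.multiply(out.grad, keep, out=g)
            _accum(x, g)

        return _bw

    return _make(y, (x,), backward)


# ---------------------------------------------------------------------------
# loss primitives


def l1(a: Tensor, b: Tensor) -> Tensor:
    """Mean absolute difference; subgradient 0 at exact ties."""
    d = a.data - b.data
    y = np.array(np.mean(np.abs(d)), dtype=a.data.dtype)

    def backward(out: Tensor):
        def _bw():
            g = np.sign(d) * (out.grad / d.size)
            if a.requires_grad:
                _accum(a, g)
            if b.requires_grad:
                _accum(b, -g)

        return _bw

    return _make(y, (a, b), backward)


def _spatial_axes(ndim: int) -> tuple[int, int]:
    if ndim == 2:
        return 0, 1
    if ndim == 4:  # NHWC
        return 1, 2
    raise ValueError("grad_mag expects a 2-D image or an NHWC batch")


def grad_mag(x: Tensor) -> Tensor:
    """Per-pixel gradient magnitude sqrt(gx^2 + gy^2).

    Forward differences with replicate boundary: the last column has zero
    horizontal gradient and the last row zero vertical gradient.
    """
    ay, ax = _spatial_axes(x.data.ndim)

    def sl(axis, s):
        idx = [slice(None)] * x.data.ndim
        idx[axis] = s
        return tuple(idx)

    gx = np.zeros_like(x.data)
    gy = np.zeros_like(x.data)
    gx[sl(ax, slice(None, -1))] = x.data[sl(ax, slice(1, None))] - x.data[
        sl(ax, slice(None, -1))
    ]
    gy[sl(ay, slice(None, -1))] = x.data[sl(ay, slice(1, None))] - x.data[
        sl(ay, slice(None, -1))
    ]
    gm = np.sqrt(gx * gx + gy * gy)

    def backward(out: Tensor):
        def _bw():
            inv = np.where(gm > 0, 1.0 / np.where(gm > 0, gm, 1.0), 0.0)
            dgx = out.grad * gx * inv
            dgy = out.grad * gy * inv
            dx = np.zeros_like(x.data)
            dx[sl(ax, slice(1, None))] += dgx[sl(ax, slice(None, -1))]
            dx[sl(ax, slice(None, -1))] -= dgx[sl(ax, slice(None, -1))]
            dx[sl(ay, slice(1, None))] += dgy[sl(ay, slice(None, -1))]
            dx[sl(ay, slice(None, -1))] -= dgy[sl(ay, slice(None, -1))]
            _accum(x, dx)

        return _bw

    return _make(gm, (x,), backward)


# ---------------------------------------------------------------------------
# parameter container


class Module:
    """Base class holding named parameters in registration order."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}

    def register(self, name: str, data: np.ndarray) -> Tensor:
        t = Tensor(data, requires_grad=True)
        self._params[name] = t
        return t

    def parameters(self) -> list[Tensor]:
        return list(self._params.values())

    def named_parameters(self) -> dict[str, Tensor]:
        return dict(self._params)

    def zero_grad(self) -> None:
        for p in self._params.values():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self._params.values()]

    def load_state_arrays(self, arrays: Iterable[np.ndarray]) -> None:
        arrays = list(arrays)
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch when loading weights")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch when loading weights")
            p.data = a.astype(p.data.dtype, copy=True)
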