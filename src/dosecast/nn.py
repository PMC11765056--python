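"""Minimal reverse-mode autodiff over numpy for 3D convolutional networks.

Implements exactly the operations the cascaded U-Net needs — 3x3x3 (optionally
strided) convolution, instance normalization, ReLU, 2x2x2 max-pooling,
trilinear x2 up-sampling and channel concatenation — each with a hand-derived
vector-Jacobian product.  Volumes are ``(C, D, H, W)`` float32 arrays without
a batch axis (the training batch size is 1).

Convolutions are evaluated as 27 shifted GEMMs against a zero-padded input:
for each kernel offset the padded volume is sliced, flattened to ``(Cin, N)``
and multiplied by the ``(Cout, Cin)`` weight slab.  This keeps peak memory at
one ``(Cin, N)`` copy instead of a full im2col buffer while still doing all
arithmetic inside BLAS.

Gradient flow: build the graph by calling the ops on :class:`Tensor` objects,
then call :func:`backward` with one or more ``(tensor, seed_gradient)`` pairs
(the cascade has two loss heads, so two seeds).
"""

from __future__ import annotations

from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np

__all__ = [
    "Tensor",
    "backward",
    "conv3d",
    "instance_norm",
    "relu",
    "maxpool2",
    "upsample2",
    "concat",
]


class Tensor:
    """A node in the computation graph: value, gradient slot, parent edges."""

    __slots__ = ("data", "grad", "parents", "name")

    def __init__(self, data: np.ndarray, parents: Sequence[Tuple["Tensor", Callable]] = (),
                 name: str = ""):
        self.data = data
        self.grad = None
        self.parents = tuple(parents)
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)


def backward(seeds: Sequence[Tuple[Tensor, np.ndarray]]) -> None:
    """Reverse-mode sweep from one or more seeded output tensors.

    Accumulates ``.grad`` on every tensor reachable through parent edges.
    Gradients of previous sweeps are overwritten.
    """
    # topological order over the union of the seeds' histories
    topo: List[Tensor] = []
    seen = set()
    stack = [t for t, _ in seeds]
    while stack:
        node = stack[-1]
        if id(node) in seen:
            stack.pop()
            continue
        unvisited = [p for p, _ in node.parents if id(p) not in seen]
        if unvisited:
            stack.extend(unvisited)
            continue
        seen.add(id(node))
        topo.append(stack.pop())

    for node in topo:
        node.grad = None
    for t, g in seeds:
        g = np.asarray(g, dtype=t.data.dtype)
        t.grad = g.copy() if t.grad is None else t.grad + g
    for node in reversed(topo):
        if node.grad is None:
            continue
        for parent, vjp in node.parents:
            g = vjp(node.grad)
            if parent.grad is None:
                parent.grad = g
            else:
                parent.grad = parent.grad + g


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _conv_offsets(kernel: int):
    r = range(kernel)
    return [(dz, dy, dx) for dz in r for dy in r for dx in r]


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(Cin * k^3, N_out) patch matrix of a 'same'-padded volume."""
    cin, D, H, W = x.shape
    pad = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
    od, oh, ow = D // stride, H // stride, W // stride
    n = od * oh * ow
    col = np.empty((cin, k ** 3, n), dtype=x.dtype)
    for i, (dz, dy, dx) in enumerate(_conv_offsets(k)):
        col[:, i, :] = xp[:, dz:dz + D:stride, dy:dy + H:stride, dx:dx + W:stride] \
            .reshape(cin, n)
    return col.reshape(cin * k ** 3, n)


#: Above this patch-matrix size the convolution runs in z-slabs instead of
#: materializing one im2col buffer (keeps 128^3 inference within memory).
_COL_BYTES_LIMIT = 256 * 2 ** 20


def _gemm_conv_slabbed(x: np.ndarray, w: np.ndarray, b: np.ndarray | None):
    cin, D, H, W = x.shape
    cout, _, k, _, _ = w.shape
    pad = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
    wf = w.reshape(cout, -1)
    out = np.empty((cout, D, H, W), dtype=x.dtype)
    slab = max(1, _COL_BYTES_LIMIT // (cin * k ** 3 * H * W * x.dtype.itemsize))
    for z0 in range(0, D, slab):
        z1 = min(z0 + slab, D)
        xs = xp[:, z0:z1 + k - 1]
        out[:, z0:z1] = (wf @ _im2col_nopad(xs, k)).reshape(cout, z1 - z0, H, W)
    if b is not None:
        out += b[:, None, None, None]
    return out


def _im2col_nopad(xp: np.ndarray, k: int) -> np.ndarray:
    """im2col of an already-padded volume (valid in z, same in y/x)."""
    cin, Dp, H, W = xp.shape
    D = Dp - (k - 1)
    n = D * (H - (k - 1)) * (W - (k - 1))
    col = np.empty((cin, k ** 3, n), dtype=xp.dtype)
    for i, (dz, dy, dx) in enumerate(_conv_offsets(k)):
        col[:, i, :] = xp[:, dz:dz + D, dy:dy + H - (k - 1), dx:dx + W - (k - 1)] \
            .reshape(cin, n)
    return col.reshape(cin * k ** 3, n)


def _gemm_conv(x: np.ndarray, w: np.ndarray, b: np.ndarray | None, stride: int):
    """Returns (out, col); ``col`` (kept for the weight gradient) is ``None``
    when the slab path was taken."""
    cin, D, H, W = x.shape
    cout, _, k, _, _ = w.shape
    if k == 1 and stride == 1:
        col = x.reshape(cin, -1)
    elif stride == 1 and cin * k ** 3 * x[0].size * x.dtype.itemsize > _COL_BYTES_LIMIT:
        return _gemm_conv_slabbed(x, w, b), None
    else:
        col = _im2col(x, k, stride)
    out = w.reshape(cout, -1) @ col
    if b is not None:
        out += b[:, None]
    od = D // stride
    return out.reshape(cout, od, H // stride, W // stride), col


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1) -> Tensor:
    """3D convolution, odd kernel, 'same' padding; stride 1 or 2.

    ``w`` has shape ``(Cout, Cin, k, k, k)``; ``b`` shape ``(Cout,)``.
    The input gradient of the stride-1 case is itself a convolution of the
    output gradient with the spatially flipped, channel-transposed kernel,
    so forward and both gradients run as single GEMMs.
    """
    cin, D, H, W = x.data.shape
    cout, _, k, _, _ = w.data.shape
    out_data, col = _gemm_conv(x.data, w.data, None if b is None else b.data, stride)
    st = stride
    pad = (k - 1) // 2

    def vjp_x(g: np.ndarray) -> np.ndarray:
        if st == 1:
            wt = w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            gx, _ = _gemm_conv(np.ascontiguousarray(g),
                               np.ascontiguousarray(wt), None, 1)
            return gx
        # stride 2 occurs once per sub-model, at the smallest spatial level:
        # scatter the 27 shifted contributions explicitly.
        gf = g.reshape(cout, -1)
        gxp = np.zeros((cin, D + 2 * pad, H + 2 * pad, W + 2 * pad), dtype=g.dtype)
        od, oh, ow = g.shape[1:]
        for dz, dy, dx in _conv_offsets(k):
            contrib = (w.data[:, :, dz, dy, dx].T @ gf).reshape(cin, od, oh, ow)
            gxp[:, dz:dz + D:st, dy:dy + H:st, dx:dx + W:st] += contrib
        return gxp[:, pad:pad + D, pad:pad + H, pad:pad + W]

    def vjp_w(g: np.ndarray) -> np.ndarray:
        c = col if col is not None else _im2col(x.data, k, st)
        return (g.reshape(cout, -1) @ c.T).reshape(w.data.shape)

    parents = [(x, vjp_x), (w, vjp_w)]
    if b is not None:
        parents.append((b, lambda g: g.reshape(cout, -1).sum(axis=1)))
    return Tensor(out_data, parents)


# ---------------------------------------------------------------------------
# normalization / activation / pooling / resampling
# ---------------------------------------------------------------------------

_IN_EPS = 1e-5


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor) -> Tensor:
    """Per-channel normalization over the spatial axes of one instance."""
    xd = x.data
    c = xd.shape[0]
    n = xd[0].size
    mean = xd.reshape(c, -1).mean(axis=1).reshape(c, 1, 1, 1)
    var = xd.reshape(c, -1).var(axis=1).reshape(c, 1, 1, 1)
    inv = 1.0 / np.sqrt(var + _IN_EPS)
    xhat = (xd - mean) * inv
    g4 = gamma.data.reshape(c, 1, 1, 1)
    out = xhat * g4 + beta.data.reshape(c, 1, 1, 1)

    def vjp_x(g: np.ndarray) -> np.ndarray:
        dxhat = g * g4
        s1 = dxhat.reshape(c, -1).sum(axis=1).reshape(c, 1, 1, 1)
        s2 = (dxhat * xhat).reshape(c, -1).sum(axis=1).reshape(c, 1, 1, 1)
        return inv * (dxhat - s1 / n - xhat * s2 / n)

    return Tensor(out, [
        (x, vjp_x),
        (gamma, lambda g: (g * xhat).reshape(c, -1).sum(axis=1)),
        (beta, lambda g: g.reshape(c, -1).sum(axis=1)),
    ])


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(np.where(mask, x.data, 0), [(x, lambda g: np.where(mask, g, 0))])


def maxpool2(x: Tensor) -> Tensor:
    """2x2x2 max pooling, stride 2; ties send the gradient to one voxel."""
    c, D, H, W = x.data.shape
    xr = x.data.reshape(c, D // 2, 2, H // 2, 2, W // 2, 2)
    xr = np.ascontiguousarray(xr.transpose(0, 1, 3, 5, 2, 4, 6)).reshape(
        c, D // 2, H // 2, W // 2, 8)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def vjp(g: np.ndarray) -> np.ndarray:
        gr = np.zeros((c, D // 2, H // 2, W // 2, 8), dtype=g.dtype)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(c, D // 2, H // 2, W // 2, 2, 2, 2).transpose(0, 1, 4, 2, 5, 3, 6)
        return np.ascontiguousarray(gr).reshape(c, D, H, W)

    return Tensor(out, [(x, vjp)])


_INTERP_CACHE: Dict[Tuple[int, type], np.ndarray] = {}


def _interp_matrix(n: int, dtype) -> np.ndarray:
    """Dense (2n, n) linear-interpolation matrix for an exact x2 up-sampling.

    Output coordinate ``o`` samples source position ``(o + 0.5)/2 - 0.5``
    (half-pixel-centered), clamped at the edges.
    """
    key = (n, np.dtype(dtype).type)
    if key not in _INTERP_CACHE:
        m = np.zeros((2 * n, n), dtype=dtype)
        for o in range(2 * n):
            src = (o + 0.5) / 2.0 - 0.5
            src = min(max(src, 0.0), n - 1.0)
            i0 = int(np.floor(src))
            f = src - i0
            m[o, i0] += 1.0 - f
            if f > 0:
                m[o, i0 + 1] += f
        _INTERP_CACHE[key] = m
    return _INTERP_CACHE[key]


def _apply_axis(x: np.ndarray, m: np.ndarray, axis: int) -> np.ndarray:
    return np.moveaxis(np.tensordot(m, x, axes=(1, axis)), 0, axis)


def upsample2(x: Tensor) -> Tensor:
    """Trilinear x2 up-sampling of the three spatial axes."""
    c, D, H, W = x.data.shape
    ms = [_interp_matrix(n, x.data.dtype) for n in (D, H, W)]
    y = x.data
    for axis, m in zip((1, 2, 3), ms):
        y = _apply_axis(y, m, axis)
    y = np.ascontiguousarray(y)

    def vjp(g: np.ndarray) -> np.ndarray:
        for axis, m in zip((1, 2, 3), ms):
            g = _apply_axis(g, m.T, axis)
        return np.ascontiguousarray(g)

    return Tensor(y, [(x, vjp)])


def concat(tensors: Sequence[Tensor]) -> Tensor:
    """Concatenate along the channel axis."""
    sizes = [t.data.shape[0] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=0)
    parents = []
    start = 0
    for t, c in zip(tensors, sizes):
        lo, hi = start, start + c

        def vjp(g: np.ndarray, lo=lo, hi=hi) -> np.ndarray:
            return g[lo:hi]

        parents.append((t, vjp))
        start = hi
    return Tensor(out, parents)
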