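"""Neural-network operations composed from (or added to) the autodiff core."""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .tensor import Tensor, as_tensor, pad

__all__ = [
    "softmax",
    "conv2d",
    "conv3d",
    "avg_pool2d",
    "max_pool2d",
    "layer_norm",
    "instance_norm",
    "bilinear_gather",
    "bilinear_sample_plan",
    "GatherPlan",
    "make_gather_plan",
    "upsample_plan",
    "resize_bilinear",
    "sinusoidal_positions_2d",
]


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    t = as_tensor(t)
    shifted = t - Tensor(t.data.max(axis=axis, keepdims=True))  # detached max
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def _conv_shift_add(x: Tensor, w: Tensor, b: Tensor | None, nd: int) -> Tensor:
    """`same` convolution in nd spatial dims, one GEMM per kernel tap.

    x: (Cin, *spatial); w: (Cout, Cin, *kernel); odd kernel sizes only.
    Single graph node with a hand-written backward.  Each tap multiplies the
    *unsliced* input (no per-tap copy of the large tensor) and adds the
    result into a shifted output window; the backward pass pads the output
    gradient once and slices that smaller tensor instead.
    """
    x, w = as_tensor(x), as_tensor(w)
    cin = x.shape[0]
    cout = w.shape[0]
    if w.shape[1] != cin:
        raise ValueError(f"channel mismatch: input {cin}, kernel expects {w.shape[1]}")
    spatial = x.shape[1:]
    kernel = w.shape[2:]
    center = tuple(k // 2 for k in kernel)
    nspat = int(np.prod(spatial))
    xflat = np.ascontiguousarray(x.data).reshape(cin, nspat)
    taps = list(np.ndindex(*kernel))
    n_taps = len(taps)
    # one fat GEMM for all taps (skinny per-tap GEMMs waste BLAS throughput),
    # then fold the per-tap slabs into shifted output windows
    w_all = np.ascontiguousarray(
        w.data.reshape(cout, cin, n_taps).transpose(2, 0, 1)
    ).reshape(n_taps * cout, cin)
    y_all = (w_all @ xflat).reshape((n_taps, cout) + spatial)
    out_data = np.zeros((cout,) + spatial, dtype=x.data.dtype)
    for ti, tap in enumerate(taps):
        off = tuple(t - c for t, c in zip(tap, center))
        dst = (slice(None),) + tuple(
            slice(max(0, -o), s - max(0, o)) for o, s in zip(off, spatial)
        )
        src = (slice(None),) + tuple(
            slice(max(0, o), s - max(0, -o)) for o, s in zip(off, spatial)
        )
        out_data[dst] += y_all[ti][src]
    del y_all
    if b is not None:
        b = as_tensor(b)
        out_data += b.data.reshape((cout,) + (1,) * nd)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _parents=parents)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accum(g.reshape(cout, nspat).sum(axis=1))
        need_w = w.requires_grad
        need_x = x.requires_grad
        if not (need_w or need_x):
            return
        gpad = np.pad(g, [(0, 0)] + [(c, c) for c in center])
        # stack all shifted output-gradient slabs so both parameter and input
        # gradients reduce to a single large GEMM each
        n_taps = len(taps)
        gs_all = np.empty((n_taps * cout, nspat), dtype=g.dtype)
        for ti, tap in enumerate(taps):
            off = tuple(t - c for t, c in zip(tap, center))
            # gs[q] = gout[q - off] (zero outside)
            sl = (slice(None),) + tuple(
                slice(c - o, c - o + s) for c, o, s in zip(center, off, spatial)
            )
            gs_all[ti * cout : (ti + 1) * cout].reshape((cout,) + spatial)[...] = gpad[sl]
        if need_w:
            gw = (gs_all @ xflat.T).reshape((n_taps, cout, cin)).transpose(1, 2, 0)
            w._accum(np.ascontiguousarray(gw).reshape(w.data.shape))
        if need_x:
            w_all = np.ascontiguousarray(
                w.data.reshape(cout, cin, n_taps).transpose(2, 0, 1)
            ).reshape(n_taps * cout, cin)
            x._accum((w_all.T @ gs_all).reshape(x.data.shape))

    out._backward = backward
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    return _conv_shift_add(x, w, b, nd=2)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    return _conv_shift_add(x, w, b, nd=3)


def _pool_reshape(t: Tensor, stride):
    sy, sx = (stride, stride) if np.isscalar(stride) else stride
    c, h, w = t.shape
    if h % sy or w % sx:
        raise ValueError(f"spatial dims {(h, w)} not divisible by pooling stride {(sy, sx)}")
    return t.reshape(c, h // sy, sy, w // sx, sx)


def avg_pool2d(t: Tensor, stride) -> Tensor:
    if stride == 1:
        return as_tensor(t)
    return _pool_reshape(as_tensor(t), stride).mean(axis=(2, 4))


def max_pool2d(t: Tensor, stride) -> Tensor:
    if stride == 1:
        return as_tensor(t)
    return _pool_reshape(as_tensor(t), stride).max(axis=2).max(axis=3)


def layer_norm(t: Tensor, gain: Tensor, bias: Tensor, axis: int = -1, eps: float = 1e-5) -> Tensor:
    mu = t.mean(axis=axis, keepdims=True)
    centred = t - mu
    var = (centred**2).mean(axis=axis, keepdims=True)
    return centred / (var + eps) ** 0.5 * gain + bias


def instance_norm(t: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalization over all spatial axes of a (C, *spatial) tensor.

    Fused single graph node: the composed form would allocate half a dozen
    full-size intermediates, which dominates memory traffic on 3D volumes.
    """
    t, gain, bias = as_tensor(t), as_tensor(gain), as_tensor(bias)
    axes = tuple(range(1, t.ndim))
    cshape = (t.shape[0],) + (1,) * (t.ndim - 1)
    x = t.data
    mu = x.mean(axis=axes, keepdims=True)
    var = x.var(axis=axes, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv_std
    g = gain.data.reshape(cshape)
    out = Tensor(xhat * g + bias.data.reshape(cshape), _parents=(t, gain, bias))

    def backward(grad):
        if bias.requires_grad:
            bias._accum(grad.sum(axis=axes))
        if gain.requires_grad:
            gain._accum((grad * xhat).sum(axis=axes))
        if t.requires_grad:
            dxhat = grad * g
            m1 = dxhat.mean(axis=axes, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
            t._accum((dxhat - m1 - xhat * m2) * inv_std)

    out._backward = backward
    return out


def bilinear_sample_plan(xs: np.ndarray, ys: np.ndarray, width: int, height: int):
    """Precompute flat indices + weights for bilinear sampling at (xs, ys).

    Points are continuous pixel coordinates (0-based, centers at integers);
    samples outside [0, w-1] x [0, h-1] get zero weight (zero padding).
    Returns (idx, wts), each of shape (4, n), consumable by bilinear_gather.
    """
    xs = np.asarray(xs, dtype=np.float64).ravel()
    ys = np.asarray(ys, dtype=np.float64).ravel()
    x0 = np.floor(xs)
    y0 = np.floor(ys)
    fx = xs - x0
    fy = ys - y0
    idx = np.empty((4, xs.size), dtype=np.int64)
    wts = np.empty((4, xs.size), dtype=np.float64)
    corners = ((0, 0), (1, 0), (0, 1), (1, 1))
    for k, (dx, dy) in enumerate(corners):
        cx = x0 + dx
        cy = y0 + dy
        inb = (cx >= 0) & (cx < width) & (cy >= 0) & (cy < height)
        wx = fx if dx else 1.0 - fx
        wy = fy if dy else 1.0 - fy
        wts[k] = np.where(inb, wx * wy, 0.0)
        idx[k] = np.where(inb, cy * width + cx, 0).astype(np.int64)
    return idx, wts


class GatherPlan:
    """Sparse linear map for bilinear sampling: out = feat_flat @ S.

    ``S`` has shape (in_size, n) with <= 4 nonzeros per column (the bilinear
    corner weights); ``ST`` is its transpose, both CSR for fast products.
    """

    __slots__ = ("_mats", "in_size", "n")

    def __init__(self, idx: np.ndarray, wts: np.ndarray, in_size: int):
        n = idx.shape[1]
        cols = np.tile(np.arange(n), 4)
        mat = sparse.coo_matrix(
            (wts.ravel().astype(np.float64), (idx.ravel(), cols)), shape=(in_size, n)
        )
        self._mats = {np.dtype(np.float64): (mat.tocsr(), mat.T.tocsr())}
        self.in_size = in_size
        self.n = n

    def matrices(self, dtype):
        """(S, S^T) in the requested dtype (cached casts)."""
        dtype = np.dtype(dtype)
        if dtype not in self._mats:
            s64, st64 = self._mats[np.dtype(np.float64)]
            self._mats[dtype] = (s64.astype(dtype), st64.astype(dtype))
        return self._mats[dtype]


def make_gather_plan(idx: np.ndarray, wts: np.ndarray, in_size: int) -> GatherPlan:
    return GatherPlan(idx, wts, in_size)


def bilinear_gather(feat: Tensor, plan, wts: np.ndarray | None = None) -> Tensor:
    """Sample (C, H*W)-flattened features with a precomputed bilinear plan.

    ``plan`` is a :class:`GatherPlan` (or a raw (4, n) index array together
    with ``wts``, in which case a plan is built on the fly).  feat: (C, H, W)
    or (C, H*W); returns (C, n).  Single graph node; the backward pass routes
    gradients through the transposed sparse map.
    """
    feat = as_tensor(feat)
    c = feat.shape[0]
    flat = feat.data.reshape(c, -1)
    if not isinstance(plan, GatherPlan):
        plan = GatherPlan(np.asarray(plan), np.asarray(wts), flat.shape[1])
    S, ST = plan.matrices(flat.dtype if flat.dtype.kind == "f" else np.float64)
    out_data = (ST @ flat.T).T  # (C, n)
    out = Tensor(np.ascontiguousarray(out_data), _parents=(feat,))

    def backward(g):
        if not feat.requires_grad:
            return
        gf = (S @ g.T).T
        feat._accum(np.ascontiguousarray(gf).reshape(feat.data.shape).astype(flat.dtype, copy=False))

    out._backward = backward
    return out


def upsample_plan(out_h: int, out_w: int, in_h: int, in_w: int):
    """Bilinear resize plan mapping an (in_h, in_w) map onto an (out_h, out_w) map.

    Uses the align_corners=False convention: output pixel centers are mapped
    through the scale of the two extents, with edge clamping.
    """
    sy = in_h / out_h
    sx = in_w / out_w
    yy, xx = np.meshgrid(np.arange(out_h), np.arange(out_w), indexing="ij")
    ys = np.clip((yy + 0.5) * sy - 0.5, 0, in_h - 1)
    xs = np.clip((xx + 0.5) * sx - 0.5, 0, in_w - 1)
    return bilinear_sample_plan(xs, ys, in_w, in_h)


_RESIZE_PLANS: dict[tuple[int, int, int, int], GatherPlan] = {}


def resize_bilinear(feat: Tensor, out_h: int, out_w: int) -> Tensor:
    feat = as_tensor(feat)
    c, in_h, in_w = feat.shape
    key = (out_h, out_w, in_h, in_w)
    plan = _RESIZE_PLANS.get(key)
    if plan is None:
        idx, wts = upsample_plan(out_h, out_w, in_h, in_w)
        plan = _RESIZE_PLANS[key] = GatherPlan(idx, wts, in_h * in_w)
        if len(_RESIZE_PLANS) > 64:
            _RESIZE_PLANS.pop(next(iter(_RESIZE_PLANS)))
    return bilinear_gather(feat, plan).reshape(c, out_h, out_w)


def sinusoidal_positions_2d(d: int, h: int, w: int, dtype=np.float32) -> np.ndarray:
    """Fixed 2D sinusoidal positional encodings, shape (d, h, w)."""
    if d % 4:
        raise ValueError("encoding dim must be divisible by 4")
    q = d // 4
    freqs = 1.0 / (10000.0 ** (np.arange(q) / max(q, 1)))
    ys = np.arange(h)[:, None] * freqs[None, :]  # (h, q)
    xs = np.arange(w)[:, None] * freqs[None, :]
    pe = np.zeros((d, h, w), dtype=dtype)
    pe[0:q] = np.sin(ys).T[:, :, None]
    pe[q : 2 * q] = np.cos(ys).T[:, :, None]
    pe[2 * q : 3 * q] = np.sin(xs).T[:, None, :]
    pe[3 * q :] = np.cos(xs).T[:, None, :]
    return pe
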