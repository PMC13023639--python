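"""Differentiable array operations used by the segmentation modules.

Everything here takes and returns :class:`~octseg.grad.tensor.Tensor`;
spatial tensors follow the (N, C, H, W) layout.
"""

from __future__ import annotations

import numpy as np

from .tensor import DTYPE, Tensor, as_tensor, concat, stack  # noqa: F401 (re-export)


# ---------------------------------------------------------------------------
# padding

def _pad_index(n: int, before: int, after: int, mode: str) -> np.ndarray:
    """Source index for every position of a 1-D pad (reflect/replicate)."""
    idx = np.arange(n)
    np_mode = {"replicate": "edge", "reflect": "reflect"}[mode]
    return np.pad(idx, (before, after), mode=np_mode)


def pad2d(x: Tensor, pad: int | tuple, mode: str = "zeros", value: float = 0.0) -> Tensor:
    """Pad the last two axes.  ``pad`` is an int or (top, bottom, left, right)."""
    if isinstance(pad, int):
        pt = pb = pl = pr = pad
    else:
        pt, pb, pl, pr = pad
    if pt == pb == pl == pr == 0:
        return x
    H, W = x.shape[-2:]
    if mode in ("zeros", "constant"):
        widths = [(0, 0)] * (x.ndim - 2) + [(pt, pb), (pl, pr)]
        out_data = np.pad(x.data, widths, mode="constant", constant_values=value)

        def backward(g):
            sl = (Ellipsis, slice(pt, pt + H), slice(pl, pl + W))
            x._accumulate(g[sl])

        return Tensor._make(out_data, (x,), backward)

    ih = _pad_index(H, pt, pb, mode)
    iw = _pad_index(W, pl, pr, mode)
    out_data = x.data[..., ih[:, None], iw[None, :]]

    def backward(g):
        buf = np.zeros_like(x.data)
        np.add.at(buf, (Ellipsis, ih[:, None], iw[None, :]), g)
        x._accumulate(buf)

    return Tensor._make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# convolution

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, pad_mode: str = "zeros") -> Tensor:
    """2-D cross-correlation of (N,C,H,W) with kernel (O,C,kh,kw)."""
    if x.ndim != 4 or w.ndim != 4:
        raise ValueError("conv2d expects (N,C,H,W) input and (O,C,kh,kw) kernel")
    if x.shape[1] != w.shape[1]:
        raise ValueError(f"channel mismatch: input {x.shape[1]} vs kernel {w.shape[1]}")
    if padding:
        x = pad2d(x, padding, mode=pad_mode)
    N, C, Hp, Wp = x.shape
    O, _, kh, kw = w.shape
    s = stride
    Hout = (Hp - kh) // s + 1
    Wout = (Wp - kw) // s + 1
    if Hout < 1 or Wout < 1:
        raise ValueError("conv2d output would be empty")

    xd, wd = x.data, w.data
    out = np.zeros((N, O, Hout, Wout), dtype=DTYPE)
    for i in range(kh):
        for j in range(kw):
            xs = xd[:, :, i:i + s * Hout:s, j:j + s * Wout:s]
            out += np.tensordot(xs, wd[:, :, i, j], axes=([1], [1])).transpose(0, 3, 1, 2)
    if b is not None:
        out += b.data.reshape(1, O, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(xd)
            for i in range(kh):
                for j in range(kw):
                    gi = np.tensordot(g, wd[:, :, i, j], axes=([1], [0])).transpose(0, 3, 1, 2)
                    gx[:, :, i:i + s * Hout:s, j:j + s * Wout:s] += gi
            x._accumulate(gx)
        if w.requires_grad:
            gw = np.zeros_like(wd)
            for i in range(kh):
                for j in range(kw):
                    xs = xd[:, :, i:i + s * Hout:s, j:j + s * Wout:s]
                    gw[:, :, i, j] = np.tensordot(g, xs, axes=([0, 2, 3], [0, 2, 3]))
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor._make(out, parents, backward)


def circular_conv_theta(x: Tensor, w: Tensor) -> Tensor:
    """Depthwise 1-D convolution along axis 2 with circular wrap.

    ``x`` is (N, C, T, R) — T the periodic (angular) axis — and ``w`` is a
    per-channel kernel (C, L), L odd.
    """
    N, C, T, R = x.shape
    Cw, L = w.shape
    if Cw != C:
        raise ValueError("kernel channel count must match input")
    if L % 2 == 0:
        raise ValueError("kernel length must be odd")
    h = L // 2
    xd, wd = x.data, w.data
    out = np.zeros_like(xd)
    for j in range(L):
        out += np.roll(xd, -(j - h), axis=2) * wd[None, :, j, None, None]

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(xd)
            for j in range(L):
                gx += np.roll(g * wd[None, :, j, None, None], j - h, axis=2)
            x._accumulate(gx)
        if w.requires_grad:
            gw = np.zeros_like(wd)
            for j in range(L):
                gw[:, j] = (g * np.roll(xd, -(j - h), axis=2)).sum(axis=(0, 2, 3))
            w._accumulate(gw)

    return Tensor._make(out, (x, w), backward)


# ---------------------------------------------------------------------------
# bilinear sampling

def bilinear_sample(x: Tensor, gx, gy, grid_grad: bool = False) -> Tensor:
    """Sample (N,C,H,W) at real-valued pixel coords with border clamping.

    ``gx``/``gy`` hold x (column) and y (row) coordinates, either shared
    across the batch with shape (Hout, Wout) or per-item (N, Hout, Wout);
    they may be numpy arrays or Tensors.  With ``grid_grad`` the output is
    also differentiable w.r.t. the coordinates (needed for learned offsets).
    """
    gx_t = gx if isinstance(gx, Tensor) else None
    gy_t = gy if isinstance(gy, Tensor) else None
    gxd = np.asarray(gx.data if gx_t is not None else gx, dtype=DTYPE)
    gyd = np.asarray(gy.data if gy_t is not None else gy, dtype=DTYPE)
    N, C, H, W = x.shape
    if gxd.ndim == 2:
        gxd = np.broadcast_to(gxd, (N,) + gxd.shape)
        gyd = np.broadcast_to(gyd, (N,) + gyd.shape)
    out_sp = gxd.shape[1:]

    in_x = (gxd > 0) & (gxd < W - 1)
    in_y = (gyd > 0) & (gyd < H - 1)
    cx = np.clip(gxd, 0, W - 1)
    cy = np.clip(gyd, 0, H - 1)
    x0 = np.floor(cx).astype(np.intp)
    y0 = np.floor(cy).astype(np.intp)
    x0 = np.minimum(x0, W - 2) if W > 1 else x0
    y0 = np.minimum(y0, H - 2) if H > 1 else y0
    x1 = np.minimum(x0 + 1, W - 1)
    y1 = np.minimum(y0 + 1, H - 1)
    fx = (cx - x0).astype(DTYPE)
    fy = (cy - y0).astype(DTYPE)

    xb = np.ascontiguousarray(x.data.transpose(0, 2, 3, 1))  # N,H,W,C
    nidx = np.arange(N)[:, None, None]
    v00 = xb[nidx, y0, x0]  # N,Hout,Wout,C
    v01 = xb[nidx, y0, x1]
    v10 = xb[nidx, y1, x0]
    v11 = xb[nidx, y1, x1]
    w00 = ((1 - fy) * (1 - fx))[..., None]
    w01 = ((1 - fy) * fx)[..., None]
    w10 = (fy * (1 - fx))[..., None]
    w11 = (fy * fx)[..., None]
    out = (v00 * w00 + v01 * w01 + v10 * w10 + v11 * w11).transpose(0, 3, 1, 2)

    parents = [x]
    if grid_grad and gx_t is not None:
        parents.append(gx_t)
    if grid_grad and gy_t is not None:
        parents.append(gy_t)

    def backward(g):
        gb = g.transpose(0, 2, 3, 1)  # N,Hout,Wout,C
        if x.requires_grad:
            buf = np.zeros_like(xb)
            np.add.at(buf, (nidx, y0, x0), gb * w00)
            np.add.at(buf, (nidx, y0, x1), gb * w01)
            np.add.at(buf, (nidx, y1, x0), gb * w10)
            np.add.at(buf, (nidx, y1, x1), gb * w11)
            x._accumulate(buf.transpose(0, 3, 1, 2))
        if grid_grad and (gx_t is not None and gx_t.requires_grad):
            dx = ((1 - fy)[..., None] * (v01 - v00) + fy[..., None] * (v11 - v10))
            gg = (gb * dx).sum(axis=-1) * in_x
            if gx_t.data.ndim == 2:
                gg = gg.sum(axis=0)
            gx_t._accumulate(gg)
        if grid_grad and (gy_t is not None and gy_t.requires_grad):
            dy = ((1 - fx)[..., None] * (v10 - v00) + fx[..., None] * (v11 - v01))
            gg = (gb * dy).sum(axis=-1) * in_y
            if gy_t.data.ndim == 2:
                gg = gg.sum(axis=0)
            gy_t._accumulate(gg)

    out_t = Tensor._make(out.astype(DTYPE), tuple(parents), backward)
    assert out_t.shape == (N, C) + out_sp
    return out_t


def upsample_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Resize (N,C,H,W) to (N,C,Hout,Wout); half-pixel-center convention."""
    H, W = x.shape[-2:]
    Hout, Wout = size
    if (Hout, Wout) == (H, W):
        return x
    ys = (np.arange(Hout, dtype=DTYPE) + 0.5) * (H / Hout) - 0.5
    xs = (np.arange(Wout, dtype=DTYPE) + 0.5) * (W / Wout) - 0.5
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    return bilinear_sample(x, gx, gy)


# ---------------------------------------------------------------------------
# pooling / softmax

def maxpool2d(x: Tensor, kernel: int = 3, stride: int = 1, padding: int = 0,
              pad_value: float = -np.inf) -> Tensor:
    """Max pooling; ``pad_value`` 0 turns it into greyscale dilation with a
    zero background (the soft-morphology building block)."""
    if padding:
        widths = [(0, 0)] * (x.ndim - 2) + [(padding, padding)] * 2
        xp = np.pad(x.data, widths, mode="constant", constant_values=pad_value)
    else:
        xp = x.data
    N, C, Hp, Wp = xp.shape
    s = stride
    Hout = (Hp - kernel) // s + 1
    Wout = (Wp - kernel) // s + 1
    out = np.full((N, C, Hout, Wout), -np.inf, dtype=DTYPE)
    for i in range(kernel):
        for j in range(kernel):
            np.maximum(out, xp[:, :, i:i + s * Hout:s, j:j + s * Wout:s], out=out)

    def backward(g):
        buf = np.zeros_like(xp)
        claimed = np.zeros(out.shape, dtype=bool)
        for i in range(kernel):
            for j in range(kernel):
                xs = xp[:, :, i:i + s * Hout:s, j:j + s * Wout:s]
                hit = (xs == out) & ~claimed
                claimed |= hit
                buf[:, :, i:i + s * Hout:s, j:j + s * Wout:s] += np.where(hit, g, 0.0)
        if padding:
            buf = buf[:, :, padding:padding + x.shape[2], padding:padding + x.shape[3]]
        x._accumulate(buf)

    return Tensor._make(out, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = (x - Tensor(m)).exp()
    return e / e.sum(axis=axis, keepdims=True)
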