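"""Deformable cross-scale fusion (D-CFM).

Multi-scale features of a curved vessel are misaligned after naive
upsampling; this module predicts per-pixel, per-tap sampling offsets
from the concatenated scales and applies a from-scratch deformable
convolution (bilinear gather at the displaced tap locations), gated by a
Sobel edge map so fusion concentrates on wall boundaries.

Offset layout: the offset field has 2*K channels for a K-tap kernel,
ordered tap-major as (dx_0, dy_0, dx_1, dy_1, ...) with taps enumerated
row-major over the kernel window.  Offsets are in pixels of the
low-level feature grid.
"""

from __future__ import annotations

import numpy as np

from .grad import Conv2d, Module, Tensor, functional as F
from .grad.tensor import DTYPE

SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
SOBEL_Y = SOBEL_X.T


def deformable_conv(f_l: Tensor, offsets: Tensor, kernel: Tensor,
                    bias: Tensor | None = None) -> Tensor:
    """Deformable 2-D convolution with one offset group.

    For output location p and tap p_k the input is sampled at
    ``p + p_k + dp(p, p_k)`` by bilinear interpolation with border
    replication, multiplied by the tap weight and summed over taps and
    input channels.  Differentiable w.r.t. input, offsets and kernel.
    """
    N, C, H, W = f_l.shape
    O, Ck, kh, kw = kernel.shape
    if Ck != C:
        raise ValueError("kernel input channels must match feature channels")
    K = kh * kw
    if offsets.shape != (N, 2 * K, H, W):
        raise ValueError(f"offsets must be (N,{2 * K},H,W), got {tuple(offsets.shape)}")

    yy, xx = np.mgrid[0:H, 0:W].astype(DTYPE)
    out = None
    for k in range(K):
        di, dj = divmod(k, kw)
        base_dy, base_dx = di - kh // 2, dj - kw // 2
        gx = offsets[:, 2 * k] + Tensor(xx + base_dx)
        gy = offsets[:, 2 * k + 1] + Tensor(yy + base_dy)
        sampled = F.bilinear_sample(f_l, gx, gy, grid_grad=True)  # (N,C,H,W)
        w_k = kernel[:, :, di, dj]  # (O, C)
        term = (sampled.reshape(N, 1, C, H, W) * w_k.reshape(1, O, C, 1, 1)).sum(axis=2)
        out = term if out is None else out + term
    if bias is not None:
        out = out + bias.reshape(1, O, 1, 1)
    return out


class OffsetPredictor(Module):
    """3x3 conv over Concat(Upsample(f_m), f_l) -> 2K offset channels.

    Zero-initialized (weights and bias), so training starts from the
    standard-convolution sampling grid.
    """

    def __init__(self, ch_m: int, ch_l: int, rng: np.random.Generator, kernel: int = 3):
        self.kernel = kernel
        self.conv = Conv2d(ch_m + ch_l, 2 * kernel * kernel, 3, rng,
                           padding=1, zero_init=True)

    def forward(self, f_m: Tensor, f_l: Tensor) -> Tensor:
        Hm, Wm = f_m.shape[-2:]
        Hl, Wl = f_l.shape[-2:]
        if Hl % Hm or Wl % Wm:
            raise ValueError(f"low-level size {(Hl, Wl)} is not an integer multiple "
                             f"of mid-level size {(Hm, Wm)}")
        up = F.upsample_bilinear(f_m, (Hl, Wl))
        return self.conv(F.concat([up, f_l], axis=1))


def predict_offsets(f_m: Tensor, f_l: Tensor, predictor: OffsetPredictor) -> Tensor:
    return predictor(f_m, f_l)


class SobelEdgeGate(Module):
    """sigma(Conv1x1(|Sobel(channel-mean f)|)) -> single-channel gate in (0,1)."""

    def __init__(self, rng: np.random.Generator):
        self.conv = Conv2d(1, 1, 1, rng)
        self.conv.weight.data = np.ones_like(self.conv.weight.data)

    def forward(self, f_l: Tensor) -> Tensor:
        mean = f_l.mean(axis=1, keepdims=True)  # (N,1,H,W)
        kx = Tensor(SOBEL_X[None, None])
        ky = Tensor(SOBEL_Y[None, None])
        padded = F.pad2d(mean, 1, mode="reflect")
        sx = F.conv2d(padded, kx)
        sy = F.conv2d(padded, ky)
        mag = (sx * sx + sy * sy + 1e-12).sqrt()
        return self.conv(mag).sigmoid()


def sobel_edge_gate(f_l: Tensor, gate: SobelEdgeGate | None = None,
                    rng: np.random.Generator | None = None) -> Tensor:
    if gate is None:
        gate = SobelEdgeGate(rng or np.random.default_rng(0))
    return gate(f_l)


class DeformableFusion(Module):
    """g * DConv(f_l, dp) + Proj(Upsample(f_m)) residual fusion.

    With ``gate=False`` the Sobel gate is dropped (the plain fusion path
    used by the module-ablation variant).
    """

    def __init__(self, ch_l: int, ch_m: int, ch_out: int, rng: np.random.Generator,
                 kernel: int = 3, gate: bool = True):
        self.offset_pred = OffsetPredictor(ch_m, ch_l, rng, kernel=kernel)
        self.dconv = Conv2d(ch_l, ch_out, kernel, rng, padding=0)  # weights only
        self.proj = Conv2d(ch_m, ch_out, 1, rng)
        self.edge_gate = SobelEdgeGate(rng) if gate else None
        self.kernel = kernel

    def forward(self, f_l: Tensor, f_m: Tensor) -> Tensor:
        offsets = self.offset_pred(f_m, f_l)
        f_def = deformable_conv(f_l, offsets, self.dconv.weight, self.dconv.bias)
        if self.edge_gate is not None:
            f_def = f_def * self.edge_gate(f_l)
        up = F.upsample_bilinear(f_m, tuple(f_l.shape[-2:]))
        return f_def + self.proj(up)


def dcfm_forward(f_l: Tensor, f_m: Tensor, module: DeformableFusion) -> Tensor:
    return module(f_l, f_m)
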