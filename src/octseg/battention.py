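"""Boundary-aware windowed attention (BAM).

A Laplacian-of-Gaussian edge map highlights candidate boundary pixels;
inside non-overlapping 7x7 windows, self-attention uses queries computed
from the edge-masked features (keys/values from the raw features), so
boundary pixels steer the aggregation.  The binary edge map is treated
as a constant during backpropagation (the indicator is
non-differentiable).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .grad import Linear, Module, Tensor, functional as F
from .grad.tensor import DTYPE


def log_edge_map(f, sigma: float = 1.0, tau_mode: str = "quantile",
                 tau_value: float = 0.9) -> np.ndarray:
    """Binary edge map: |LoG_sigma(channel-mean f)| above a threshold.

    ``tau_mode='quantile'`` thresholds at the ``tau_value`` quantile of
    the per-map absolute response (adapts to feature scale);
    ``tau_mode='fixed'`` uses ``tau_value`` directly.  Computed with
    reflect padding on the forward values only; constant maps give an
    empty (all-zero) edge map.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if tau_mode not in ("quantile", "fixed"):
        raise ValueError(f"unknown tau_mode {tau_mode!r}")
    x = f.numpy() if isinstance(f, Tensor) else np.asarray(f, dtype=np.float64)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[:, None]
    mean = x.mean(axis=1)  # (N, H, W)
    out = np.empty_like(mean, dtype=np.uint8)
    for i, img in enumerate(mean):
        resp = np.abs(ndimage.gaussian_laplace(img.astype(np.float64), sigma,
                                               mode="reflect"))
        tau = np.quantile(resp, tau_value) if tau_mode == "quantile" else tau_value
        out[i] = resp > tau
    return out[0] if squeeze else out[:, None]


# ---------------------------------------------------------------------------
# window bookkeeping

def window_partition(x: Tensor, window: int) -> tuple[Tensor, tuple]:
    """(N,C,H,W) -> (N*nh*nw, window*window, C) tokens.

    The map is replicate-padded up to a multiple of the window size;
    the returned meta tuple drives the exact inverse."""
    if window < 1:
        raise ValueError("window must be >= 1")
    N, C, H, W = x.shape
    ph = (-H) % window
    pw = (-W) % window
    if ph or pw:
        x = F.pad2d(x, (0, ph, 0, pw), mode="replicate")
    Hp, Wp = H + ph, W + pw
    nh, nw = Hp // window, Wp // window
    t = x.reshape(N, C, nh, window, nw, window)
    t = t.transpose(0, 2, 4, 3, 5, 1)  # N, nh, nw, ws, ws, C
    tokens = t.reshape(N * nh * nw, window * window, C)
    return tokens, (N, C, H, W, nh, nw, window)


def window_unpartition(tokens: Tensor, meta: tuple) -> Tensor:
    N, C, H, W, nh, nw, window = meta
    t = tokens.reshape(N, nh, nw, window, window, C)
    t = t.transpose(0, 5, 1, 3, 2, 4)  # N, C, nh, ws, nw, ws
    x = t.reshape(N, C, nh * window, nw * window)
    return x[:, :, :H, :W]


@dataclasses.dataclass
class WindowAttentionParams:
    window: int = 7
    heads: int = 1
    sigma: float = 1.0
    tau_mode: str = "quantile"
    tau_value: float = 0.9

    def validate(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.heads < 1:
            raise ValueError("heads must be >= 1")


class BoundaryWindowAttention(Module):
    """Edge-modulated attention inside non-overlapping windows.

    Queries are projected from the edge-masked features E*f; keys and
    values from f itself.  Softmax(Q K^T / sqrt(d)) V, residual added to
    the input, output projection zero-initialized so the block starts as
    the identity.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 params: WindowAttentionParams | None = None):
        self.p = params or WindowAttentionParams()
        self.p.validate()
        if channels % self.p.heads:
            raise ValueError("channels must divide evenly into heads")
        self.wq = Linear(channels, channels, rng)
        self.wk = Linear(channels, channels, rng)
        self.wv = Linear(channels, channels, rng)
        self.proj = Linear(channels, channels, rng, zero_init=True)
        self.channels = channels

    def attention(self, f: Tensor, edge: np.ndarray):
        ws, h = self.p.window, self.p.heads
        N, C, H, W = f.shape
        e = np.broadcast_to(np.asarray(edge, dtype=DTYPE).reshape(N, -1, H, W), f.shape)
        tokens, meta = window_partition(f, ws)
        etokens, _ = window_partition(f * Tensor(np.ascontiguousarray(e)), ws)
        B, T, _ = tokens.shape
        d = C // h

        def split_heads(t):
            return t.reshape(B, T, h, d).transpose(0, 2, 1, 3)  # B,h,T,d

        q = split_heads(self.wq(etokens))
        k = split_heads(self.wk(tokens))
        v = split_heads(self.wv(tokens))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d))
        attn = F.softmax(scores, axis=-1)  # B,h,T,T
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, C)
        out = window_unpartition(self.proj(ctx), meta)
        return f + out, attn

    def forward(self, f: Tensor, edge: np.ndarray) -> Tensor:
        return self.attention(f, edge)[0]


def edge_windowed_attention(f: Tensor, edge: np.ndarray,
                            module: BoundaryWindowAttention) -> Tensor:
    if tuple(np.asarray(edge).shape[-2:]) != tuple(f.shape[-2:]):
        raise ValueError("edge map and features are not spatially aligned")
    return module(f, edge)


class BoundaryAttentionModule(Module):
    """LoG edge extraction + edge-modulated windowed attention."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 params: WindowAttentionParams | None = None):
        self.p = params or WindowAttentionParams()
        self.attn = BoundaryWindowAttention(channels, rng, self.p)

    def forward(self, f: Tensor) -> Tensor:
        edge = log_edge_map(f, sigma=self.p.sigma, tau_mode=self.p.tau_mode,
                            tau_value=self.p.tau_value)
        return self.attn(f, edge)


def bam_forward(f: Tensor, module: BoundaryAttentionModule) -> Tensor:
    return module(f)
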