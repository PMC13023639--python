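"""Radial Intensity Module: polar resampling and angular processing.

Vessel cross-sections are concentric: a dark lumen inside bright wall
layers.  Resampling features onto a (theta, r) grid centered on the
lumen turns those rings into horizontal bands, so a cheap depthwise
convolution along the periodic angular axis models annular structure
directly.  A DCT-frequency channel attention then gates channels by the
spectral signature of their angular profile (speckle is broadband;
anatomy concentrates in low frequencies).

Conventions: pixel-center coordinates, origin top-left, y down; the
normalized radius is ``r = 2*sqrt((x-cx)^2+(y-cy)^2)/(D-1)`` and the
normalized angle ``theta = atan2(y-cy, x-cx)/pi`` in (-1, 1], measured
from +x toward +y.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .grad import Linear, Module, Parameter, Tensor, functional as F
from .grad.tensor import DTYPE


@dataclasses.dataclass
class PolarGrid:
    """Precomputed Cartesian sampling locations of a (theta, r) raster."""

    n_theta: int
    n_r: int
    center: tuple[float, float]  # (cx, cy)
    diameter: float
    source_shape: tuple[int, int]  # (H, W)
    theta: np.ndarray  # (n_theta,) normalized angles in (-1, 1]
    r: np.ndarray  # (n_r,) normalized radii in [0, 1]
    sample_x: np.ndarray  # (n_theta, n_r)
    sample_y: np.ndarray


def build_polar_grid(height: int, width: int, center: tuple[float, float] | None = None,
                     n_theta: int = 720, n_r: int | None = None,
                     diameter: float | None = None) -> PolarGrid:
    """Uniform polar sampling grid over the inscribed disk.

    The Cartesian sample point of bin (theta, r) is
    ``(cx + r*cos(pi*theta)*(D-1)/2, cy + r*sin(pi*theta)*(D-1)/2)``.
    720 angular bins give 0.5 degree increments (0.25/1/5 degree
    sensitivity settings are reachable through ``n_theta``).
    """
    if n_theta < 1 or (n_r is not None and n_r < 1):
        raise ValueError("n_theta and n_r must be >= 1")
    if center is None:
        center = ((width - 1) / 2.0, (height - 1) / 2.0)
    cx, cy = center
    if not (0 <= cx <= width - 1 and 0 <= cy <= height - 1):
        raise ValueError(f"center {center} outside the {height}x{width} image")
    if diameter is None:
        diameter = float(min(height, width))
    if diameter < 2:
        raise ValueError("diameter must be >= 2")
    if n_r is None:
        n_r = max(min(height, width) // 2, 1)

    theta = -1.0 + 2.0 * (np.arange(n_theta) + 1) / n_theta  # (-1, 1]
    r = np.linspace(0.0, 1.0, n_r) if n_r > 1 else np.zeros(1)
    half = (diameter - 1) / 2.0
    ang = np.pi * theta
    sample_x = cx + r[None, :] * np.cos(ang)[:, None] * half
    sample_y = cy + r[None, :] * np.sin(ang)[:, None] * half
    return PolarGrid(n_theta=n_theta, n_r=n_r, center=(cx, cy), diameter=diameter,
                     source_shape=(height, width), theta=theta, r=r,
                     sample_x=sample_x.astype(DTYPE), sample_y=sample_y.astype(DTYPE))


def point_to_polar(x: float, y: float, center: tuple[float, float],
                   diameter: float) -> tuple[float, float]:
    """Normalized (r, theta) address of a Cartesian point."""
    cx, cy = center
    r = 2.0 * np.hypot(x - cx, y - cy) / (diameter - 1)
    theta = np.arctan2(y - cy, x - cx) / np.pi
    return float(r), float(theta)


def cartesian_to_polar(f: Tensor, grid: PolarGrid) -> Tensor:
    """Resample (N,C,H,W) features onto the polar grid (bilinear, border)."""
    if tuple(f.shape[-2:]) != grid.source_shape:
        raise ValueError(f"feature spatial shape {tuple(f.shape[-2:])} does not match "
                         f"grid source shape {grid.source_shape}")
    return F.bilinear_sample(f, grid.sample_x, grid.sample_y)


def polar_to_cartesian(fp: Tensor, grid: PolarGrid, out_shape: tuple[int, int] | None = None,
                       fallback: Tensor | None = None) -> Tensor:
    """Inverse resampling: every Cartesian pixel inside the disk reads its
    (r, theta) address from the polar map (theta interpolated circularly);
    pixels outside the disk come from ``fallback`` (default zeros)."""
    if tuple(fp.shape[-2:]) != (grid.n_theta, grid.n_r):
        raise ValueError("polar map does not match grid")
    if out_shape is None:
        out_shape = grid.source_shape
    H, W = out_shape
    if H < 1 or W < 1:
        raise ValueError("out_shape must be at least 1x1")
    cx, cy = grid.center
    half = (grid.diameter - 1) / 2.0
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    rad = np.hypot(xx - cx, yy - cy) / half  # normalized r
    theta = np.arctan2(yy - cy, xx - cx) / np.pi

    # fractional bin addresses; theta_i = -1 + 2(i+1)/n  =>  i = (theta+1)*n/2 - 1
    ti = ((theta + 1.0) * grid.n_theta / 2.0 - 1.0) % grid.n_theta
    ri = rad * (grid.n_r - 1) if grid.n_r > 1 else np.zeros_like(rad)

    # circular wrap: append the first angular row so ti in [n-1, n] blends seam rows
    fp_ext = F.concat([fp, fp[:, :, :1, :]], axis=2)
    sampled = F.bilinear_sample(fp_ext, ri.astype(DTYPE), ti.astype(DTYPE))

    inside = Tensor((rad <= 1.0).astype(DTYPE))
    out = sampled * inside
    if fallback is not None:
        out = out + fallback * (1.0 - inside)
    return out


# ---------------------------------------------------------------------------
# DCT channel attention

def dct_matrix(n: int, k: int) -> np.ndarray:
    """First ``k`` rows of the orthonormal DCT-II matrix of size n."""
    t = np.arange(n)
    freqs = np.arange(k)
    mat = np.cos(np.pi * (2 * t[None, :] + 1) * freqs[:, None] / (2 * n))
    mat[0] *= np.sqrt(1.0 / n)
    mat[1:] *= np.sqrt(2.0 / n)
    return mat  # (k, n)


@dataclasses.dataclass
class RIMParams:
    kernel_theta: int = 7
    dct_k: int = 16
    bottleneck: int = 4

    def validate(self) -> None:
        if self.kernel_theta % 2 == 0:
            raise ValueError("kernel_theta must be odd")
        if self.bottleneck < 1:
            raise ValueError("bottleneck must be >= 1")


class DCTAttention(Module):
    """Channel gate from the low-frequency DCT spectrum of the
    radially-averaged angular profile."""

    def __init__(self, params: RIMParams, rng: np.random.Generator):
        params.validate()
        self.k = params.dct_k
        hidden = max(1, params.dct_k // params.bottleneck)
        self.fc1 = Linear(params.dct_k, hidden, rng)
        self.fc2 = Linear(hidden, 1, rng, zero_init=True)
        self._dct_cache: dict[int, np.ndarray] = {}

    def forward(self, fp: Tensor) -> Tensor:
        """fp: (N, C, T, R) polar features -> per-channel weights (N, C)."""
        n_theta = fp.shape[2]
        if self.k > n_theta:
            raise ValueError(f"retained DCT frequencies ({self.k}) exceed angular "
                             f"bins ({n_theta})")
        profile = fp.mean(axis=3)  # (N, C, T)
        if n_theta not in self._dct_cache:
            self._dct_cache[n_theta] = dct_matrix(n_theta, self.k).T.astype(DTYPE)
        coeffs = profile @ Tensor(self._dct_cache[n_theta])  # (N, C, k)
        h = self.fc1(coeffs).relu()
        return self.fc2(h).sigmoid().reshape(fp.shape[0], fp.shape[1])


def dct_attention(fp: Tensor, params: RIMParams, rng: np.random.Generator | None = None,
                  module: DCTAttention | None = None) -> Tensor:
    """Functional form; builds a fresh (zero-output-layer) module unless given."""
    if module is None:
        module = DCTAttention(params, rng or np.random.default_rng(0))
    return module(fp)


# ---------------------------------------------------------------------------
# center estimation

def dark_centroid(image: np.ndarray) -> tuple[float, float]:
    """Intensity-weighted centroid of the darkest intensity decile —
    a mask-free lumen-center estimate (lumens are dark)."""
    img = np.asarray(image, dtype=np.float64)
    thr = np.percentile(img, 10)
    w = np.where(img <= thr, thr - img + 1e-9, 0.0)
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    total = w.sum()
    return (float((w * xx).sum() / total), float((w * yy).sum() / total))


# ---------------------------------------------------------------------------
# the module

class RadialIntensityModule(Module):
    """f + inverse(omega * DepthwiseConv_theta(polar(f))) residual block.

    ``center_mode`` selects the polar origin: the geometric image center
    (catheter-centered acquisition prior), a dark-centroid estimate, or a
    fixed caller-supplied point.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 n_theta: int = 720, n_r: int | None = None,
                 params: RIMParams | None = None, center_mode: str = "image_center",
                 kernel_init: str = "delta"):
        if center_mode not in ("image_center", "dark_centroid", "fixed"):
            raise ValueError(f"unknown center_mode {center_mode!r}")
        self.params = params or RIMParams()
        self.params.validate()
        self.n_theta = n_theta
        self.n_r = n_r
        self.center_mode = center_mode
        self.use_attention = True
        L = self.params.kernel_theta
        if kernel_init == "delta":
            w = np.zeros((channels, L), dtype=DTYPE)
            w[:, L // 2] = 1.0
            w += rng.normal(0, 0.02, size=w.shape).astype(DTYPE)
        else:
            w = rng.normal(0, 1.0 / np.sqrt(L), size=(channels, L)).astype(DTYPE)
        self.w_theta = Parameter(w)
        self.attention = DCTAttention(self.params, rng)
        self._grid_cache: dict = {}

    def set_identity(self) -> None:
        """Exact delta kernel and attention forced to 1 (diagnostics)."""
        w = np.zeros_like(self.w_theta.data)
        w[:, w.shape[1] // 2] = 1.0
        self.w_theta.data = w
        self.use_attention = False

    def grid_for(self, height: int, width: int,
                 center: tuple[float, float] | None) -> PolarGrid:
        key = (height, width, None if center is None else
               (round(center[0], 3), round(center[1], 3)))
        if key not in self._grid_cache:
            self._grid_cache[key] = build_polar_grid(
                height, width, center=center, n_theta=self.n_theta, n_r=self.n_r)
        return self._grid_cache[key]

    def forward(self, f: Tensor, center: tuple[float, float] | None = None,
                image: np.ndarray | None = None) -> Tensor:
        H, W = f.shape[-2:]
        if center is None:
            if self.center_mode == "dark_centroid":
                src = image if image is not None else f.data.mean(axis=(0, 1))
                cx, cy = dark_centroid(src)
                # dark-centroid estimates live on the source image grid;
                # rescale when features are strided
                if image is not None and image.shape != (H, W):
                    cx *= (W - 1) / (image.shape[1] - 1)
                    cy *= (H - 1) / (image.shape[0] - 1)
                center = (cx, cy)
            elif self.center_mode == "fixed":
                raise ValueError("center_mode='fixed' requires an explicit center")
        grid = self.grid_for(H, W, center)
        fp = cartesian_to_polar(f, grid)
        fp = F.circular_conv_theta(fp, self.w_theta)
        if self.use_attention:
            omega = self.attention(fp)  # (N, C)
            fp = fp * omega.reshape(fp.shape[0], fp.shape[1], 1, 1)
        back = polar_to_cartesian(fp, grid, out_shape=(H, W))
        return f + back


def rim_forward(f: Tensor, module: RadialIntensityModule,
                center: tuple[float, float] | None = None) -> Tensor:
    return module(f, center=center)
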