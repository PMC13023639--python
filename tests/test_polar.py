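"""Polar resampling, DCT channel attention and the radial module."""

import numpy as np
import pytest
from scipy import ndimage

from octseg.grad import Tensor
from octseg.polar import (
    DCTAttention,
    RadialIntensityModule,
    RIMParams,
    build_polar_grid,
    cartesian_to_polar,
    dark_centroid,
    dct_matrix,
    point_to_polar,
    polar_to_cartesian,
)


def brute_force_dct2(profile: np.ndarray) -> np.ndarray:
    """Orthonormal DCT-II by the direct O(n^2) cosine sum."""
    n = len(profile)
    out = np.zeros(n)
    for k in range(n):
        s = np.sqrt(1.0 / n) if k == 0 else np.sqrt(2.0 / n)
        out[k] = s * sum(profile[t] * np.cos(np.pi * (2 * t + 1) * k / (2 * n))
                         for t in range(n))
    return out


def disk_grid(size=32, n_theta=720, n_r=64):
    return build_polar_grid(size, size, n_theta=n_theta, n_r=n_r)


class TestPolarGrid:
    def test_point_on_positive_x_axis_is_unit_radius(self):
        g = disk_grid()
        cx, cy = g.center
        r, theta = point_to_polar(cx + (g.diameter - 1) / 2, cy, g.center, g.diameter)
        assert r == pytest.approx(1.0)
        assert theta == pytest.approx(0.0)

    def test_center_is_zero_radius(self):
        g = disk_grid()
        r, _ = point_to_polar(*g.center, g.center, g.diameter)
        assert r == 0.0

    def test_straight_down_is_theta_half(self):
        """y increases downward, so (cx, cy + (D-1)/4) sits at r=0.5,
        theta=atan2(+dy, 0)/pi = 0.5."""
        g = disk_grid()
        cx, cy = g.center
        r, theta = point_to_polar(cx, cy + (g.diameter - 1) / 4, g.center, g.diameter)
        assert r == pytest.approx(0.5)
        assert theta == pytest.approx(0.5)

    def test_grid_invariants(self):
        g = disk_grid(n_theta=90, n_r=16)
        assert np.all(np.diff(g.r) > 0)
        assert np.allclose(np.diff(g.theta), 2.0 / 90)
        assert np.allclose(g.sample_x[:, 0], g.center[0], atol=1e-5)
        assert np.allclose(g.sample_y[:, 0], g.center[1], atol=1e-5)

    def test_center_outside_image_rejected(self):
        with pytest.raises(ValueError):
            build_polar_grid(32, 32, center=(40.0, 10.0))

    def test_tiny_diameter_rejected(self):
        with pytest.raises(ValueError):
            build_polar_grid(32, 32, diameter=1.0)


class TestForwardResampling:
    def test_constant_image_maps_to_constant(self):
        g = disk_grid()
        f = Tensor(np.full((1, 1, 32, 32), 0.37, dtype=np.float32))
        fp = cartesian_to_polar(f, g)
        assert np.allclose(fp.numpy(), 0.37, atol=1e-6)

    def test_annulus_is_theta_invariant(self):
        """A centered bright ring becomes rows that are constant along
        theta (away from the ring edges)."""
        g = disk_grid(size=64)
        yy, xx = np.mgrid[0:64, 0:64]
        rad = np.hypot(xx - 31.5, yy - 31.5)
        img = np.exp(-0.5 * ((rad - 16) / 3.0) ** 2)
        fp = cartesian_to_polar(Tensor(img[None, None].astype(np.float32)), g).numpy()[0, 0]
        radius_px = g.r * 31.5
        peak = np.abs(radius_px - 16) < 1.0  # flat ring top
        for j in np.nonzero(peak)[0]:
            row = fp[:, j]
            assert row.var() < 1e-4 * row.mean() ** 2
        far = radius_px > 28  # far field: essentially zero everywhere
        assert fp[:, far].var() < 1e-8

    def test_center_row_is_constant(self):
        g = disk_grid()
        img = np.zeros((32, 32), dtype=np.float32)
        img[15, 15] = img[15, 16] = img[16, 15] = img[16, 16] = 1.0  # center 2x2
        fp = cartesian_to_polar(Tensor(img[None, None]), g).numpy()[0, 0]
        assert np.allclose(fp[:, 0], fp[0, 0])

    def test_linearity_exact(self, rng):
        g = disk_grid()
        a = rng.normal(size=(1, 2, 32, 32)).astype(np.float32)
        b = rng.normal(size=(1, 2, 32, 32)).astype(np.float32)
        pa = cartesian_to_polar(Tensor(a), g).numpy()
        pb = cartesian_to_polar(Tensor(b), g).numpy()
        pc = cartesian_to_polar(Tensor(2.0 * a + 0.5 * b), g).numpy()
        assert np.allclose(pc, 2.0 * pa + 0.5 * pb, atol=1e-4)

    def test_shape_mismatch_rejected(self):
        g = disk_grid()
        with pytest.raises(ValueError):
            cartesian_to_polar(Tensor(np.zeros((1, 1, 16, 16))), g)

    def test_rotation_covariance(self):
        """Rotating the image by k angular bins cyclically shifts the
        polar map by k rows, to within interpolation error."""
        g = disk_grid(size=64)
        yy, xx = np.mgrid[0:64, 0:64]
        rad = np.hypot(xx - 31.5, yy - 31.5) / 31.5
        img = np.exp(-((rad * 2) ** 2)) * (1 + 0.5 * np.cos(np.arctan2(yy - 31.5, xx - 31.5)))
        img = img.astype(np.float32)
        k = 12  # 12 bins of 0.5 deg
        rot = ndimage.rotate(img, np.degrees(2 * np.pi * k / g.n_theta),
                             reshape=False, order=3, mode="nearest")
        p0 = cartesian_to_polar(Tensor(img[None, None]), g).numpy()[0, 0]
        p1 = cartesian_to_polar(Tensor(rot[None, None]), g).numpy()[0, 0]
        dyn = img.max() - img.min()
        inner = g.r < 0.9  # rim touches rotation resampling artifacts
        # scipy rotates counter-clockwise on screen; theta runs from +x
        # toward +y (down), i.e. clockwise, so the polar map shifts by -k
        err = np.abs(np.roll(p0, -k, axis=0) - p1)[:, inner].max()
        assert err < 0.02 * dyn


class TestInverseResampling:
    def test_round_trip_smooth_radial_image(self):
        g = disk_grid(size=64)
        yy, xx = np.mgrid[0:64, 0:64]
        rad = np.hypot(xx - 31.5, yy - 31.5) / 31.5
        img = np.exp(-((rad * 2) ** 2)).astype(np.float32)
        back = polar_to_cartesian(
            cartesian_to_polar(Tensor(img[None, None]), g), g).numpy()[0, 0]
        m = rad <= 0.9
        rel = np.linalg.norm((back - img)[m]) / np.linalg.norm(img[m])
        assert rel < 0.05

    def test_constant_polar_map_fills_disk(self):
        g = disk_grid()
        fp = Tensor(np.full((1, 1, g.n_theta, g.n_r), 0.8, dtype=np.float32))
        out = polar_to_cartesian(fp, g).numpy()[0, 0]
        yy, xx = np.mgrid[0:32, 0:32]
        inside = np.hypot(xx - 15.5, yy - 15.5) / 15.5 <= 1.0
        assert np.allclose(out[inside], 0.8, atol=1e-5)
        assert np.allclose(out[~inside], 0.0)

    def test_theta_seam_has_no_artifact(self):
        """A feature crossing theta=+/-1 (the -x axis seam) reconstructs
        as smoothly as one at theta=0: compare against a half-turn-rotated
        grid that moves the seam to the other side."""
        size = 64
        g = build_polar_grid(size, size, n_theta=360, n_r=32)
        yy, xx = np.mgrid[0:size, 0:size]
        c = (size - 1) / 2
        rad = np.hypot(xx - c, yy - c) / c
        ang = np.arctan2(yy - c, xx - c)
        # blob straddling the seam (centered on the -x axis)
        img = (np.exp(-0.5 * ((rad - 0.6) / 0.1) ** 2)
               * np.exp(-0.5 * (np.abs(np.abs(ang) - np.pi) / 0.3) ** 2)).astype(np.float32)
        back = polar_to_cartesian(cartesian_to_polar(Tensor(img[None, None]), g),
                                  g).numpy()[0, 0]
        mirrored = img[::-1, ::-1].copy()  # seam feature now at theta=0
        back_m = polar_to_cartesian(cartesian_to_polar(Tensor(mirrored[None, None]), g),
                                    g).numpy()[0, 0]
        err_seam = np.abs(back - img)[rad <= 0.9].max()
        err_ref = np.abs(back_m - mirrored)[rad <= 0.9].max()
        assert err_seam < err_ref + 0.01

    def test_bad_out_shape_rejected(self):
        g = disk_grid()
        fp = Tensor(np.zeros((1, 1, g.n_theta, g.n_r)))
        with pytest.raises(ValueError):
            polar_to_cartesian(fp, g, out_shape=(0, 5))


class TestDCTAttention:
    def test_constant_profile_has_zero_ac_coefficients(self):
        coeffs = brute_force_dct2(np.full(16, 3.0))
        assert abs(coeffs[0]) > 0
        assert np.allclose(coeffs[1:], 0.0, atol=1e-12)

    def test_zeroed_mlp_outputs_half(self, rng):
        att = DCTAttention(RIMParams(dct_k=8), rng)
        att.fc1.weight.data[:] = 0
        att.fc1.bias.data[:] = 0
        att.fc2.weight.data[:] = 0
        att.fc2.bias.data[:] = 0
        fp = Tensor(rng.normal(size=(2, 3, 32, 8)).astype(np.float32))
        omega = att(fp).numpy()
        assert np.allclose(omega, 0.5, atol=1e-6)

    def test_single_frequency_recovery_matches_brute_force(self):
        """cos(pi*(2t+1)m/(2N)) excites exactly coefficient m."""
        n, m = 32, 5
        t = np.arange(n)
        profile = np.cos(np.pi * (2 * t + 1) * m / (2 * n))
        coeffs = brute_force_dct2(profile)
        assert abs(coeffs[m]) > 1.0
        others = np.delete(coeffs, m)
        assert np.abs(others).max() < 1e-10
        # the module's internal matrix agrees with the brute-force sum
        mat = dct_matrix(n, n)
        assert np.allclose(mat @ profile, coeffs, atol=1e-10)

    def test_too_many_frequencies_rejected(self, rng):
        att = DCTAttention(RIMParams(dct_k=64), rng)
        with pytest.raises(ValueError):
            att(Tensor(np.zeros((1, 1, 32, 4))))

    def test_output_in_open_unit_interval(self, rng):
        att = DCTAttention(RIMParams(dct_k=8), rng)
        omega = att(Tensor(rng.normal(size=(2, 4, 32, 8)).astype(np.float32))).numpy()
        assert np.all(omega > 0) and np.all(omega < 1)


class TestRadialIntensityModule:
    def test_identity_configuration_doubles_smooth_input(self, rng):
        """Delta kernel + unit attention make the branch a pure round
        trip, so output ~ 2f on a radially smooth map."""
        rim = RadialIntensityModule(1, rng, n_theta=720, n_r=64)
        rim.set_identity()
        yy, xx = np.mgrid[0:64, 0:64]
        rad = np.hypot(xx - 31.5, yy - 31.5) / 31.5
        img = np.exp(-((rad * 2) ** 2)).astype(np.float32)
        out = rim(Tensor(img[None, None])).numpy()[0, 0]
        m = rad <= 0.9
        rel = np.linalg.norm((out - 2 * img)[m]) / np.linalg.norm(img[m])
        assert rel < 0.05

    def test_zero_input_gives_zero_output(self, rng):
        rim = RadialIntensityModule(2, rng, n_theta=90, n_r=8)
        out = rim(Tensor(np.zeros((1, 2, 16, 16), dtype=np.float32))).numpy()
        assert np.allclose(out, 0.0, atol=1e-6)

    def test_gradient_flows_to_input(self, rng):
        rim = RadialIntensityModule(2, rng, n_theta=90, n_r=8)
        f = Tensor(rng.normal(size=(1, 2, 16, 16)).astype(np.float32), requires_grad=True)
        (rim(f) ** 2).sum().backward()
        assert np.all(np.isfinite(f.grad))
        assert np.abs(f.grad).max() > 0

    def test_dark_centroid_finds_dark_lumen(self, small_phantom):
        image, mask, params = small_phantom
        cx, cy = dark_centroid(image)
        true_cx, true_cy = params.center()
        assert abs(cx - true_cx) < 3 and abs(cy - true_cy) < 3
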