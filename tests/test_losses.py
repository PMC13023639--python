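"""Loss identities, boundary-band morphology oracle, and surface metrics."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial.distance import cdist

from octseg.grad import Tensor
from octseg.losses import (
    LossWeights,
    boundary_extract,
    boundary_iou_loss,
    dice_loss,
    focal_tversky_loss,
    oct_loss,
    soft_boundary_band,
)
from octseg.metrics import (
    UndefinedMetricError,
    aggregate,
    dice_score,
    evaluate_pair,
    hd95,
    hd95_px,
    iou_score,
)


def morphology_oracle_band(mask, dilation=2):
    """Independent reference: scipy binary morphology with the 3x3 square."""
    m = mask.astype(bool)
    struct = np.ones((3, 3), dtype=bool)
    inner = m & ~ndimage.binary_erosion(m, structure=struct, border_value=0)
    return ndimage.binary_dilation(inner, structure=struct, iterations=dilation)


def bruteforce_hd95(a, b):
    """All-pairs distance reference for HD95 on small masks."""
    pa = np.argwhere(a.astype(bool) & ~ndimage.binary_erosion(
        a.astype(bool), np.ones((3, 3), bool), border_value=0))
    pb = np.argwhere(b.astype(bool) & ~ndimage.binary_erosion(
        b.astype(bool), np.ones((3, 3), bool), border_value=0))
    d = cdist(pa, pb)
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return np.percentile(pooled, 95)


def square_mask(size, top, left, side):
    m = np.zeros((size, size), dtype=np.uint8)
    m[top:top + side, left:left + side] = 1
    return m


class TestDiceLoss:
    def test_perfect_overlap_is_zero(self):
        g = square_mask(16, 4, 4, 5).astype(float)
        assert dice_loss(Tensor(g), g).item() == pytest.approx(0.0, abs=1e-5)

    def test_half_overlap_example(self):
        """|X| = |Y| = 4 with overlap 2 gives 1 - 4/8 = 0.5."""
        g = np.zeros((4, 4))
        g[0, :4] = 1
        p = np.zeros((4, 4))
        p[0, 2:] = 1
        p[1, :2] = 1
        assert dice_loss(Tensor(p), g).item() == pytest.approx(0.5, abs=1e-5)

    def test_empty_prediction_is_total_loss(self):
        g = square_mask(8, 2, 2, 3).astype(float)
        assert dice_loss(Tensor(np.zeros((8, 8))), g).item() == pytest.approx(1.0, abs=1e-4)

    def test_empty_tensor_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(Tensor(np.zeros((0,))), np.zeros((0,)))


class TestFocalTversky:
    def test_perfect_overlap_is_zero(self):
        g = square_mask(16, 4, 4, 5).astype(float)
        assert focal_tversky_loss(Tensor(g), g).item() == pytest.approx(0.0, abs=1e-5)

    def test_hand_computed_counts(self):
        """TP=8, FP=2, FN=2 with alpha=0.3, beta=0.7: TI = 8/10, and the
        loss is 0.2^(4/3) ~ 0.11696."""
        p = np.zeros(12)
        g = np.zeros(12)
        p[:10] = 1  # 8 true positives + 2 false positives
        g[:8] = 1
        g[10:12] = 1  # 2 false negatives
        got = focal_tversky_loss(Tensor(p), g).item()
        assert got == pytest.approx(0.2 ** (4.0 / 3.0), abs=1e-4)

    def test_reduces_to_dice_at_symmetric_parameters(self):
        g = square_mask(12, 3, 3, 4).astype(float)
        p = square_mask(12, 4, 3, 4).astype(float)
        ft = focal_tversky_loss(Tensor(p), g, alpha=0.5, beta=0.5, gamma=1.0).item()
        dl = dice_loss(Tensor(p), g).item()
        assert ft == pytest.approx(dl, abs=1e-5)

    def test_invalid_parameters_rejected(self):
        g = np.ones((4, 4))
        with pytest.raises(ValueError):
            focal_tversky_loss(Tensor(g), g, alpha=-0.1)
        with pytest.raises(ValueError):
            focal_tversky_loss(Tensor(g), g, gamma=0.0)


class TestBoundaryBand:
    def test_full_mask_band_hugs_border(self):
        band = boundary_extract(np.ones((16, 16)), dilation=2)
        assert band[:3].all() and band[-3:].all()
        assert band[3:-3, 3:-3].sum() == 0

    def test_single_pixel_gives_chebyshev_disk(self):
        m = np.zeros((16, 16), dtype=np.uint8)
        m[8, 8] = 1
        band = boundary_extract(m, dilation=2)
        assert band.sum() == 25
        assert band[6:11, 6:11].all()

    def test_matches_morphology_oracle_on_random_masks(self, rng):
        for _ in range(100):
            m = ndimage.binary_closing(rng.random((32, 32)) > 0.6)
            got = boundary_extract(m.astype(np.uint8), dilation=2)
            want = morphology_oracle_band(m, dilation=2)
            assert np.array_equal(got.astype(bool), want)

    def test_soft_band_converges_to_hard_band(self):
        """Sharpening a probability map drives the soft band to the hard
        band of its binarization."""
        g = square_mask(24, 8, 8, 7).astype(float)
        hard = boundary_extract(g, 2).astype(float)
        for sharp, tol in ((5.0, 0.5), (50.0, 1e-3)):
            p = 1.0 / (1.0 + np.exp(-sharp * (g - 0.5)))
            soft = soft_boundary_band(Tensor(p), 2).numpy()
            assert np.abs(soft - hard).max() < 2 * tol


class TestBoundaryIoU:
    def test_perfect_match_is_zero(self):
        g = square_mask(16, 4, 4, 6)
        assert boundary_iou_loss(g, g) == pytest.approx(0.0)

    def test_distant_single_pixels_are_total_loss(self):
        a = np.zeros((20, 20), dtype=np.uint8)
        b = np.zeros((20, 20), dtype=np.uint8)
        a[4, 4] = 1
        b[4, 12] = 1  # 8 px apart, bands of radius 2 are disjoint
        assert boundary_iou_loss(a, b) == pytest.approx(1.0)

    def test_translation_strictly_increases_loss(self):
        g = square_mask(24, 8, 8, 8)
        shifted = square_mask(24, 8, 9, 8)
        assert boundary_iou_loss(shifted, g) > 0.0

    def test_both_empty_is_perfect_by_convention(self):
        z = np.zeros((8, 8), dtype=np.uint8)
        assert boundary_iou_loss(z, z) == 0.0

    def test_soft_loss_at_target_is_near_zero(self):
        g = square_mask(24, 8, 8, 8).astype(float)
        assert boundary_iou_loss(Tensor(g), g).item() == pytest.approx(0.0, abs=1e-4)


class TestOctLoss:
    def test_weighted_combination_exact(self, rng):
        p = Tensor(rng.random((16, 16)).astype(np.float32))
        g = (rng.random((16, 16)) > 0.9).astype(float)
        total, comps = oct_loss(p, g)
        want = 0.5 * comps["dice"].item() + 0.3 * comps["biou"].item() \
            + 0.2 * comps["ft"].item()
        assert total.item() == pytest.approx(want, abs=1e-6)

    def test_perfect_prediction_is_zero(self):
        g = square_mask(16, 4, 4, 6).astype(float)
        total, _ = oct_loss(Tensor(g), g)
        assert total.item() == pytest.approx(0.0, abs=1e-4)

    def test_dice_only_weights(self, rng):
        p = Tensor(rng.random((12, 12)).astype(np.float32))
        g = (rng.random((12, 12)) > 0.9).astype(float)
        total, _ = oct_loss(p, g, LossWeights(w_dice=1.0, w_biou=0.0, w_ft=0.0))
        assert total.item() == pytest.approx(dice_loss(Tensor(p.numpy()), g).item(),
                                             abs=1e-6)

    def test_all_components_in_unit_interval(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            p = Tensor(r.random((16, 16)).astype(np.float32))
            g = (r.random((16, 16)) > 0.95).astype(float)
            total, comps = oct_loss(p, g)
            for v in [total] + list(comps.values()):
                val = v.item() if isinstance(v, Tensor) else float(v)
                assert -1e-6 <= val <= 1.0 + 1e-6

    def test_gradients_finite_and_nonzero(self, rng):
        p = Tensor(rng.uniform(0.2, 0.8, (16, 16)).astype(np.float32), requires_grad=True)
        g = square_mask(16, 5, 5, 4).astype(float)
        total, _ = oct_loss(p, g)
        total.backward()
        assert np.all(np.isfinite(p.grad)) and np.abs(p.grad).max() > 0


class TestOverlapScores:
    def test_confusion_example(self):
        """TP=2, FP=2, FN=2 gives DSC = 4/8 = 0.5."""
        pred = np.zeros(6)
        gt = np.zeros(6)
        pred[:4] = 1
        gt[2:] = 1
        assert dice_score(pred, gt) == pytest.approx(0.5)
        assert iou_score(pred, gt) == pytest.approx(2 / 6)

    def test_identical_masks_score_one(self):
        m = square_mask(10, 2, 2, 4)
        assert dice_score(m, m) == 1.0 and iou_score(m, m) == 1.0

    def test_disjoint_masks_score_zero(self):
        assert dice_score(square_mask(12, 1, 1, 3), square_mask(12, 7, 7, 3)) == 0.0

    def test_both_empty_convention(self):
        z = np.zeros((5, 5))
        assert dice_score(z, z) == 1.0 and iou_score(z, z) == 1.0


class TestHD95:
    def test_identical_masks_zero_distance(self):
        m = square_mask(32, 8, 8, 10)
        assert hd95_px(m, m) == 0.0

    def test_shifted_squares_give_shift_times_spacing(self):
        """Two large squares offset by k px have HD95 = k * spacing."""
        for k in (1, 2, 3):
            a = square_mask(64, 20, 20, 24)
            b = square_mask(64, 20, 20 + k, 24)
            assert hd95(a, b, spacing_mm=0.005) == pytest.approx(k * 0.005, rel=1e-6)

    def test_symmetric_in_arguments(self, rng):
        a = ndimage.binary_closing(rng.random((32, 32)) > 0.6).astype(np.uint8)
        b = ndimage.binary_closing(rng.random((32, 32)) > 0.6).astype(np.uint8)
        if a.sum() and b.sum():
            assert hd95_px(a, b) == pytest.approx(hd95_px(b, a))

    def test_matches_bruteforce_all_pairs(self, rng):
        count = 0
        while count < 50:
            a = ndimage.binary_closing(rng.random((48, 48)) > 0.55)
            b = ndimage.binary_closing(rng.random((48, 48)) > 0.55)
            if a.sum() == 0 or b.sum() == 0:
                continue
            count += 1
            assert hd95_px(a, b) == pytest.approx(bruteforce_hd95(a, b), abs=1e-6)

    def test_matches_distance_transform_route(self, rng):
        """Cross-check against an independent EDT-based surface-distance
        implementation on 50 random pairs."""

        def edt_hd95(a, b):
            struct = np.ones((3, 3), bool)
            sa = a & ~ndimage.binary_erosion(a, struct, border_value=0)
            sb = b & ~ndimage.binary_erosion(b, struct, border_value=0)
            dta = ndimage.distance_transform_edt(~sa)
            dtb = ndimage.distance_transform_edt(~sb)
            pooled = np.concatenate([dtb[sa], dta[sb]])
            return np.percentile(pooled, 95)

        count = 0
        while count < 50:
            a = ndimage.binary_closing(rng.random((40, 40)) > 0.55)
            b = ndimage.binary_closing(rng.random((40, 40)) > 0.55)
            if a.sum() == 0 or b.sum() == 0:
                continue
            count += 1
            assert hd95_px(a, b) == pytest.approx(edt_hd95(a, b), abs=1e-6)

    def test_empty_mask_raises(self):
        with pytest.raises(UndefinedMetricError):
            hd95_px(np.zeros((8, 8)), square_mask(8, 2, 2, 3))

    def test_aggregate_reports_missing_hd95(self):
        g = square_mask(16, 4, 4, 5)
        records = [evaluate_pair(g, g), evaluate_pair(np.zeros_like(g), g)]
        agg = aggregate(records)
        assert agg["hd95_missing"] == 1
        assert agg["hd95_px"]["n"] == 1
        assert records[1]["hd95_px"] is None
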