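"""Evaluation metrics: Dice/IoU overlap and the 95th-percentile
Hausdorff surface distance (HD95), reported in pixels and millimetres.

HD95 follows the common symmetric definition: boundary pixels are
extracted from both masks, the two directed point-to-nearest-boundary
distance lists are pooled, and the 95th percentile (linear
interpolation) of the pooled list is returned.  Physical distances use
an isotropic pixel spacing, default 0.005 mm (5 um native resolution).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

DEFAULT_SPACING_MM = 0.005


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined (e.g. HD95 with an empty mask)."""


def _confusion(pred, gt):
    p = np.asarray(pred) > 0.5
    g = np.asarray(gt) > 0.5
    if p.shape != g.shape:
        raise ValueError("shape mismatch")
    tp = np.logical_and(p, g).sum()
    fp = np.logical_and(p, ~g).sum()
    fn = np.logical_and(~p, g).sum()
    return tp, fp, fn


def dice_score(pred, gt) -> float:
    """DSC = 2TP / (2TP + FP + FN); both masks empty counts as 1.0."""
    tp, fp, fn = _confusion(pred, gt)
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2 * tp / denom


def iou_score(pred, gt) -> float:
    tp, fp, fn = _confusion(pred, gt)
    denom = tp + fp + fn
    return 1.0 if denom == 0 else tp / denom


def boundary_points(mask) -> np.ndarray:
    """(row, col) coordinates of the one-pixel inner boundary layer."""
    m = np.asarray(mask) > 0.5
    eroded = ndimage.binary_erosion(m, structure=np.ones((3, 3)), border_value=0)
    return np.argwhere(m & ~eroded)


def hd95_px(pred, gt) -> float:
    """HD95 in pixels over the pooled symmetric surface distances."""
    pb = boundary_points(pred)
    gb = boundary_points(gt)
    if len(pb) == 0 or len(gb) == 0:
        raise UndefinedMetricError("undefined HD95: empty prediction or reference mask")
    d_pg = cKDTree(gb).query(pb)[0]
    d_gp = cKDTree(pb).query(gb)[0]
    return float(np.percentile(np.concatenate([d_pg, d_gp]), 95))


def hd95(pred, gt, spacing_mm: float = DEFAULT_SPACING_MM) -> float:
    """HD95 in millimetres at the given isotropic pixel spacing."""
    return hd95_px(pred, gt) * spacing_mm


def evaluate_pair(pred, gt, spacing_mm: float = DEFAULT_SPACING_MM) -> dict:
    """Per-image metric record; HD95 is None when undefined."""
    rec = {"dice": dice_score(pred, gt), "iou": iou_score(pred, gt)}
    try:
        px = hd95_px(pred, gt)
        rec["hd95_px"] = px
        rec["hd95_mm"] = px * spacing_mm
    except UndefinedMetricError:
        rec["hd95_px"] = None
        rec["hd95_mm"] = None
    return rec


def aggregate(records: list[dict]) -> dict:
    """Mean and SD per metric over images; missing HD95 values are
    excluded and counted."""
    out: dict = {"n_images": len(records)}
    for key in ("dice", "iou", "hd95_px", "hd95_mm"):
        vals = [r[key] for r in records if r.get(key) is not None]
        out[key] = {
            "mean": float(np.mean(vals)) if vals else None,
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0 if vals else None,
            "n": len(vals),
        }
    out["hd95_missing"] = sum(1 for r in records if r.get("hd95_px") is None)
    return out


def paired_ttest(a: list[float], b: list[float]):
    """Paired t-test convenience wrapper (statistic, p-value)."""
    from scipy import stats

    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
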