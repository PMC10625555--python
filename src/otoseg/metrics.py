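"""Segmentation and localization evaluation criteria.

Overlap metrics: Dice-Sørensen coefficient (DSC, the primary metric),
intersection-over-union (IoU / Jaccard) and volumetric similarity (VS).
Distance metrics: the Hausdorff distance HD (max of directed max-min
distances between the two foreground voxel sets) and its outlier-robust
average variant <HD> (mean of the two directed mean distances). Distances
are computed between full foreground voxel sets — not extracted surfaces —
via the Euclidean distance transform, and are reported in voxel units.

Localization error is the per-landmark Euclidean distance between ground
truth and predicted (argmax) voxel coordinates. Report aggregation follows
the mean / SD / median convention with sample SD (ddof=1) across instances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_core import LANDMARK_NAMES, LandmarkSet


class MetricError(ValueError):
    pass


def _as_bool(a) -> np.ndarray:
    a = np.asarray(a)
    return a.astype(bool)


def _check_grids(a: np.ndarray, b: np.ndarray):
    if a.shape != b.shape:
        raise MetricError(f"grid mismatch: {a.shape} vs {b.shape}")


def dsc(a, b) -> float:
    """Dice-Sørensen coefficient; 1.0 when both masks are empty."""
    a, b = _as_bool(a), _as_bool(b)
    _check_grids(a, b)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def iou(a, b) -> float:
    """Intersection-over-union (Jaccard index); 1.0 when both empty."""
    a, b = _as_bool(a), _as_bool(b)
    _check_grids(a, b)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def vs(a, b) -> float:
    """Volumetric similarity: 1 - | |a| - |b| | / (|a| + |b|)."""
    a, b = _as_bool(a), _as_bool(b)
    _check_grids(a, b)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 1.0 - abs(na - nb) / (na + nb)


def hausdorff(a, b) -> tuple[float, float]:
    """(HD, <HD>) between two nonempty binary masks, in voxel units.

    Directed distances d(x, S) = min Euclidean distance from voxel x of one
    foreground to the other foreground set; HD takes the max over both
    directions, <HD> the mean of the two directed averages.
    """
    a, b = _as_bool(a), _as_bool(b)
    _check_grids(a, b)
    if not a.any() or not b.any():
        raise MetricError("Hausdorff distance undefined for an empty mask")
    # distance from every voxel to the nearest foreground voxel of the mask
    dist_to_b = ndimage.distance_transform_edt(~b)
    dist_to_a = ndimage.distance_transform_edt(~a)
    d_ab = dist_to_b[a]  # distances of a's voxels to b
    d_ba = dist_to_a[b]
    hd = float(max(d_ab.max(), d_ba.max()))
    avg_hd = float((d_ab.mean() + d_ba.mean()) / 2.0)
    return hd, avg_hd


def landmark_deviation(pred: LandmarkSet, truth: LandmarkSet) -> dict[str, float]:
    """Per-landmark Euclidean deviation plus the three-landmark average."""
    out = {}
    for name in LANDMARK_NAMES:
        p = np.asarray(getattr(pred, name), dtype=float)
        t = np.asarray(getattr(truth, name), dtype=float)
        if p.shape != (3,) or t.shape != (3,):
            raise MetricError(f"missing or malformed landmark {name}")
        out[name] = float(np.linalg.norm(p - t))
    out["average"] = float(np.mean([out[n] for n in LANDMARK_NAMES]))
    return out


def evaluate_pair(pred_mask, truth_mask, pred_lms: LandmarkSet | None = None,
                  truth_lms: LandmarkSet | None = None,
                  distances: bool = True) -> dict[str, float]:
    """All criteria for one instance; landmark columns when sets given."""
    row = {
        "dsc": dsc(pred_mask, truth_mask),
        "iou": iou(pred_mask, truth_mask),
        "vs": vs(pred_mask, truth_mask),
    }
    if distances:
        hd, ahd = hausdorff(pred_mask, truth_mask)
        row["hd"] = hd
        row["avg_hd"] = ahd
    if pred_lms is not None and truth_lms is not None:
        dev = landmark_deviation(pred_lms, truth_lms)
        row.update({f"dev_{k}": v for k, v in dev.items()})
    return row


def aggregate(rows) -> pd.DataFrame:
    """Mean / SD / median table over per-instance metric rows.

    SD is the sample standard deviation (ddof=1; 0 for a single row).
    """
    df = pd.DataFrame(list(rows))
    if df.empty:
        raise MetricError("no rows to aggregate")
    agg = pd.DataFrame(
        {
            "mean": df.mean(),
            "sd": df.std(ddof=1).fillna(0.0),
            "median": df.median(),
        }
    )
    return agg


def cdl_worst_case(dev_helicotrema: float, dev_round_window: float,
                   voxel_um: float = 99.0) -> float:
    """Worst-case cochlear-duct-length error in millimetres.

    Both endpoint localization errors (voxel units) add up and convert to
    physical units via the isotropic voxel edge length in micrometres.
    """
    if dev_helicotrema < 0 or dev_round_window < 0 or voxel_um <= 0:
        raise MetricError("deviations must be >= 0 and voxel size positive")
    return (dev_helicotrema + dev_round_window) * voxel_um / 1000.0
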