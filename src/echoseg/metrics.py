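"""Segmentation evaluation indices: Dice, IoU, Hausdorff distance, and the
mean absolute boundary deviation (MAD).

Dice and IoU are region-overlap statistics; HD and MAD are contour
statistics computed between boundary pixel sets.  A boundary pixel is a
foreground pixel with at least one background 4-neighbour (the inner
contour); distances are Euclidean in pixel units, computed with a k-d tree
over the opposite boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyRegionError

__all__ = [
    "MetricsReport",
    "boundary_pixels",
    "dice_score",
    "iou_score",
    "hausdorff_distance",
    "mad",
    "evaluate_pair",
    "evaluate_set",
]


@dataclass
class MetricsReport:
    """Metric values for one mask pair or averaged over a set."""

    dice: float
    iou: float
    hd: float
    mad: float
    n_images: int = 1
    n_skipped: int = 0


def _as_bool(mask) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def boundary_pixels(mask) -> np.ndarray:
    """(K, 2) row/col coordinates of the inner contour of ``mask``.

    A pixel belongs to the boundary iff it is foreground and at least one of
    its 4-neighbours (pixels outside the array count as background) is
    background.
    """
    m = _as_bool(mask)
    if m.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {m.shape}")
    padded = np.pad(m, 1)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return np.argwhere(m & ~interior)


def dice_score(pred, truth) -> float:
    """2 |R n G| / (|R| + |G|); both-empty convention: 1.0 (with a warning)."""
    r = _as_bool(pred)
    g = _as_bool(truth)
    if r.shape != g.shape:
        raise ValueError(f"shape mismatch: {r.shape} vs {g.shape}")
    denom = r.sum() + g.sum()
    if denom == 0:
        warnings.warn("dice of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * float(np.count_nonzero(r & g)) / float(denom)


def iou_score(pred, truth) -> float:
    """|R n G| / |R u G|; both-empty convention: 1.0 (with a warning)."""
    r = _as_bool(pred)
    g = _as_bool(truth)
    if r.shape != g.shape:
        raise ValueError(f"shape mismatch: {r.shape} vs {g.shape}")
    union = np.count_nonzero(r | g)
    if union == 0:
        warnings.warn("IoU of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    return float(np.count_nonzero(r & g)) / float(union)


def _boundary_pair(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    br = boundary_pixels(pred)
    bg = boundary_pixels(truth)
    if br.size == 0:
        raise EmptyRegionError("predicted region has an empty boundary")
    if bg.size == 0:
        raise EmptyRegionError("ground-truth region has an empty boundary")
    return br.astype(np.float64), bg.astype(np.float64)


def hausdorff_distance(pred, truth) -> float:
    """Symmetric Hausdorff distance between the two inner contours:
    max over both directions of the farthest nearest-neighbour distance."""
    br, bg = _boundary_pair(pred, truth)
    d_rg = cKDTree(bg).query(br)[0]
    d_gr = cKDTree(br).query(bg)[0]
    return float(max(d_rg.max(), d_gr.max()))


def mad(pred, truth) -> float:
    """Mean absolute boundary deviation: the average of the two directed
    mean nearest-neighbour distances between the contours."""
    br, bg = _boundary_pair(pred, truth)
    d_rg = cKDTree(bg).query(br)[0]
    d_gr = cKDTree(br).query(bg)[0]
    return 0.5 * (float(d_rg.mean()) + float(d_gr.mean()))


def evaluate_pair(pred, truth) -> MetricsReport:
    """All four indices for one predicted/truth mask pair."""
    return MetricsReport(
        dice=dice_score(pred, truth),
        iou=iou_score(pred, truth),
        hd=hausdorff_distance(pred, truth),
        mad=mad(pred, truth),
        n_images=1,
    )


def evaluate_set(pairs) -> MetricsReport:
    """Unweighted mean of each metric over (pred, truth) mask pairs.

    Pairs for which the contour metrics are undefined (an empty boundary on
    either side) are skipped and counted in ``n_skipped``.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("evaluate_set requires at least one pair")
    reports = []
    skipped = 0
    for pred, truth in pairs:
        try:
            reports.append(evaluate_pair(pred, truth))
        except EmptyRegionError:
            skipped += 1
    if not reports:
        raise EmptyRegionError("every pair had an undefined contour metric")
    return MetricsReport(
        dice=float(np.mean([r.dice for r in reports])),
        iou=float(np.mean([r.iou for r in reports])),
        hd=float(np.mean([r.hd for r in reports])),
        mad=float(np.mean([r.mad for r in reports])),
        n_images=len(reports),
        n_skipped=skipped,
    )
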