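"""Overlap losses and surface-distance metrics for binary segmentations.

Overlap is quantified by the Sørensen-Dice coefficient
``DSC = 2|X∩Y| / (|X|+|Y|)`` and the Jaccard index ``r = |X∩Y| / |X∪Y|``;
the (soft) Jaccard loss ``J = 1 - r`` drives back-propagation while the
Dice loss ``1 - DSC`` scores models during validation ranking.  Boundary
quality is quantified in physical millimetres by the directed RMS surface
distance and the symmetric Hausdorff distance between surface point sets.

A pair of empty masks has no defined overlap and an empty (or full) mask
has no surface; these cases raise or return NaN explicitly rather than
silently scoring 0 or 1, mirroring the exclusion of failed segmentations
from cohort statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "OverlapCounts",
    "SurfacePointSet",
    "EmptyMaskError",
    "overlap_counts",
    "dice_coefficient",
    "dice_loss",
    "jaccard_index",
    "jaccard_loss",
    "binary_accuracy",
    "surface_points",
    "rms_surface_distance",
    "symmetric_mean_surface_distance",
    "hausdorff_distance",
]

EPS = 1e-5  # smoothing constant of the soft Jaccard loss


class EmptyMaskError(ValueError):
    """Raised where a metric is undefined (empty/full mask)."""


@dataclass(frozen=True)
class OverlapCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class SurfacePointSet:
    """World coordinates (mm) of the centres of a mask's boundary voxels."""

    points: np.ndarray  # (M, 3)

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.shape[0] == 0 or pts.shape[1] != 3:
            raise EmptyMaskError("a surface point set must contain at least one 3-D point")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]


def _as_binary(mask, name="mask") -> np.ndarray:
    arr = np.asarray(mask)
    if hasattr(mask, "values"):
        arr = np.asarray(mask.values)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} is not binary")
    return arr.astype(bool)


def overlap_counts(pred, truth) -> OverlapCounts:
    x = _as_binary(pred, "prediction")
    y = _as_binary(truth, "ground truth")
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    tp = int(np.count_nonzero(x & y))
    fp = int(np.count_nonzero(x & ~y))
    fn = int(np.count_nonzero(~x & y))
    return OverlapCounts(tp, fp, fn, x.size - tp - fp - fn)


def dice_coefficient(pred, truth) -> float:
    """``2|X∩Y| / (|X|+|Y|)``; NaN when both masks are empty."""
    c = overlap_counts(pred, truth)
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return float("nan")
    return 2.0 * c.tp / denom


def dice_loss(pred, truth) -> float:
    return 1.0 - dice_coefficient(pred, truth)


def jaccard_index(pred, truth) -> float:
    """``|X∩Y| / |X∪Y|``; NaN when both masks are empty."""
    c = overlap_counts(pred, truth)
    union = c.tp + c.fp + c.fn
    if union == 0:
        return float("nan")
    return c.tp / union


def jaccard_loss(prob: np.ndarray, truth, eps: float = EPS) -> float:
    """Soft Jaccard loss ``1 - (sum(p*y)+eps) / (sum(p)+sum(y)-sum(p*y)+eps)``.

    ``prob`` carries per-voxel probabilities in [0, 1]; on hard 0/1 input it
    reduces to ``1 - r`` up to the smoothing constant.
    """
    p = np.asarray(prob, dtype=np.float64)
    y = _as_binary(truth, "ground truth").astype(np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {y.shape}")
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    inter = float((p * y).sum())
    union = float(p.sum() + y.sum() - inter)
    return 1.0 - (inter + eps) / (union + eps)


def binary_accuracy(prob: np.ndarray, truth) -> float:
    """Fraction of voxels with ``(p >= 0.5) == y``."""
    p = np.asarray(prob, dtype=float)
    y = _as_binary(truth, "ground truth")
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {y.shape}")
    return float(np.count_nonzero((p >= 0.5) == y)) / p.size


def surface_points(mask, spacing=(1.0, 1.0, 1.0),
                   origin=(0.0, 0.0, 0.0)) -> SurfacePointSet:
    """Boundary voxels of a mask as world-coordinate points.

    A mask voxel is a boundary voxel when at least one of its six
    face-neighbours is background; voxels beyond the grid edge count as
    background.  If ``mask`` is an ImageGrid its spacing/origin are used.
    """
    if hasattr(mask, "spacing"):
        spacing, origin = mask.spacing, mask.origin
    m = _as_binary(mask)
    if not m.any():
        raise EmptyMaskError("empty mask has no surface")
    if m.all():
        raise EmptyMaskError("full-grid mask has no surface")
    interior = np.ones_like(m)
    for axis in range(3):
        lo = np.roll(m, 1, axis=axis)
        hi = np.roll(m, -1, axis=axis)
        # grid edges: rolled-in values are from the far side; force background
        edge_lo = [slice(None)] * 3
        edge_lo[axis] = slice(0, 1)
        edge_hi = [slice(None)] * 3
        edge_hi[axis] = slice(-1, None)
        lo[tuple(edge_lo)] = False
        hi[tuple(edge_hi)] = False
        interior &= lo & hi
    boundary = m & ~interior
    idx = np.argwhere(boundary).astype(float)
    pts = np.asarray(origin, dtype=float) + idx * np.asarray(spacing, dtype=float)
    return SurfacePointSet(pts)


def _nearest_distances(a: SurfacePointSet, b: SurfacePointSet) -> np.ndarray:
    d, _ = cKDTree(b.points).query(a.points, k=1)
    return np.asarray(d, dtype=float)


def rms_surface_distance(pred: SurfacePointSet, truth: SurfacePointSet) -> float:
    """Directed prediction-to-reference RMS of nearest-surface distances (mm).

    ``sqrt(mean_x min_q |x - q|^2)`` over x in the prediction surface.  Note
    this is directed and therefore not symmetric in its arguments.
    """
    d = _nearest_distances(pred, truth)
    return float(np.sqrt(np.mean(d * d)))


def symmetric_mean_surface_distance(pred: SurfacePointSet, truth: SurfacePointSet) -> float:
    """Mean of the two directed RMS surface distances (informational)."""
    return 0.5 * (rms_surface_distance(pred, truth) + rms_surface_distance(truth, pred))


def hausdorff_distance(pred: SurfacePointSet, truth: SurfacePointSet) -> float:
    """Symmetric Hausdorff distance: max of the two directed max-min distances."""
    return float(max(_nearest_distances(pred, truth).max(),
                     _nearest_distances(truth, pred).max()))
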