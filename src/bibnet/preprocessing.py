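"""Spacing harmonization, axial downsampling and uint8 quantization.

Volumes from different scanners arrive at heterogeneous voxel spacings
(in-plane 0.98-1.27 mm, slice thickness 2.5-3 mm); they are first brought
to a common spacing by trilinear interpolation and then downsampled by an
integer factor in the axial plane to the working resolution.  Masks are
interpolated the same way and re-binarized at 0.5.

Conventions (the interpolation boundary rule and the output-shape rounding
are free choices here): sampling outside the source grid uses edge-value
extension, which avoids introducing spurious air at the body border, and
the output shape is ``ceil(shape * spacing / target_spacing)`` so no
physical extent is discarded.  The origin (first voxel centre) is
preserved.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

from .core_io import ImageGrid

__all__ = [
    "resample_trilinear",
    "resample_to_geometry",
    "downsample_axial",
    "resample_mask",
    "quantize_uint8",
]

Triple = tuple[float, float, float]


def resample_to_geometry(
    grid: ImageGrid,
    spacing: Triple,
    shape: tuple[int, int, int],
    origin: Triple | None = None,
) -> ImageGrid:
    """Trilinearly sample ``grid`` at the voxel centres of a target geometry."""
    if any(s <= 0 for s in spacing):
        raise ValueError(f"target spacing must be positive, got {spacing}")
    origin = grid.origin if origin is None else origin
    axes = [
        (origin[a] + spacing[a] * np.arange(shape[a]) - grid.origin[a]) / grid.spacing[a]
        for a in range(3)
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    out = map_coordinates(
        np.asarray(grid.values, dtype=np.float64),
        np.stack([m.ravel() for m in mesh]),
        order=1,
        mode="nearest",  # edge-value extension outside the source grid
    ).reshape(shape)
    return ImageGrid(out.astype(np.float32), tuple(spacing), tuple(origin))


def resample_trilinear(grid: ImageGrid, target_spacing: Triple) -> ImageGrid:
    """Resample to ``target_spacing`` (mm); shape follows the ceiling rule."""
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    shape = tuple(
        int(np.ceil(grid.shape[a] * grid.spacing[a] / target_spacing[a])) for a in range(3)
    )
    return resample_to_geometry(grid, tuple(target_spacing), shape, grid.origin)


def downsample_axial(grid: ImageGrid, factor: int) -> ImageGrid:
    """Coarsen the in-plane (x, y) spacing by an integer factor; z untouched."""
    factor = int(factor)
    if factor < 1:
        raise ValueError(f"downsampling factor must be >= 1, got {factor}")
    if factor == 1:
        return grid
    sx, sy, sz = grid.spacing
    return resample_trilinear(grid, (sx * factor, sy * factor, sz))


def resample_mask(mask: ImageGrid, target_spacing: Triple) -> ImageGrid:
    """Trilinear interpolation of the 0/1 field, re-binarized at 0.5."""
    vals = np.asarray(mask.values)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("resample_mask requires a binary mask")
    resampled = resample_trilinear(mask.with_values(vals.astype(np.float32)), target_spacing)
    return ImageGrid(
        (resampled.values >= 0.5).astype(np.uint8), resampled.spacing, resampled.origin
    )


def quantize_uint8(grid: ImageGrid, window: tuple[float, float] = (-1024.0, 1024.0)) -> ImageGrid:
    """Window intensities to [lo, hi], map linearly to 0..255 and round.

    Rounding is half-away-from-zero on the non-negative mapped scale
    (i.e. half-up), and values outside the window clip to 0/255.  The
    result is stored as uint8, the wire format used for inference inputs.
    """
    lo, hi = float(window[0]), float(window[1])
    if lo >= hi:
        raise ValueError(f"window must satisfy lo < hi, got {(lo, hi)}")
    scaled = (np.asarray(grid.values, dtype=np.float64) - lo) / (hi - lo) * 255.0
    out = np.floor(np.clip(scaled, 0.0, 255.0) + 0.5).clip(0, 255).astype(np.uint8)
    return ImageGrid(out, grid.spacing, grid.origin)
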