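"""Full-image and patch-wise inference plus the clinical post-processing chain.

The fully convolutional BibNet segments a whole volume in one forward pass
(padding internally when extents are not stride-divisible).  The baseline
valid-convolution U-Net instead tiles the volume: input windows are
shifted by exactly the output-patch size so the output patches abut, and
because every output voxel of a valid-convolution network depends only on
its own input window, the assembled result equals a single large pass over
the covered interior exactly.

Post-processing converts a working-resolution probability map into a
clinical-resolution mask: trilinear upsampling to the CT geometry,
spacing-aware Gaussian smoothing of the probabilities (to suppress
resampling aliasing), thresholding, and keeping the largest connected
component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import nn
from .core_io import ImageGrid
from .models import UNET3_MIN_INPUT, unet3_output_shape
from .preprocessing import resample_to_geometry
from .training import normalize_intensity

__all__ = [
    "PostprocessSpec",
    "infer_full_image",
    "infer_patchwise",
    "postprocess",
    "largest_component",
]

_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class PostprocessSpec:
    gaussian_sigma: float = 1.5        # mm
    binarize_threshold: float = 0.5
    connectivity: int = 26

    def __post_init__(self):
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if not (0.0 < self.binarize_threshold < 1.0):
            raise ValueError("binarize_threshold must lie in (0, 1)")
        if self.connectivity not in _CONNECTIVITY_STRUCTS:
            raise ValueError("connectivity must be one of 6, 18, 26")


def infer_full_image(
    net: nn.Module,
    grid: ImageGrid,
    window: tuple[float, float] = (-1024.0, 1024.0),
    normalize: bool = True,
) -> dict[str, ImageGrid]:
    """One forward pass over the whole volume; per-organ probability grids.

    The network runs in evaluation mode (dropout off, batch norm on running
    statistics), so repeated calls are bitwise identical.
    """
    net.eval()
    values = normalize_intensity(grid.values, window) if normalize else np.asarray(
        grid.values, dtype=np.float32
    )
    pred = net(nn.Tensor(values[None, None])).data[0]
    names = getattr(net, "output_names", tuple(f"organ_{i}" for i in range(pred.shape[0])))
    return {
        name: ImageGrid(pred[c], grid.spacing, grid.origin)
        for c, name in enumerate(names)
    }


def infer_patchwise(
    net: nn.Module,
    grid: ImageGrid,
    patch_size: tuple[int, int, int],
    window: tuple[float, float] = (-1024.0, 1024.0),
    normalize: bool = True,
) -> tuple[dict[str, ImageGrid], np.ndarray]:
    """Tile a volume with a valid-convolution network; abutting output tiles.

    Output patches are placed edge-to-edge (no averaging); voxels whose
    full input window would leave the volume are not covered.  Returns the
    per-organ probability grids (zero outside the covered interior) and a
    boolean validity mask flagging the covered region.
    """
    out_patch = unet3_output_shape(tuple(patch_size))
    margin = tuple((patch_size[a] - out_patch[a]) // 2 for a in range(3))
    shape = grid.shape
    if any(shape[a] < patch_size[a] for a in range(3)):
        raise ValueError(
            f"volume {shape} smaller than the inference patch {tuple(patch_size)} "
            f"(minimum admissible input extent is {UNET3_MIN_INPUT})"
        )
    net.eval()
    values = normalize_intensity(grid.values, window) if normalize else np.asarray(
        grid.values, dtype=np.float32
    )

    n_out = net.config.out_channels
    prob = np.zeros((n_out,) + shape, dtype=np.float32)
    valid = np.zeros(shape, dtype=bool)
    starts = []
    for a in range(3):
        # tile offsets stay multiples of the total pooling stride (4) so a
        # tile's internal pooling grid coincides with a single big pass
        last = shape[a] - patch_size[a]
        last -= last % 4
        pos = list(range(0, last + 1, out_patch[a]))
        if pos[-1] != last:
            pos.append(last)
        starts.append(pos)

    for sx in starts[0]:
        for sy in starts[1]:
            for sz in starts[2]:
                off = (sx, sy, sz)
                sl_in = tuple(slice(off[a], off[a] + patch_size[a]) for a in range(3))
                tile = net(nn.Tensor(values[sl_in][None, None])).data[0]
                sl_out = tuple(
                    slice(off[a] + margin[a], off[a] + margin[a] + out_patch[a])
                    for a in range(3)
                )
                prob[(slice(None),) + sl_out] = tile
                valid[sl_out] = True

    names = getattr(net, "output_names", tuple(f"organ_{i}" for i in range(n_out)))
    grids = {
        name: ImageGrid(prob[c], grid.spacing, grid.origin)
        for c, name in enumerate(names)
    }
    return grids, valid


def largest_component(mask: np.ndarray | ImageGrid, connectivity: int = 26) -> np.ndarray:
    """Voxels of the largest connected component (empty in -> empty out).

    Ties between equally large components break deterministically toward
    the component containing the lexicographically smallest voxel index,
    which is the lowest scipy label among the tied sizes.
    """
    arr = np.asarray(mask.values if isinstance(mask, ImageGrid) else mask).astype(bool)
    if not arr.any():
        return np.zeros_like(arr, dtype=np.uint8)
    labels, n = ndimage.label(arr, structure=_CONNECTIVITY_STRUCTS[connectivity])
    if n == 1:
        return arr.astype(np.uint8)
    sizes = ndimage.sum_labels(arr, labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1  # argmax returns the first (lowest) label on ties
    return (labels == best).astype(np.uint8)


def postprocess(
    prob: ImageGrid,
    target: ImageGrid,
    spec: PostprocessSpec = PostprocessSpec(),
) -> tuple[ImageGrid, bool]:
    """Probability map at working resolution -> binary mask at CT geometry.

    Pipeline: trilinear resample to the target geometry, Gaussian smoothing
    with a physical sigma (mm, divided by the per-axis spacing), threshold,
    largest connected component.  Smoothing acts on the probabilities
    before binarization.  Returns ``(mask, empty_flag)``; an empty result
    is returned with the flag set rather than raising, mirroring how
    failed segmentations are excluded rather than scored.
    """
    up = resample_to_geometry(prob, target.spacing, target.shape, target.origin)
    values = up.values
    if spec.gaussian_sigma > 0:
        sigma_vox = [spec.gaussian_sigma / s for s in target.spacing]
        values = ndimage.gaussian_filter(values, sigma=sigma_vox)
    binary = values >= spec.binarize_threshold
    component = largest_component(binary, spec.connectivity)
    mask = ImageGrid(component.astype(np.uint8), target.spacing, target.origin)
    return mask, not bool(component.any())
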