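"""Volume/mask data model, NIfTI I/O and patch extraction.

Axis convention
---------------
Arrays are indexed ``(x, y, z)`` throughout the package, matching the
radiological shorthand "256 x 256 x 128 (xyz)".  NIfTI stores data in
Fortran order with the affine mapping voxel indices to world millimetres;
we write a diagonal affine ``diag(sx, sy, sz)`` with the origin in the
fourth column, so the in-memory ``(x, y, z)`` array maps directly onto the
on-disk NIfTI payload with no axis permutation.  Voxel indices are 0-based
and the world coordinate of voxel ``(i, j, k)`` is
``origin + (i*sx, j*sy, k*sz)`` (voxel-centre convention).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "ImageGrid",
    "StructureSet",
    "Patch",
    "FormatError",
    "read_image",
    "write_image",
    "read_structure_set",
    "write_structure_set",
    "extract_patch",
]


class FormatError(ValueError):
    """Raised for files or arrays that violate the 3-D volume contract."""


@dataclass(frozen=True)
class ImageGrid:
    """A 3-D scalar intensity grid with physical spacing and origin (mm)."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise FormatError(f"ImageGrid requires a rank-3 array, got rank {values.ndim}")
        if not np.all(np.isfinite(values)):
            raise FormatError("ImageGrid values must be finite")
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise FormatError(f"spacing must be 3 positive numbers, got {spacing}")
        if len(origin) != 3:
            raise FormatError(f"origin must be a 3-vector, got {origin}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def with_values(self, values: np.ndarray) -> "ImageGrid":
        """Same geometry, new voxel data (shape may differ)."""
        return ImageGrid(values, self.spacing, self.origin)

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates (mm) of voxel centres."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a], dtype=float)
            for a in range(3)
        )  # type: ignore[return-value]

    def same_geometry(self, other: "ImageGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class StructureSet:
    """Named binary organ masks sharing one grid geometry."""

    masks: dict[str, ImageGrid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ref = None
        for name, grid in self.masks.items():
            vals = np.asarray(grid.values)
            if not np.isin(vals, (0, 1)).all():
                raise FormatError(f"mask {name!r} is not binary")
            if ref is None:
                ref = grid
            elif not grid.same_geometry(ref):
                raise FormatError(f"mask {name!r} does not share the reference geometry")

    @property
    def organs(self) -> list[str]:
        return list(self.masks)

    def __getitem__(self, organ: str) -> ImageGrid:
        return self.masks[organ]

    def __contains__(self, organ: str) -> bool:
        return organ in self.masks

    def stacked(self, organs: list[str] | None = None) -> np.ndarray:
        """Masks stacked into a (n_organs, x, y, z) uint8 array."""
        organs = self.organs if organs is None else organs
        return np.stack([np.asarray(self.masks[o].values, dtype=np.uint8) for o in organs])


@dataclass(frozen=True)
class Patch:
    """A sub-grid extracted at an integer voxel offset of a source grid."""

    values: np.ndarray
    offset: tuple[int, int, int]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def read_image(path: str | os.PathLike) -> ImageGrid:
    """Read a 3-D NIfTI volume into an :class:`ImageGrid`.

    Spacing is taken from the header zooms and the origin from the affine
    translation.  Raises :class:`FileNotFoundError` for a missing file and
    :class:`FormatError` for a non-3-D payload.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D payload, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageGrid(np.asarray(data), tuple(float(z) for z in zooms), origin)


def write_image(grid: ImageGrid, path: str | os.PathLike) -> None:
    """Write an :class:`ImageGrid` as NIfTI (.nii or .nii.gz).

    Binary masks should be passed as uint8 arrays, probabilities as
    float32; the array dtype is preserved on disk.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    img = nib.Nifti1Image(np.asarray(grid.values), _affine(grid.spacing, grid.origin))
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def read_structure_set(directory: str | os.PathLike, sidecar: str = "structures.json") -> StructureSet:
    """Read masks listed in a JSON sidecar mapping organ name -> filename."""
    directory = Path(directory)
    with open(directory / sidecar) as fh:
        mapping: Mapping[str, str] = json.load(fh)
    masks = {}
    for organ, fname in mapping.items():
        grid = read_image(directory / fname)
        masks[organ] = ImageGrid(
            np.asarray(grid.values, dtype=np.uint8), grid.spacing, grid.origin
        )
    return StructureSet(masks)


def write_structure_set(
    structures: StructureSet, directory: str | os.PathLike, sidecar: str = "structures.json"
) -> None:
    """Write each mask as uint8 NIfTI plus the organ->filename JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mapping = {}
    for organ, grid in structures.masks.items():
        fname = f"{organ}.nii.gz"
        write_image(
            ImageGrid(np.asarray(grid.values, dtype=np.uint8), grid.spacing, grid.origin),
            directory / fname,
        )
        mapping[organ] = fname
    with open(directory / sidecar, "w") as fh:
        json.dump(mapping, fh, indent=1, sort_keys=True)


def extract_patch(
    grid: ImageGrid, offset: tuple[int, int, int], size: tuple[int, int, int]
) -> Patch:
    """Extract the sub-array of ``size`` voxels starting at ``offset``.

    Out-of-bounds requests raise :class:`IndexError`; there is no silent
    clipping.
    """
    offset = tuple(int(v) for v in offset)
    size = tuple(int(v) for v in size)
    shape = grid.shape
    for a in range(3):
        if offset[a] < 0 or size[a] < 1 or offset[a] + size[a] > shape[a]:
            raise IndexError(
                f"patch offset={offset} size={size} out of bounds for grid shape {shape}"
            )
    sl = tuple(slice(offset[a], offset[a] + size[a]) for a in range(3))
    return Patch(values=grid.values[sl], offset=offset)
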