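"""Training-patch samplers: entropy, shell (mm from a structure surface), mask.

Patch-wise training on large volumes wastes most draws on uninformative
air unless sampling is steered.  Three admissibility rules are provided,
plus a weighted composite that mixes them:

* entropy — the uint8 intensity histogram of the candidate patch must
  exceed an entropy threshold (rejects flat regions such as air),
* shell — the patch centre must lie within a given physical distance
  (mm, inside or outside) of a ground-truth structure surface,
* mask — the patch must intersect the ground-truth structure.

Admissibility is anchored on the patch CENTRE voxel for the shell rule;
all randomness flows from the caller-supplied generator so a draw
sequence is reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core_io import ImageGrid, Patch, StructureSet, extract_patch
from .metrics import EmptyMaskError, surface_points
from .preprocessing import quantize_uint8

__all__ = [
    "SamplerConfig",
    "SamplerExhausted",
    "patch_entropy",
    "sample_entropy",
    "sample_shell",
    "sample_mask",
    "composite_sampler",
    "surface_distance_map",
]


class SamplerExhausted(RuntimeError):
    """No admissible patch position found within the rejection budget."""


@dataclass(frozen=True)
class SamplerConfig:
    patch_size: tuple[int, int, int] = (32, 32, 16)
    entropy_threshold: float = 2.0            # bits
    shell_distances: tuple[float, ...] = (20.0, 40.0)   # mm
    # weights over (entropy, shell@d1, shell@d2, ..., mask)
    sampler_weights: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    quantize_window: tuple[float, float] = (-1024.0, 1024.0)
    max_rejections: int = 10_000

    def __post_init__(self):
        if len(self.sampler_weights) != 2 + len(self.shell_distances):
            raise ValueError(
                "sampler_weights needs one weight for the entropy sampler, one per "
                "shell distance and one for the mask sampler"
            )
        if any(w < 0 for w in self.sampler_weights) or sum(self.sampler_weights) <= 0:
            raise ValueError("sampler_weights must be nonnegative with positive sum")
        if any(s < 1 for s in self.patch_size):
            raise ValueError("patch_size must be positive")


def patch_entropy(patch: Patch | np.ndarray,
                  window: tuple[float, float] = (-1024.0, 1024.0)) -> float:
    """Shannon entropy (bits) of the 256-bin uint8 intensity histogram."""
    values = patch.values if isinstance(patch, Patch) else np.asarray(patch)
    if values.size == 0:
        raise ValueError("patch is empty")
    q = quantize_uint8(ImageGrid(np.atleast_3d(values).astype(np.float32)), window).values
    counts = np.bincount(q.ravel(), minlength=256)
    f = counts[counts > 0] / q.size
    return float(-(f * np.log2(f)).sum())


def _offsets(grid_shape, patch_size) -> tuple[np.ndarray, ...]:
    """Valid offset range per axis (inclusive upper bound + 1)."""
    hi = tuple(grid_shape[a] - patch_size[a] for a in range(3))
    if any(h < 0 for h in hi):
        raise ValueError(f"patch {patch_size} does not fit in volume {grid_shape}")
    return hi


def _random_offset(hi, rng: np.random.Generator) -> tuple[int, int, int]:
    return tuple(int(rng.integers(0, h + 1)) for h in hi)


def _center(offset, patch_size) -> tuple[int, ...]:
    return tuple(offset[a] + patch_size[a] // 2 for a in range(3))


def sample_entropy(grid: ImageGrid, cfg: SamplerConfig, rng: np.random.Generator) -> Patch:
    """Uniform draw over patch positions whose entropy exceeds the threshold."""
    hi = _offsets(grid.shape, cfg.patch_size)
    for _ in range(cfg.max_rejections):
        off = _random_offset(hi, rng)
        patch = extract_patch(grid, off, cfg.patch_size)
        if patch_entropy(patch, cfg.quantize_window) > cfg.entropy_threshold:
            return patch
    raise SamplerExhausted(
        f"no patch with entropy > {cfg.entropy_threshold} bits in "
        f"{cfg.max_rejections} draws"
    )


def surface_distance_map(mask: ImageGrid) -> np.ndarray:
    """Per-voxel Euclidean distance (mm) to the mask's surface-voxel centres."""
    pts = surface_points(mask).points
    axes = mask.world_coordinates()
    mesh = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([m.ravel() for m in mesh], axis=1)
    d, _ = cKDTree(pts).query(coords, k=1)
    return d.reshape(mask.shape)


def sample_shell(
    grid: ImageGrid,
    mask: ImageGrid,
    distance: float,
    cfg: SamplerConfig,
    rng: np.random.Generator,
    dmap: np.ndarray | None = None,
) -> Patch:
    """Patch whose centre voxel lies within ``distance`` mm of the mask surface.

    Distances are true Euclidean millimetres under the (possibly
    anisotropic) voxel spacing, measured to surface voxel centres, on
    either side of the surface.  Admissible centres are enumerated once,
    so the draw is uniform over them.
    """
    if not np.asarray(mask.values).any():
        raise EmptyMaskError("shell sampler requires a nonempty mask")
    hi = _offsets(grid.shape, cfg.patch_size)
    if dmap is None:
        dmap = surface_distance_map(mask)
    half = tuple(cfg.patch_size[a] // 2 for a in range(3))
    window = dmap[
        half[0] : half[0] + hi[0] + 1,
        half[1] : half[1] + hi[1] + 1,
        half[2] : half[2] + hi[2] + 1,
    ]
    admissible = np.argwhere(window <= distance)
    if admissible.shape[0] == 0:
        raise SamplerExhausted(f"no admissible centre within {distance} mm of the surface")
    off = tuple(int(v) for v in admissible[rng.integers(0, admissible.shape[0])])
    return extract_patch(grid, off, cfg.patch_size)


def sample_mask(
    grid: ImageGrid, mask: ImageGrid, cfg: SamplerConfig, rng: np.random.Generator
) -> Patch:
    """Patch intersecting the ground-truth structure in >= 1 voxel."""
    m = np.asarray(mask.values).astype(bool)
    if not m.any():
        raise EmptyMaskError("mask sampler requires a nonempty mask")
    hi = _offsets(grid.shape, cfg.patch_size)
    for _ in range(cfg.max_rejections):
        off = _random_offset(hi, rng)
        sl = tuple(slice(off[a], off[a] + cfg.patch_size[a]) for a in range(3))
        if m[sl].any():
            return extract_patch(grid, off, cfg.patch_size)
    raise SamplerExhausted(f"no intersecting patch in {cfg.max_rejections} draws")


def composite_sampler(
    grid: ImageGrid,
    structures: StructureSet,
    cfg: SamplerConfig,
    rng: np.random.Generator,
    organs: tuple[str, ...] | None = None,
    stats: dict[str, int] | None = None,
):
    """Infinite stream of (image patch, label patch) pairs.

    Each draw picks one sampler by the configured weights (entropy, one
    shell sampler per distance, mask), then the structure-conditioned
    samplers pick a structure uniformly.  The label patch is the stacked
    ground-truth crop at the same offset, shape ``(n_organs, *patch_size)``.
    If ``stats`` is given, per-sampler draw counts are accumulated into it.
    Surface-distance maps are computed once per organ and reused.
    """
    organs = tuple(organs if organs is not None else structures.organs)
    labels = structures.stacked(list(organs))
    w = np.asarray(cfg.sampler_weights, dtype=float)
    w = w / w.sum()
    n_shell = len(cfg.shell_distances)
    dmaps: dict[str, np.ndarray] = {}
    while True:
        choice = int(rng.choice(len(w), p=w))
        if choice == 0:
            name = "entropy"
            patch = sample_entropy(grid, cfg, rng)
        else:
            organ = organs[int(rng.integers(0, len(organs)))]
            if choice <= n_shell:
                name = f"shell_{cfg.shell_distances[choice - 1]:g}mm"
                if organ not in dmaps:
                    dmaps[organ] = surface_distance_map(structures[organ])
                patch = sample_shell(
                    grid, structures[organ], cfg.shell_distances[choice - 1],
                    cfg, rng, dmap=dmaps[organ],
                )
            else:
                name = "mask"
                patch = sample_mask(grid, structures[organ], cfg, rng)
        if stats is not None:
            stats[name] = stats.get(name, 0) + 1
        off = patch.offset
        sl = (slice(None),) + tuple(
            slice(off[a], off[a] + cfg.patch_size[a]) for a in range(3)
        )
        yield patch, labels[sl]
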