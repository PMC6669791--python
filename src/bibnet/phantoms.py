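"""Seeded thorax-like phantom volumes with ground-truth organ masks.

Each phantom is a CT-like intensity grid: an ellipsoidal soft-tissue body
on an air background, two low-intensity lung ellipsoids, a heart ellipsoid
between the lungs and two anterior breast ellipsoids, plus additive
Gaussian noise.  Intensities are Hounsfield-like class means (air ~ -1000,
lung ~ -700, body fat ~ -100, soft tissue ~ 40) so intensity windowing
downstream is exercised realistically.  Ground truth is returned as a
:class:`~bibnet.core_io.StructureSet` with masks ``left_breast``,
``right_breast`` and ``heart``.

Axes are (x, y, z) with x running right -> left, y anterior -> posterior
and z inferior -> superior; the default grid is 64 x 64 x 32 voxels at
(2.34, 2.34, 3.0) mm, a scaled-down working resolution that keeps every
downstream stage trainable on one CPU.

Cohorts jitter each case's geometry (multiplicative per-axis radius
jitter, additive centre jitter, both uniform and seeded), standing in for
anatomical variation between patients.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core_io import ImageGrid, StructureSet

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "GeometryError",
    "generate_phantom",
    "generate_cohort",
    "cohort_case_spec",
    "ORGAN_NAMES",
]

ORGAN_NAMES = ("left_breast", "right_breast", "heart")


class GeometryError(ValueError):
    """Raised when an organ does not fit inside the body."""


Triple = tuple[float, float, float]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry (mm), tissue intensities and noise level of one phantom."""

    shape: tuple[int, int, int] = (64, 64, 32)
    spacing: Triple = (2.34, 2.34, 3.0)
    origin: Triple = (0.0, 0.0, 0.0)

    # geometry: centres relative to the volume centre, radii absolute (mm)
    body_radii: Triple = (70.0, 58.0, 95.0)
    lung_radii: Triple = (24.0, 30.0, 55.0)
    lung_separation: float = 33.0         # |x| offset of each lung centre
    lung_shift: Triple = (0.0, 8.0, 0.0)
    heart_radii: Triple = (20.0, 18.0, 22.0)
    heart_center: Triple = (-4.0, 4.0, -4.0)
    breast_radii: Triple = (14.0, 11.0, 16.0)
    breast_separation: float = 28.0       # |x| offset of each breast centre
    breast_depth: float = -30.0           # anterior y offset of breast centres

    # per-case cohort jitter
    radius_jitter: float = 0.08           # multiplicative, U(1-j, 1+j) per axis
    center_jitter: float = 3.0            # additive mm, U(-j, j) per axis

    # tissue class mean intensities (HU-like) and noise
    intensity_air: float = -1000.0
    intensity_lung: float = -700.0
    intensity_fat: float = -100.0
    intensity_soft: float = 40.0
    noise_sd: float = 20.0

    seed: int = 0

    def __post_init__(self):
        if len(self.shape) != 3 or any(
            s < m for s, m in zip(self.shape, (16, 16, 8))
        ):
            raise ValueError(f"shape must be at least (16, 16, 8), got {self.shape}")
        radii = (self.body_radii, self.lung_radii, self.heart_radii, self.breast_radii)
        if any(r <= 0 for triple in radii for r in triple):
            raise ValueError("all radii must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.radius_jitter < 1):
            raise ValueError("radius_jitter must be in [0, 1)")

    @property
    def extent(self) -> Triple:
        return tuple(self.shape[a] * self.spacing[a] for a in range(3))  # type: ignore

    @property
    def volume_center(self) -> Triple:
        return tuple(self.origin[a] + 0.5 * self.extent[a] for a in range(3))  # type: ignore

    def jittered(self, rng: np.random.Generator, seed: int) -> "PhantomSpec":
        """A per-case copy with jittered radii/centres and the given noise seed."""
        def jr(radii):
            f = rng.uniform(1 - self.radius_jitter, 1 + self.radius_jitter, 3)
            return tuple(float(r * fi) for r, fi in zip(radii, f))

        def jc(center):
            d = rng.uniform(-self.center_jitter, self.center_jitter, 3)
            return tuple(float(c + di) for c, di in zip(center, d))

        return replace(
            self,
            body_radii=jr(self.body_radii),
            lung_radii=jr(self.lung_radii),
            heart_radii=jr(self.heart_radii),
            heart_center=jc(self.heart_center),
            breast_radii=jr(self.breast_radii),
            lung_separation=float(
                self.lung_separation * rng.uniform(1 - self.radius_jitter, 1 + self.radius_jitter)
            ),
            breast_separation=float(
                self.breast_separation * rng.uniform(1 - self.radius_jitter, 1 + self.radius_jitter)
            ),
            breast_depth=float(self.breast_depth + rng.uniform(-self.center_jitter, self.center_jitter)),
            seed=int(seed),
        )


@dataclass(frozen=True)
class PhantomCase:
    case_id: str
    image: ImageGrid
    structures: StructureSet
    spec: PhantomSpec


def _ellipsoid(coords, center: Triple, radii: Triple) -> np.ndarray:
    x, y, z = coords
    q = (
        ((x - center[0]) / radii[0])[:, None, None] ** 2
        + (((y - center[1]) / radii[1]) ** 2)[None, :, None]
        + (((z - center[2]) / radii[2]) ** 2)[None, None, :]
    )
    return q <= 1.0


def generate_phantom(
    spec: PhantomSpec, include_body: bool = False
) -> tuple[ImageGrid, StructureSet]:
    """Render one phantom; bitwise deterministic for a fixed spec.

    Raises :class:`GeometryError` when any organ voxel falls outside the
    body or the organ masks collide.
    """
    geom = dict(spacing=spec.spacing, origin=spec.origin)
    coords = ImageGrid(np.zeros(spec.shape, np.float32), **geom).world_coordinates()
    cx, cy, cz = spec.volume_center

    body = _ellipsoid(coords, (cx, cy, cz), spec.body_radii)

    lungs = {}
    for sign, side in ((+1, "left"), (-1, "right")):
        center = (
            cx + sign * spec.lung_separation + spec.lung_shift[0],
            cy + spec.lung_shift[1],
            cz + spec.lung_shift[2],
        )
        lungs[side] = _ellipsoid(coords, center, spec.lung_radii)

    heart = _ellipsoid(
        coords,
        tuple(c + d for c, d in zip((cx, cy, cz), spec.heart_center)),
        spec.heart_radii,
    )

    breasts = {}
    for sign, side in ((+1, "left"), (-1, "right")):
        center = (cx + sign * spec.breast_separation, cy + spec.breast_depth, cz)
        breasts[side] = _ellipsoid(coords, center, spec.breast_radii)

    organs = {
        "left_breast": breasts["left"],
        "right_breast": breasts["right"],
        "heart": heart,
    }
    for name, mask in organs.items():
        outside = int(np.count_nonzero(mask & ~body))
        if outside:
            raise GeometryError(
                f"{name} does not fit inside the body ({outside} voxels outside)"
            )
    if (organs["left_breast"] & organs["right_breast"]).any():
        raise GeometryError("left and right breast masks overlap")
    for side in ("left_breast", "right_breast"):
        if (organs[side] & heart).any():
            raise GeometryError(f"{side} overlaps the heart")

    image = np.full(spec.shape, spec.intensity_air, dtype=np.float32)
    image[body] = spec.intensity_fat
    image[lungs["left"] | lungs["right"]] = spec.intensity_lung
    image[heart] = spec.intensity_soft
    image[breasts["left"] | breasts["right"]] = spec.intensity_soft
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sd, spec.shape).astype(np.float32)

    masks = {name: ImageGrid(m.astype(np.uint8), **geom) for name, m in organs.items()}
    if include_body:
        masks["body"] = ImageGrid(body.astype(np.uint8), **geom)
    return ImageGrid(image, **geom), StructureSet(masks)


def cohort_case_spec(spec: PhantomSpec, seed: int, index: int) -> PhantomSpec:
    """The jittered per-case spec for cohort member ``index`` (reproducible)."""
    root = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    case_seeds = root.integers(0, 2**31 - 1, size=index + 1)
    case_rng = np.random.default_rng(int(case_seeds[index]))
    return spec.jittered(case_rng, seed=int(case_seeds[index]))


def generate_cohort(spec: PhantomSpec, n: int, seed: int) -> list[PhantomCase]:
    """``n`` phantoms with per-case jittered geometry, reproducible from seed."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    root = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    case_seeds = root.integers(0, 2**31 - 1, size=n)
    cases = []
    for i in range(n):
        case_rng = np.random.default_rng(int(case_seeds[i]))
        cspec = spec.jittered(case_rng, seed=int(case_seeds[i]))
        image, structures = generate_phantom(cspec)
        cases.append(PhantomCase(f"case_{i:03d}", image, structures, cspec))
    return cases
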