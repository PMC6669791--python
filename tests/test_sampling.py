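import numpy as np
import pytest

from bibnet.core_io import ImageGrid, Patch, StructureSet
from bibnet.metrics import EmptyMaskError
from bibnet.sampling import (
    SamplerConfig,
    SamplerExhausted,
    composite_sampler,
    patch_entropy,
    sample_entropy,
    sample_mask,
    sample_shell,
    surface_distance_map,
)


@pytest.fixture
def toy_volume():
    """Left half air, right half structured tissue."""
    rng = np.random.default_rng(7)
    values = np.full((24, 12, 8), -1000.0, dtype=np.float32)
    values[12:] = rng.uniform(-200.0, 200.0, size=(12, 12, 8)).astype(np.float32)
    return ImageGrid(values, spacing=(2.0, 2.0, 3.0))


@pytest.fixture
def sphere_mask():
    idx = np.indices((24, 12, 8)).astype(float)
    center = np.array([16.0, 6.0, 4.0])
    r = np.sqrt(((idx - center[:, None, None, None]) ** 2).sum(axis=0))
    mask = (r <= 2.5).astype(np.uint8)
    return ImageGrid(mask, spacing=(2.0, 2.0, 3.0))


def cfg(**kw):
    defaults = dict(patch_size=(6, 6, 4), entropy_threshold=2.0)
    defaults.update(kw)
    return SamplerConfig(**defaults)


class TestPatchEntropy:
    def test_constant_patch_zero_bits(self):
        assert patch_entropy(Patch(np.zeros((4, 4, 4)), (0, 0, 0))) == 0.0

    def test_two_equal_symbols_one_bit(self):
        values = np.zeros((4, 4, 2))
        values[..., 1] = 1024.0  # maps to a distinct uint8 bin
        assert patch_entropy(Patch(values, (0, 0, 0))) == pytest.approx(1.0)

    def test_matches_histogram_formula(self, rng):
        values = rng.uniform(-1024, 1024, size=(6, 6, 6))
        scaled = np.floor(np.clip((values + 1024) * 255 / 2048, 0, 255) + 0.5)
        counts = np.bincount(scaled.astype(int).ravel(), minlength=256)
        f = counts[counts > 0] / scaled.size
        expected = float(-(f * np.log2(f)).sum())
        assert patch_entropy(Patch(values, (0, 0, 0))) == pytest.approx(expected, abs=1e-12)


class TestEntropySampler:
    def test_zero_threshold_accepts_everywhere(self, toy_volume):
        sampler_cfg = cfg(entropy_threshold=-1.0)
        rng = np.random.default_rng(0)
        patch = sample_entropy(toy_volume, sampler_cfg, rng)
        assert patch.shape == (6, 6, 4)

    def test_impossible_threshold_exhausts(self, toy_volume):
        sampler_cfg = cfg(entropy_threshold=9.0, max_rejections=200)
        with pytest.raises(SamplerExhausted):
            sample_entropy(toy_volume, sampler_cfg, np.random.default_rng(0))

    def test_accepted_patches_avoid_plain_air(self, toy_volume):
        """Every accepted offset lies in the exhaustively enumerated
        admissible set."""
        sampler_cfg = cfg(entropy_threshold=2.0)
        admissible = set()
        from bibnet.core_io import extract_patch

        for ox in range(toy_volume.shape[0] - 6 + 1):
            for oy in range(toy_volume.shape[1] - 6 + 1):
                for oz in range(toy_volume.shape[2] - 4 + 1):
                    p = extract_patch(toy_volume, (ox, oy, oz), (6, 6, 4))
                    if patch_entropy(p) > 2.0:
                        admissible.add((ox, oy, oz))
        rng = np.random.default_rng(1)
        for _ in range(200):
            patch = sample_entropy(toy_volume, sampler_cfg, rng)
            assert patch.offset in admissible


class TestShellSampler:
    def test_infinite_distance_admits_any_centre(self, toy_volume, sphere_mask):
        patch = sample_shell(toy_volume, sphere_mask, np.inf, cfg(), np.random.default_rng(0))
        assert patch.shape == (6, 6, 4)

    def test_empty_mask_rejected(self, toy_volume):
        empty = ImageGrid(np.zeros((24, 12, 8), np.uint8), spacing=(2.0, 2.0, 3.0))
        with pytest.raises(EmptyMaskError):
            sample_shell(toy_volume, empty, 20.0, cfg(), np.random.default_rng(0))

    def test_admissible_centres_match_brute_force(self, toy_volume, sphere_mask):
        """Shell admissibility equals exhaustive per-voxel thresholding of
        the distance to surface-voxel centres (anisotropic mm)."""
        from bibnet.metrics import surface_points

        distance = 10.0
        pts = surface_points(sphere_mask).points
        dmap = surface_distance_map(sphere_mask)
        # oracle: per-voxel min distance over all surface points
        for _ in range(50):
            rng = np.random.default_rng(_)
            patch = sample_shell(toy_volume, sphere_mask, distance, cfg(), rng)
            cx, cy, cz = (patch.offset[a] + (6, 6, 4)[a] // 2 for a in range(3))
            world = np.array([cx * 2.0, cy * 2.0, cz * 3.0])
            brute = np.sqrt(((pts - world) ** 2).sum(axis=1)).min()
            assert brute <= distance + 1e-9
            assert dmap[cx, cy, cz] == pytest.approx(brute, abs=1e-9)

    def test_surface_centre_always_admissible(self, toy_volume, sphere_mask):
        dmap = surface_distance_map(sphere_mask)
        surface_voxels = np.argwhere(dmap == 0.0)
        assert len(surface_voxels) > 0


class TestMaskSampler:
    def test_full_mask_any_patch(self, toy_volume):
        full = ImageGrid(np.ones((24, 12, 8), np.uint8), spacing=(2.0, 2.0, 3.0))
        patch = sample_mask(toy_volume, full, cfg(), np.random.default_rng(0))
        assert patch.shape == (6, 6, 4)

    def test_returned_patches_always_intersect(self, toy_volume, sphere_mask):
        rng = np.random.default_rng(2)
        m = sphere_mask.values.astype(bool)
        for _ in range(200):
            patch = sample_mask(toy_volume, sphere_mask, cfg(), rng)
            o = patch.offset
            assert m[o[0]:o[0]+6, o[1]:o[1]+6, o[2]:o[2]+4].any()

    def test_single_voxel_mask_offset_window(self, toy_volume):
        """Admissible offsets for a single-voxel mask are exactly the
        window of offsets whose patch contains it."""
        mask = np.zeros((24, 12, 8), np.uint8)
        mask[10, 5, 3] = 1
        grid_mask = ImageGrid(mask, spacing=(2.0, 2.0, 3.0))
        expected = set()
        for ox in range(24 - 6 + 1):
            for oy in range(12 - 6 + 1):
                for oz in range(8 - 4 + 1):
                    if ox <= 10 < ox + 6 and oy <= 5 < oy + 6 and oz <= 3 < oz + 4:
                        expected.add((ox, oy, oz))
        rng = np.random.default_rng(3)
        seen = set()
        for _ in range(300):
            seen.add(sample_mask(toy_volume, grid_mask, cfg(), rng).offset)
        assert seen <= expected


class TestCompositeSampler:
    def _structures(self, sphere_mask):
        return StructureSet({"heart": sphere_mask})

    def test_pure_entropy_weights(self, toy_volume, sphere_mask):
        sampler_cfg = cfg(sampler_weights=(1.0, 0.0, 0.0, 0.0), entropy_threshold=-1.0)
        rng = np.random.default_rng(4)
        stream = composite_sampler(toy_volume, self._structures(sphere_mask), sampler_cfg, rng)
        rng_ref = np.random.default_rng(4)
        for _ in range(20):
            patch, label = next(stream)
            assert label.shape == (1, 6, 6, 4)

    def test_label_patch_shares_offset(self, toy_volume, sphere_mask):
        structures = self._structures(sphere_mask)
        stream = composite_sampler(toy_volume, structures, cfg(entropy_threshold=-1.0),
                                   np.random.default_rng(5))
        stacked = structures.stacked(["heart"])
        for _ in range(50):
            patch, label = next(stream)
            o = patch.offset
            np.testing.assert_array_equal(
                label[0], stacked[0, o[0]:o[0]+6, o[1]:o[1]+6, o[2]:o[2]+4]
            )

    def test_equal_weights_frequencies(self, toy_volume, sphere_mask):
        """Sampler pick frequencies over 4000 draws stay within 3 sigma of
        1/4 under equal weights (multinomial bound)."""
        n = 4000
        stats: dict[str, int] = {}
        sampler_cfg = cfg(entropy_threshold=-1.0, shell_distances=(10.0, 20.0))
        stream = composite_sampler(toy_volume, self._structures(sphere_mask), sampler_cfg,
                                   np.random.default_rng(6), stats=stats)
        for _ in range(n):
            next(stream)
        assert sum(stats.values()) == n
        sigma = np.sqrt(n * 0.25 * 0.75)
        for name in ("entropy", "shell_10mm", "shell_20mm", "mask"):
            assert abs(stats[name] - n * 0.25) <= 3 * sigma, stats

    def test_deterministic_given_seed(self, toy_volume, sphere_mask):
        structures = self._structures(sphere_mask)
        a = composite_sampler(toy_volume, structures, cfg(entropy_threshold=-1.0),
                              np.random.default_rng(8))
        b = composite_sampler(toy_volume, structures, cfg(entropy_threshold=-1.0),
                              np.random.default_rng(8))
        for _ in range(30):
            pa, la = next(a)
            pb, lb = next(b)
            assert pa.offset == pb.offset
            np.testing.assert_array_equal(la, lb)


class TestSamplerConfig:
    def test_weight_length_validated(self):
        with pytest.raises(ValueError):
            SamplerConfig(sampler_weights=(1.0, 1.0))
        with pytest.raises(ValueError):
            SamplerConfig(sampler_weights=(0.0, 0.0, 0.0, 0.0))
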