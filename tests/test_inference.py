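import numpy as np
import pytest
from scipy import ndimage

from bibnet import nn
from bibnet.core_io import ImageGrid
from bibnet.inference import (
    PostprocessSpec,
    infer_full_image,
    infer_patchwise,
    largest_component,
    postprocess,
)
from bibnet.models import BibNetConfig, UNetConfig, build_bibnet, build_unet3
from bibnet.training import normalize_intensity


@pytest.fixture(scope="module")
def micro_bibnet():
    cfg = BibNetConfig(
        n_levels=2, base_filters=2, enc_blocks=(1, 1), lat_blocks=(1, 1),
        dec_blocks=(1,), dropout_rate=0.3, out_channels=3, seed=8,
    )
    return build_bibnet(cfg)


@pytest.fixture(scope="module")
def unet():
    return build_unet3(UNetConfig(seed=4))


class TestFullImageInference:
    def test_probability_grids_cover_volume(self, micro_bibnet, noisy_phantom):
        img, _ = noisy_phantom
        probs = infer_full_image(micro_bibnet, img)
        assert set(probs) == {"left_breast", "right_breast", "heart"}
        for grid in probs.values():
            assert grid.shape == img.shape
            assert grid.spacing == img.spacing
            assert 0.0 <= grid.values.min() and grid.values.max() <= 1.0

    def test_repeat_calls_bitwise_identical(self, micro_bibnet, noisy_phantom):
        img, _ = noisy_phantom
        a = infer_full_image(micro_bibnet, img)
        b = infer_full_image(micro_bibnet, img)
        for organ in a:
            np.testing.assert_array_equal(a[organ].values, b[organ].values)

    def test_constant_input_translation_invariant_interior(self, micro_bibnet):
        # constant input: the interior is periodic with the pooling stride
        # (transpose convolutions tile their kernel), so equality holds per
        # phase of the stride-2 lattice
        # voxels further than the receptive-field half-width from every
        # border are unaffected by padding
        grid = ImageGrid(np.zeros((32, 32, 32), dtype=np.float32))
        probs = infer_full_image(micro_bibnet, grid)
        inner = probs["heart"].values[10:22, 10:22, 10:22]
        for px in range(2):
            for py in range(2):
                for pz in range(2):
                    phase = inner[px::2, py::2, pz::2]
                    assert phase.std() < 1e-3


class TestPatchwiseInference:
    def test_single_patch_equals_direct_pass(self, unet):
        rng = np.random.default_rng(0)
        grid = ImageGrid(rng.normal(0, 300, size=(44, 44, 44)).astype(np.float32))
        probs, valid = infer_patchwise(unet, grid, (44, 44, 44))
        direct = unet(nn.Tensor(normalize_intensity(grid.values)[None, None])).data[0, 0]
        got = probs["organ_0"].values[20:24, 20:24, 20:24]
        np.testing.assert_array_equal(got, direct)
        assert valid.sum() == 4 * 4 * 4

    def test_tiles_match_big_pass_exactly(self, unet):
        """Abutting output tiles equal a single large forward pass on the
        covered interior with zero tolerance."""
        rng = np.random.default_rng(1)
        grid = ImageGrid(rng.normal(0, 300, size=(56, 52, 48)).astype(np.float32))
        probs, valid = infer_patchwise(unet, grid, (48, 48, 48))
        big = unet(nn.Tensor(normalize_intensity(grid.values)[None, None])).data[0, 0]
        # big pass covers voxels [20, shape-20); compare where both cover
        interior = np.zeros(grid.shape, bool)
        interior[20:36, 20:32, 20:28] = True
        both = interior & valid
        assert both.any()
        patch_vals = probs["organ_0"].values[both]
        big_full = np.zeros(grid.shape, np.float32)
        big_full[20:36, 20:32, 20:28] = big
        np.testing.assert_array_equal(patch_vals, big_full[both])

    def test_undersized_patch_rejected(self, unet):
        grid = ImageGrid(np.zeros((48, 48, 48), dtype=np.float32))
        with pytest.raises(ValueError):
            infer_patchwise(unet, grid, (40, 40, 40))

    def test_volume_smaller_than_patch_rejected(self, unet):
        grid = ImageGrid(np.zeros((32, 32, 32), dtype=np.float32))
        with pytest.raises(ValueError):
            infer_patchwise(unet, grid, (44, 44, 44))


class TestLargestComponent:
    def test_single_component_unchanged(self):
        m = np.zeros((10, 10, 5), np.uint8)
        m[2:5, 2:5, 1:4] = 1
        np.testing.assert_array_equal(largest_component(m), m)

    def test_keeps_bigger_of_two(self):
        m = np.zeros((20, 10, 5), np.uint8)
        m[1:6, 1:6, 1:5] = 1          # 100 voxels
        m[15:16, 8:9, 0:5] = 1        # 5 voxels
        out = largest_component(m)
        assert out.sum() == 100
        assert out[15, 8, 2] == 0

    def test_empty_in_empty_out(self):
        z = np.zeros((4, 4, 4), np.uint8)
        np.testing.assert_array_equal(largest_component(z), z)

    def test_matches_flood_fill_oracle(self, rng):
        for trial in range(10):
            m = (rng.random((12, 12, 8)) < 0.25).astype(np.uint8)
            if not m.any():
                continue
            got = largest_component(m, connectivity=26)
            labels, n = ndimage.label(m, structure=np.ones((3, 3, 3)))
            sizes = [(labels == i).sum() for i in range(1, n + 1)]
            assert got.sum() == max(sizes)
            # the kept voxels are a single connected component of the input
            relabel, k = ndimage.label(got, structure=np.ones((3, 3, 3)))
            assert k == 1


class TestPostprocess:
    def _prob_grid(self):
        values = np.zeros((20, 20, 10), np.float32)
        values[4:10, 4:10, 3:7] = 0.9
        return ImageGrid(values, spacing=(2.0, 2.0, 2.0))

    def test_sigma_zero_is_resample_threshold(self):
        prob = self._prob_grid()
        target = ImageGrid(np.zeros((40, 40, 20), np.float32), spacing=(1.0, 1.0, 1.0))
        spec = PostprocessSpec(gaussian_sigma=0.0, binarize_threshold=0.5)
        mask, empty = postprocess(prob, target, spec)
        assert not empty
        from bibnet.preprocessing import resample_to_geometry

        up = resample_to_geometry(prob, target.spacing, target.shape, target.origin)
        expected = largest_component(up.values >= 0.5)
        np.testing.assert_array_equal(mask.values, expected)

    def test_small_blob_removed(self):
        values = np.zeros((30, 30, 10), np.float32)
        values[2:12, 2:12, 2:7] = 0.95    # 500 voxels
        values[25:29, 25:29, 6:8] = 0.95  # 32 voxels (well separated)
        prob = ImageGrid(values, spacing=(1.0, 1.0, 1.0))
        mask, _ = postprocess(prob, prob, PostprocessSpec(gaussian_sigma=0.0))
        assert mask.values[5, 5, 4] == 1
        assert mask.values[27, 27, 6] == 0

    def test_output_single_component_or_empty(self, rng):
        values = (rng.random((16, 16, 8)) < 0.3).astype(np.float32) * 0.8
        prob = ImageGrid(values, spacing=(2.0, 2.0, 2.0))
        mask, empty = postprocess(prob, prob, PostprocessSpec(gaussian_sigma=1.0))
        if not empty:
            _, n = ndimage.label(mask.values, structure=np.ones((3, 3, 3)))
            assert n == 1

    def test_empty_result_flagged(self):
        prob = ImageGrid(np.zeros((10, 10, 10), np.float32))
        mask, empty = postprocess(prob, prob, PostprocessSpec())
        assert empty
        assert mask.values.sum() == 0

    def test_smoothing_does_not_fragment_convex_blob(self):
        values = np.zeros((24, 24, 12), np.float32)
        values[8:16, 8:16, 4:8] = 1.0
        prob = ImageGrid(values, spacing=(1.0, 1.0, 1.0))
        for sigma in (0.5, 1.0, 2.0):
            mask, empty = postprocess(prob, prob, PostprocessSpec(gaussian_sigma=sigma))
            assert not empty
            _, n = ndimage.label(mask.values, structure=np.ones((3, 3, 3)))
            assert n == 1

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            PostprocessSpec(gaussian_sigma=-1.0)
        with pytest.raises(ValueError):
            PostprocessSpec(binarize_threshold=0.0)
        with pytest.raises(ValueError):
            PostprocessSpec(connectivity=4)
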