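"""Image container, NIfTI I/O, resampling, smoothing, percentile normalization."""

import nibabel as nib
import numpy as np
import pytest

from aslnorm.errors import (
    DegenerateInputError,
    DimensionalityError,
    GeometryError,
    ParameterError,
)
from aslnorm.image_core import (
    FWHM_TO_SIGMA,
    ImageGeometry,
    VolumetricImage,
    centered_geometry,
    gaussian_smooth,
    percentile_normalize,
    read_volume,
    resample,
    write_volume,
)
from aslnorm.transforms import RigidParams


class TestGeometry:
    def test_voxel_sizes_from_affine(self):
        g = centered_geometry((10, 10, 10), (2.0, 2.0, 2.0))
        assert np.allclose(g.voxel_sizes_mm, 2.0)

    def test_singular_affine_rejected(self):
        mat = np.eye(4)
        mat[0, 0] = 0.0
        with pytest.raises(ParameterError):
            ImageGeometry((5, 5, 5), mat)

    def test_world_voxel_round_trip(self, rng):
        g = centered_geometry((8, 9, 10), (1.5, 2.0, 2.5))
        pts = rng.uniform(-10, 10, (20, 3))
        back = g.world_to_voxel_points(g.voxel_to_world_points(pts))
        assert np.allclose(back, pts, atol=1e-12)


class TestVolumetricImage:
    def test_shape_mismatch_rejected(self, small_geometry):
        with pytest.raises(GeometryError):
            VolumetricImage(small_geometry, np.zeros((3, 3, 3)))

    def test_probability_bounds_enforced(self, small_geometry):
        with pytest.raises(ParameterError):
            VolumetricImage(small_geometry, np.full(small_geometry.shape, 1.5), "probability")

    def test_mask_values_enforced(self, small_geometry):
        with pytest.raises(ParameterError):
            VolumetricImage(small_geometry, np.full(small_geometry.shape, 0.5), "mask")


class TestNiftiIO:
    def test_round_trip_preserves_affine_and_data(self, tmp_path, rng):
        g = centered_geometry((10, 10, 10), (2.0, 2.0, 2.0))
        data = rng.uniform(0, 100, g.shape).astype(np.float32).astype(float)
        img = VolumetricImage(g, data, "cbf_ml_per_100g_min")
        path = tmp_path / "cbf.nii.gz"
        write_volume(img, path)
        back = read_volume(path, "cbf_ml_per_100g_min")
        assert np.array_equal(back.geometry.voxel_to_world, g.voxel_to_world)
        assert np.abs(back.voxels - data).max() < 1e-6

    def test_mask_written_as_uint8(self, tmp_path, small_geometry):
        mask = VolumetricImage(
            small_geometry, (np.arange(1000).reshape(10, 10, 10) % 2).astype(float), "mask"
        )
        path = tmp_path / "mask.nii.gz"
        write_volume(mask, path)
        assert nib.load(str(path)).get_data_dtype() == np.uint8

    def test_cbf_written_as_float32(self, tmp_path, random_volume):
        path = tmp_path / "cbf.nii.gz"
        write_volume(random_volume, path)
        assert nib.load(str(path)).get_data_dtype() == np.float32

    def test_four_dimensional_input_rejected(self, tmp_path):
        img = nib.Nifti1Image(np.zeros((5, 5, 5, 3), dtype=np.float32), np.eye(4))
        path = tmp_path / "timeseries.nii.gz"
        nib.save(img, str(path))
        with pytest.raises(DimensionalityError, match="axis 3"):
            read_volume(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(IOError):
            read_volume(tmp_path / "nope.nii.gz")


class TestResample:
    def test_identity_exact(self, random_volume):
        out = resample(random_volume, random_volume.geometry, RigidParams(), order=1)
        assert np.allclose(out.voxels, random_volume.voxels, atol=1e-12)

    def test_one_voxel_translation_nearest(self, small_geometry):
        data = np.zeros(small_geometry.shape)
        data[5, 5, 5] = 1.0
        img = VolumetricImage(small_geometry, data)
        # pull-back: output voxel i samples input at i + 1 voxel along x,
        # so the hot voxel appears one index lower
        shift = RigidParams(translation=(2.0, 0.0, 0.0))
        out = resample(img, small_geometry, shift, order=0)
        expected = np.zeros(small_geometry.shape)
        expected[4, 5, 5] = 1.0
        assert np.array_equal(out.voxels, expected)

    def test_constant_preserved_interior(self, small_geometry):
        img = VolumetricImage(small_geometry, np.full(small_geometry.shape, 7.0))
        warp = RigidParams(translation=(0.3, -0.4, 0.2))
        out = resample(img, small_geometry, warp, order=1)
        interior = out.voxels[2:-2, 2:-2, 2:-2]
        assert np.allclose(interior, 7.0, atol=1e-12)

    def test_out_of_volume_is_zero(self, random_volume):
        out = resample(
            random_volume,
            random_volume.geometry,
            RigidParams(translation=(1000.0, 0, 0)),
            order=1,
        )
        assert np.all(out.voxels == 0)

    def test_unsupported_order(self, random_volume):
        with pytest.raises(ParameterError):
            resample(random_volume, random_volume.geometry, RigidParams(), order=2)


class TestGaussianSmooth:
    def test_zero_fwhm_identity(self, random_volume):
        out = gaussian_smooth(random_volume, (0, 0, 0))
        assert np.array_equal(out.voxels, random_volume.voxels)

    def test_interior_impulse_mass_conserved(self, small_geometry):
        data = np.zeros(small_geometry.shape)
        data[5, 5, 5] = 1.0
        out = gaussian_smooth(VolumetricImage(small_geometry, data), (4, 4, 4))
        assert abs(out.voxels.sum() - 1.0) < 1e-6

    def test_half_maximum_radius(self):
        # 8 mm FWHM on a 2 mm grid: value at 2 voxels (= half FWHM) from an
        # impulse is half the centre value
        g = centered_geometry((21, 21, 21), (2.0, 2.0, 2.0))
        data = np.zeros(g.shape)
        data[10, 10, 10] = 1.0
        out = gaussian_smooth(VolumetricImage(g, data), (8.0, 8.0, 8.0)).voxels
        ratio = out[12, 10, 10] / out[10, 10, 10]
        assert ratio == pytest.approx(0.5, abs=0.02)

    def test_linearity(self, small_geometry, rng):
        a = VolumetricImage(small_geometry, rng.uniform(0, 1, small_geometry.shape))
        b = VolumetricImage(small_geometry, rng.uniform(0, 1, small_geometry.shape))
        lhs = gaussian_smooth(a.with_voxels(a.voxels + b.voxels), (5, 5, 5)).voxels
        rhs = gaussian_smooth(a, (5, 5, 5)).voxels + gaussian_smooth(b, (5, 5, 5)).voxels
        assert np.allclose(lhs, rhs, rtol=1e-6, atol=1e-9)

    def test_negative_fwhm_rejected(self, random_volume):
        with pytest.raises(ParameterError):
            gaussian_smooth(random_volume, (-1, 0, 0))

    def test_sigma_conversion_constant(self):
        assert FWHM_TO_SIGMA == pytest.approx(1 / 2.3548, abs=1e-4)


class TestPercentileNormalize:
    def _mask(self, geometry, sel):
        return VolumetricImage(geometry, sel.astype(float), "mask")

    def test_constant_image(self, small_geometry):
        img = VolumetricImage(small_geometry, np.full(small_geometry.shape, 42.0))
        mask = self._mask(small_geometry, np.ones(small_geometry.shape, bool))
        normed, included = percentile_normalize(img, mask)
        assert np.allclose(normed.voxels, 1.0)
        assert np.array_equal(included.voxels, mask.voxels)

    def test_values_1_to_100_brute_force(self):
        # independent brute-force percentile with the linear interpolation
        # rule: rank position q = p/100*(n-1) between sorted order statistics
        g = centered_geometry((100, 1, 1), (1, 1, 1))
        vals = np.arange(1.0, 101.0)
        img = VolumetricImage(g, vals.reshape(100, 1, 1))
        mask = self._mask(g, np.ones(g.shape, bool))
        normed, included = percentile_normalize(img, mask, p=97)
        srt = np.sort(vals)
        q = 0.97 * (len(srt) - 1)
        lo = int(np.floor(q))
        P_brute = srt[lo] + (q - lo) * (srt[lo + 1] - srt[lo])
        assert P_brute == pytest.approx(97.03)
        assert normed.voxels.max() == pytest.approx(100.0 / P_brute)
        excluded = mask.mask_array() & ~included.mask_array()
        assert sorted(vals[excluded.reshape(100)]) == [98.0, 99.0, 100.0]

    def test_included_values_within_unit_interval(self, random_volume):
        sel = np.ones(random_volume.geometry.shape, bool)
        normed, included = percentile_normalize(
            random_volume, self._mask(random_volume.geometry, sel)
        )
        inc = included.mask_array()
        assert normed.voxels[inc].min() >= 0.0
        assert normed.voxels[inc].max() <= 1.0

    def test_nonpositive_image_rejected(self, small_geometry):
        img = VolumetricImage(small_geometry, -np.ones(small_geometry.shape))
        mask = self._mask(small_geometry, np.ones(small_geometry.shape, bool))
        with pytest.raises(DegenerateInputError):
            percentile_normalize(img, mask)

    def test_empty_mask_rejected(self, random_volume):
        mask = self._mask(random_volume.geometry, np.zeros(random_volume.geometry.shape, bool))
        with pytest.raises(DegenerateInputError):
            percentile_normalize(random_volume, mask)
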