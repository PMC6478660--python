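import warnings

import numpy as np
import pytest

from ezpet.image import Volume
from ezpet.phantom import make_patient
from ezpet.preprocess import (
    FWHM_TO_SIGMA,
    AffineTransform,
    affine_register,
    apply_deformation,
    intensity_normalize_parabola,
    intensity_normalize_proportional,
    resample,
    smooth_gaussian,
)


def _flat_volume(values, shape=None):
    values = np.asarray(values, dtype=float)
    if shape is None:
        n = int(round(len(values) ** (1 / 3)))
        while n**3 < len(values):
            n += 1
        padded = np.zeros(n**3)
        padded[: len(values)] = values
        return Volume(padded.reshape(n, n, n)), n**3 - len(values)
    return Volume(values.reshape(shape)), 0


class TestParabolaNormalization:
    def test_exact_global_scale(self):
        ref = Volume(np.full((10, 10, 10), 50.0))
        pat = ref.with_data(ref.data * 2.0)
        mask = ref.with_data(np.ones(ref.shape, dtype=bool))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # single-bin histogram is flagged
            res = intensity_normalize_parabola(pat, ref, mask)
        assert res.factor == pytest.approx(2.0, abs=1e-9)
        assert np.allclose(res.apply(pat).data, ref.data)

    def test_recovers_mode_of_unimodal_quotients(self):
        rng = np.random.default_rng(7)
        q = rng.normal(1.2, 0.05, 10_000)
        vol, pad = _flat_volume(q)
        ref = vol.with_data(np.ones(vol.shape))
        mask = vol.with_data(np.arange(vol.data.size).reshape(vol.shape) < 10_000)
        res = intensity_normalize_parabola(vol, ref, mask, bins=100, fit_half_width=3)
        assert res.factor == pytest.approx(1.2, abs=0.01)

    def test_mode_beats_global_mean_under_contamination(self):
        # 10% hot voxels triple the mean ratio but leave the mode in place
        rng = np.random.default_rng(21)
        q = rng.normal(1.0, 0.03, 10_000)
        q[:1000] = 3.0
        vol, _ = _flat_volume(q)
        ref = vol.with_data(np.ones(vol.shape))
        mask = vol.with_data(np.arange(vol.data.size).reshape(vol.shape) < 10_000)
        res = intensity_normalize_parabola(vol, ref, mask)
        assert res.factor == pytest.approx(1.0, abs=0.02)
        global_mean_ratio = q.mean()
        assert global_mean_ratio > 1.15

    @pytest.mark.parametrize("c", [0.5, 2.0, 3.0])
    def test_homogeneity_up_to_bin_width(self, c):
        rng = np.random.default_rng(3)
        q = rng.normal(1.1, 0.04, 8_000)
        vol, _ = _flat_volume(q)
        ref = vol.with_data(np.ones(vol.shape))
        mask = vol.with_data(np.arange(vol.data.size).reshape(vol.shape) < 8_000)
        base = intensity_normalize_parabola(vol, ref, mask)
        scaled = intensity_normalize_parabola(vol.with_data(vol.data * c), ref, mask)
        tol = c * base.diagnostics["bin_width"]
        assert scaled.factor == pytest.approx(c * base.factor, abs=tol)

    def test_empty_mask_and_nonpositive_reference_are_rejected(self):
        vol = Volume(np.ones((4, 4, 4)))
        empty = vol.with_data(np.zeros(vol.shape, dtype=bool))
        with pytest.raises(ValueError, match="mask"):
            intensity_normalize_parabola(vol, vol, empty)
        full = vol.with_data(np.ones(vol.shape, dtype=bool))
        with pytest.raises(ValueError, match="positive"):
            intensity_normalize_parabola(vol, vol.with_data(np.zeros(vol.shape)), full)


class TestProportionalScaling:
    @pytest.mark.parametrize("value,grand_mean,factor", [(50.0, 50.0, 1.0), (100.0, 50.0, 2.0)])
    def test_constant_images(self, value, grand_mean, factor):
        vol = Volume(np.full((6, 6, 6), value))
        mask = vol.with_data(np.ones(vol.shape, dtype=bool))
        res = intensity_normalize_proportional(vol, mask, grand_mean)
        assert res.factor == pytest.approx(factor)

    def test_normalized_masked_mean_equals_grand_mean(self):
        rng = np.random.default_rng(5)
        vol = Volume(rng.uniform(10, 90, (8, 8, 8)))
        mask = vol.with_data(rng.uniform(size=vol.shape) > 0.4)
        res = intensity_normalize_proportional(vol, mask, 50.0)
        normalized = res.apply(vol)
        assert normalized.data[mask.data].mean() == pytest.approx(50.0, rel=1e-10)

    def test_zero_mean_is_rejected(self):
        vol = Volume(np.zeros((4, 4, 4)))
        mask = vol.with_data(np.ones(vol.shape, dtype=bool))
        with pytest.raises(ValueError, match="zero"):
            intensity_normalize_proportional(vol, mask, 50.0)


class TestSmoothing:
    def test_sigma_matches_fwhm_closed_form(self):
        # fwhm 8 mm at 2 mm spacing -> sigma = 8/(2 sqrt(2 ln 2))/2 = 1.6986 voxels
        assert 8.0 / FWHM_TO_SIGMA / 2.0 == pytest.approx(1.6986, abs=1e-4)
        spike = np.zeros((33, 33, 33))
        spike[16, 16, 16] = 1.0
        vol = Volume(spike, np.diag([2.0, 2.0, 2.0, 1.0]))
        out = smooth_gaussian(vol, 8.0).data
        # measured standard deviation of the kernel along x, in voxels
        profile = out.sum(axis=(1, 2))
        x = np.arange(33)
        mu = (profile * x).sum() / profile.sum()
        sd = np.sqrt((profile * (x - mu) ** 2).sum() / profile.sum())
        assert sd == pytest.approx(1.6986, abs=2e-3)

    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(0)
        vol = Volume(rng.normal(size=(9, 9, 9)))
        assert np.array_equal(smooth_gaussian(vol, 0.0).data, vol.data)

    def test_negative_fwhm_is_rejected(self):
        with pytest.raises(ValueError):
            smooth_gaussian(Volume(np.ones((4, 4, 4))), -1.0)

    def test_interior_mass_is_conserved(self):
        spike = np.zeros((41, 41, 41))
        spike[20, 20, 20] = 123.0
        vol = Volume(spike, np.diag([2.0, 2.0, 2.0, 1.0]))
        out = smooth_gaussian(vol, 8.0)
        assert out.data.sum() == pytest.approx(123.0, rel=1e-6)

    def test_smoothing_commutes_with_scaling(self):
        rng = np.random.default_rng(11)
        vol = Volume(rng.uniform(size=(12, 12, 12)), np.diag([2.6, 2.6, 2.4, 1.0]))
        a = smooth_gaussian(vol.with_data(vol.data * 3.5), 8.0).data
        b = 3.5 * smooth_gaussian(vol, 8.0).data
        assert np.allclose(a, b, rtol=1e-10)


class TestResampleAndDeformation:
    def test_identity_is_bitwise_exact(self):
        rng = np.random.default_rng(1)
        vol = Volume(rng.normal(size=(10, 10, 10)), np.diag([2.6, 2.6, 2.4, 1.0]))
        out = resample(vol, AffineTransform.identity())
        assert np.array_equal(out.data, vol.data)

    def test_constant_preserved_in_field(self):
        vol = Volume(np.full((16, 16, 16), 5.0), np.diag([2.0, 2.0, 2.0, 1.0]))
        tr = AffineTransform(translation=[1.0, -0.5, 0.7], rotation=[0.02, 0.0, -0.01])
        out = resample(vol, tr)
        assert np.allclose(out.data[4:12, 4:12, 4:12], 5.0)

    def test_integer_translation_moves_spike(self):
        data = np.zeros((12, 12, 12))
        data[6, 6, 6] = 1.0
        vol = Volume(data, np.diag([2.0, 2.0, 2.0, 1.0]))
        # pull-back by +2 voxels in x samples the spike at target voxel 4
        tr = AffineTransform(translation=[4.0, 0.0, 0.0])
        out = resample(vol, tr)
        assert out.data[4, 6, 6] == pytest.approx(1.0)
        assert out.data.sum() == pytest.approx(1.0)

    def test_zero_scale_transform_is_rejected(self):
        with pytest.raises(ValueError):
            AffineTransform(scale=[1.0, 0.0, 1.0])

    def test_zero_deformation_is_identity(self):
        rng = np.random.default_rng(2)
        vol = Volume(rng.normal(size=(8, 8, 8)))
        out = apply_deformation(vol, np.zeros(vol.shape + (3,)))
        assert np.array_equal(out.data, vol.data)

    def test_uniform_one_voxel_field_equals_integer_translation(self):
        data = np.zeros((10, 10, 10))
        data[5, 5, 5] = 1.0
        vol = Volume(data, np.diag([2.0, 2.0, 2.0, 1.0]))
        field = np.zeros(vol.shape + (3,))
        field[..., 0] = 2.0  # one voxel spacing in mm
        out = apply_deformation(vol, field)
        assert out.data[4, 5, 5] == pytest.approx(1.0)

    def test_smooth_field_on_constant_image_keeps_constant(self):
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(3)
        vol = Volume(np.full((14, 14, 14), 9.0), np.diag([2.0, 2.0, 2.0, 1.0]))
        field = gaussian_filter(rng.normal(0, 1.0, vol.shape + (3,)), sigma=(2, 2, 2, 0))
        out = apply_deformation(vol, field)
        assert np.allclose(out.data[2:-2, 2:-2, 2:-2], 9.0)

    def test_shape_mismatch_is_rejected(self):
        vol = Volume(np.zeros((6, 6, 6)))
        with pytest.raises(ValueError, match="shape"):
            apply_deformation(vol, np.zeros((5, 6, 6, 3)))

    def test_deformation_field_nifti_roundtrip(self, tmp_path):
        from ezpet.preprocess import read_deformation_field, write_deformation_field

        rng = np.random.default_rng(6)
        field = rng.normal(size=(7, 7, 7, 3))
        write_deformation_field(field, np.diag([2.0, 2.0, 2.0, 1.0]), tmp_path / "f.nii")
        back = read_deformation_field(tmp_path / "f.nii")
        assert back.shape == (7, 7, 7, 3)
        assert np.allclose(back, field)


class TestRegistration:
    def test_self_registration_is_identity(self, template_and_atlas):
        template, _ = template_and_atlas
        tr = affine_register(template, template)
        assert np.all(np.abs(tr.translation) < 0.1)
        assert np.all(np.abs(tr.scale - 1.0) < 0.001)
        assert np.all(np.abs(tr.rotation) < 0.001)

    def test_known_shift_recovered_within_quarter_voxel(self, template_and_atlas):
        template, _ = template_and_atlas
        shift_mm = np.array([2, -3, 1]) * template.spacing
        truth = AffineTransform(translation=shift_mm)
        moved = resample(template, truth, template)
        rec = affine_register(moved, template)
        residual = truth.matrix() @ rec.matrix()  # identity if exactly recovered
        err_mm = np.abs(residual[:3, 3])
        assert np.all(err_mm < 0.25 * template.spacing)

    def test_random_affine_recovered_within_ten_percent(self, default_spec, template_and_atlas):
        template, atlas = template_and_atlas
        spec = default_spec.replace(rot_max_deg=5.0, shift_max_mm=5.0)
        patient, _, info = make_patient(spec, 11, template, atlas)
        rec = affine_register(patient, template)
        residual = info["transform"].matrix() @ rec.matrix()
        # 10% of the sampled ranges: 0.5 mm translation, 0.5 deg ~ 0.0087 linear
        assert np.abs(residual[:3, 3]).max() < 0.5
        assert np.abs(residual[:3, :3] - np.eye(3)).max() < 0.0087
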