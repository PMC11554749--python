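import numpy as np
import pytest

from afmi import preprocess as pp
from afmi.io import MaskImage, ReferenceSpectra
from afmi.synthetic import simulate_references, status_scenario


@pytest.fixture
def cfg():
    return pp.PreprocessConfig()


def _mask_with_square(h, w, cell_id=1, size=4):
    labels = np.zeros((h, w), dtype=np.int64)
    labels[2 : 2 + size, 2 : 2 + size] = cell_id
    return MaskImage(labels=labels)


class TestCosmicRays:
    def test_single_injected_spike_replaced_exactly(self, make_cube, cfg):
        pixels = np.full((10, 10, 2), 5.0)
        pixels[4, 7, 1] = 500.0
        cube = make_cube(pixels)
        out, n = pp.remove_cosmic_rays(cube, cfg)
        assert n == 1
        assert out.pixels[4, 7, 1] == 5.0
        changed = out.pixels != pixels
        assert changed.sum() == 1

    def test_constant_cube_untouched(self, make_cube, cfg):
        cube = make_cube(np.full((8, 8, 3), 2.0))
        out, n = pp.remove_cosmic_rays(cube, cfg)
        assert n == 0
        np.testing.assert_array_equal(out.pixels, cube.pixels)

    def test_stage_becomes_preprocessed(self, make_cube, cfg):
        out, _ = pp.remove_cosmic_rays(make_cube(np.ones((5, 5, 2))), cfg)
        assert out.stage == "preprocessed"
        assert out.history == ("cosmic_rays",)

    def test_requires_raw_stage(self, make_cube, cfg):
        cube = make_cube(np.ones((5, 5, 2)), stage="preprocessed",
                         history=("cosmic_rays",))
        with pytest.raises(pp.PipelineOrderError):
            pp.remove_cosmic_rays(cube, cfg)


class TestDenoise:
    def test_noise_free_low_rank_cube_preserved(self, make_cube):
        rng = np.random.default_rng(0)
        spectra = rng.uniform(0.5, 1.5, (3, 8))
        weights = rng.uniform(0, 1, (12, 12, 3))
        pixels = weights @ spectra  # exact rank 3
        cube = make_cube(pixels, stage="preprocessed", history=("cosmic_rays",))
        out = pp.denoise_lowrank(
            cube, pp.PreprocessConfig(denoise_rank=3, denoise_wavelet_levels=0)
        )
        rel = np.sqrt(np.mean((out.pixels - pixels) ** 2)) / np.sqrt(
            np.mean(pixels**2)
        )
        assert rel < 1e-6

    def test_full_rank_zero_levels_is_identity(self, make_cube):
        rng = np.random.default_rng(1)
        pixels = rng.uniform(0, 2, (10, 10, 5))
        cube = make_cube(pixels, stage="preprocessed", history=("cosmic_rays",))
        out = pp.denoise_lowrank(
            cube, pp.PreprocessConfig(denoise_rank=5, denoise_wavelet_levels=0)
        )
        np.testing.assert_allclose(out.pixels, pixels, atol=1e-10)

    def test_noise_reduced_on_low_rank_scene(self, make_cube):
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(2)
        spectra = rng.uniform(0.5, 1.5, (3, 12))
        # spatially smooth abundance maps, as in a real field of view
        weights = gaussian_filter(
            rng.uniform(0.2, 1, (24, 24, 3)), (3, 3, 0)
        )
        truth = weights @ spectra
        noisy = truth * (1 + 0.05 * rng.normal(size=truth.shape))
        cube = make_cube(noisy, stage="preprocessed", history=("cosmic_rays",))
        out = pp.denoise_lowrank(
            cube, pp.PreprocessConfig(denoise_rank=3, denoise_wavelet_levels=1)
        )
        err_in = np.sqrt(np.mean((noisy - truth) ** 2))
        err_out = np.sqrt(np.mean((out.pixels - truth) ** 2))
        assert err_out < err_in

    def test_rank_above_channels_rejected(self, make_cube):
        cube = make_cube(np.ones((5, 5, 3)), stage="preprocessed",
                         history=("cosmic_rays",))
        with pytest.raises(ValueError, match="denoise_rank"):
            pp.denoise_lowrank(cube, pp.PreprocessConfig(denoise_rank=4))

    def test_output_nonnegative(self, make_cube):
        rng = np.random.default_rng(3)
        pixels = np.abs(rng.normal(0.1, 0.2, (16, 16, 6)))
        cube = make_cube(pixels, stage="preprocessed", history=("cosmic_rays",))
        out = pp.denoise_lowrank(cube, pp.PreprocessConfig(denoise_rank=2))
        assert out.pixels.min() >= 0


class TestBackground:
    def _prep_cube(self, make_cube, pixels):
        return make_cube(pixels, stage="preprocessed",
                         history=("cosmic_rays", "denoise"))

    def test_uniform_offset_removed_exactly(self, make_cube, cfg):
        offsets = np.array([0.5, 1.0, 2.0])
        pixels = np.zeros((10, 10, 3)) + offsets
        mask = _mask_with_square(10, 10)
        pixels[mask.labels == 1] += 3.0
        cube = self._prep_cube(make_cube, pixels)
        out = pp.subtract_background(cube, mask, cfg)
        bg = np.asarray(out.meta["background_levels"])
        np.testing.assert_allclose(bg, offsets)
        assert np.all(out.pixels[mask.labels == 0] == 0)
        np.testing.assert_allclose(out.pixels[mask.labels == 1], 3.0)

    def test_zero_background_unchanged(self, make_cube, cfg):
        pixels = np.zeros((8, 8, 2))
        mask = _mask_with_square(8, 8)
        pixels[mask.labels == 1] = 1.5
        cube = self._prep_cube(make_cube, pixels)
        out = pp.subtract_background(cube, mask, cfg)
        np.testing.assert_array_equal(out.pixels, pixels)

    def test_all_foreground_mask_rejected(self, make_cube, cfg):
        cube = self._prep_cube(make_cube, np.ones((6, 6, 2)))
        mask = MaskImage(labels=np.ones((6, 6), dtype=np.int64))
        with pytest.raises(ValueError, match="background"):
            pp.subtract_background(cube, mask, cfg)


class TestFlatten:
    def _bg_cube(self, make_cube, pixels, mask, cfg):
        cube = make_cube(pixels, stage="preprocessed",
                         history=("cosmic_rays", "denoise"))
        return pp.subtract_background(cube, mask, cfg)

    def test_linear_ramp_removed_from_uniform_target(self, make_cube, cfg):
        h, w = 48, 48
        ramp = 1.0 + 0.2 * (np.arange(w) / (w - 1) - 0.5) * 2  # 0.8 -> 1.2
        pixels = np.ones((h, w, 2)) * ramp[None, :, None]
        mask = MaskImage(labels=np.zeros((h, w), dtype=np.int64))  # blank dish
        sub = self._bg_cube(make_cube, pixels, mask, cfg)
        # undo the (uniform-field) background subtraction to study flattening
        sub = sub.replace(pixels=pixels.copy())
        out = pp.flatten_field(sub, mask, cfg)
        for k in range(2):
            vals = out.pixels[:, :, k]
            assert vals.std() / vals.mean() < 0.01

    def test_uniform_illumination_unchanged(self, make_cube, cfg):
        pixels = np.full((24, 24, 2), 0.7)
        mask = _mask_with_square(24, 24)
        sub = self._bg_cube(make_cube, pixels, mask, cfg)
        out = pp.flatten_field(sub, mask, cfg)
        np.testing.assert_allclose(out.pixels, sub.pixels, atol=1e-9)

    def test_degree_zero_is_identity_after_normalisation(self, make_cube):
        cfg0 = pp.PreprocessConfig(flatfield_poly_degree=0)
        rng = np.random.default_rng(0)
        pixels = rng.uniform(0.5, 1.0, (16, 16, 2))
        mask = _mask_with_square(16, 16)
        sub = self._bg_cube(make_cube, pixels, mask, cfg0)
        out = pp.flatten_field(sub, mask, cfg0)
        np.testing.assert_allclose(out.pixels, sub.pixels, atol=1e-9)


class TestSmoothReference:
    def test_constant_spectrum_unchanged(self, cfg):
        x = np.full(47, 3.0)
        np.testing.assert_allclose(pp.smooth_reference(x, cfg), x, atol=1e-9)

    def test_spiky_quadratic_gets_closer_to_truth(self, cfg):
        t = np.linspace(-1, 1, 47)
        truth = 2 + 0.5 * t - t**2
        rng = np.random.default_rng(0)
        noisy = truth + 0.2 * rng.normal(size=47)
        smoothed = pp.smooth_reference(noisy, cfg)
        assert np.sqrt(np.mean((smoothed - truth) ** 2)) < np.sqrt(
            np.mean((noisy - truth) ** 2)
        )

    def test_near_idempotent(self, cfg):
        rng = np.random.default_rng(1)
        x = 1 + 0.3 * rng.normal(size=47) + np.linspace(0, 1, 47)
        once = pp.smooth_reference(x, cfg)
        twice = pp.smooth_reference(once, cfg)
        assert np.sqrt(np.mean((twice - once) ** 2)) < 0.01 * np.sqrt(
            np.mean(once**2)
        )

    def test_short_spectrum_passthrough_with_warning(self, cfg):
        x = np.arange(5, dtype=float)
        with pytest.warns(UserWarning, match="shorter"):
            out = pp.smooth_reference(x, cfg)
        np.testing.assert_array_equal(out, x)


class TestCalibrate:
    def _flat_cube(self, make_cube, pixels):
        return make_cube(
            pixels, stage="preprocessed",
            history=("cosmic_rays", "denoise", "background", "flatten"),
        )

    def test_identity_when_measured_equals_reference(self, make_cube, cfg):
        ref = np.linspace(0.5, 2.0, 3)
        refs = ReferenceSpectra(
            water_mean=np.zeros(3), calib_measured=ref, calib_reference=ref
        )
        pixels = np.random.default_rng(0).uniform(0, 1, (6, 6, 3))
        out = pp.calibrate(self._flat_cube(make_cube, pixels), refs, cfg)
        np.testing.assert_allclose(out.pixels, pixels)
        assert out.stage == "calibrated"

    def test_calibrating_the_fluid_reproduces_reference(self, make_cube, cfg):
        rng = np.random.default_rng(1)
        ref = rng.uniform(0.5, 2.0, 4)
        gains_true = rng.uniform(0.7, 1.4, 4)
        water = np.full(4, 0.05)
        measured = ref / gains_true + water
        refs = ReferenceSpectra(
            water_mean=water, calib_measured=measured, calib_reference=ref
        )
        fluid = np.ones((5, 5, 4)) * (measured - water)[None, None, :]
        out = pp.calibrate(self._flat_cube(make_cube, fluid), refs, cfg)
        np.testing.assert_allclose(
            out.pixels, np.broadcast_to(ref, out.pixels.shape), rtol=1e-6
        )

    def test_gain_distortions_inverted(self, make_cube, cfg):
        scenario = status_scenario(seed=4, ref_noise_sd=0.0)
        refs, gains = simulate_references(scenario)
        pixels = np.ones((4, 4, 47)) / gains[None, None, :]
        out = pp.calibrate(self._flat_cube(make_cube, pixels), refs, cfg)
        np.testing.assert_allclose(out.pixels, 1.0, rtol=1e-9)

    def test_noisy_references_recover_gains_after_smoothing(self, cfg, channel_table):
        scenario = status_scenario(seed=5, ref_noise_sd=0.01)
        refs, gains = simulate_references(scenario)
        smoothed = pp.smooth_references(refs, channel_table, cfg)
        est = smoothed.calib_reference / (
            smoothed.calib_measured - smoothed.water_mean
        )
        rel = np.sqrt(np.mean(((est - gains) / gains) ** 2))
        assert rel < 0.03

    def test_nonpositive_denominator_names_channels(self, make_cube, cfg):
        refs = ReferenceSpectra(
            water_mean=np.array([0.0, 2.0]),
            calib_measured=np.array([1.0, 1.0]),
            calib_reference=np.array([1.0, 1.0]),
        )
        cube = self._flat_cube(make_cube, np.ones((4, 4, 2)))
        with pytest.raises(pp.CalibrationError, match="1"):
            pp.calibrate(cube, refs, cfg)


class TestPipeline:
    def test_order_enforced(self, make_cube, cfg):
        raw = make_cube(np.ones((8, 8, 3)))
        mask = _mask_with_square(8, 8)
        with pytest.raises(pp.PipelineOrderError):
            pp.denoise_lowrank(raw, pp.PreprocessConfig(denoise_rank=2))
        with pytest.raises(pp.PipelineOrderError):
            pp.subtract_background(raw, mask, cfg)
        with pytest.raises(pp.PipelineOrderError):
            pp.flatten_field(raw, mask, cfg)

    def test_stages_preserve_shape_and_nonnegativity(self, make_cube, cfg):
        rng = np.random.default_rng(0)
        pixels = rng.uniform(0.1, 1.0, (20, 20, 6))
        mask = _mask_with_square(20, 20, size=6)
        refs = ReferenceSpectra(
            water_mean=np.zeros(6),
            calib_measured=np.ones(6),
            calib_reference=np.ones(6),
        )
        cube = make_cube(pixels)
        cube, _ = pp.remove_cosmic_rays(cube, cfg)
        for step in (
            lambda c: pp.denoise_lowrank(c, pp.PreprocessConfig(denoise_rank=4)),
            lambda c: pp.subtract_background(c, mask, cfg),
            lambda c: pp.flatten_field(c, mask, cfg),
            lambda c: pp.calibrate(c, refs, cfg),
        ):
            cube = step(cube)
            assert cube.shape == (20, 20, 6)
            assert np.all(np.isfinite(cube.pixels))
            assert cube.pixels.min() >= 0
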