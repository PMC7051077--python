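"""Spectral simulator: scene physics, sensor model and cohort generator."""

from dataclasses import replace

import numpy as np
import pytest

from scbkit.colorimetry import (
    Spectrum,
    default_grid,
    jeci,
    spectrum_to_xyz,
    standard_observer,
    xyz_to_chromaticity,
)
from scbkit.raw_frames import extract_roi_rgb
from scbkit.simulate import (
    ScleraModel,
    illuminant_preset,
    make_flash_pair,
    make_jeci_chart,
    mosaic_and_quantize,
    render_patch,
    scale_preset_to_signal,
    sclera_reflectance,
    simulate_cohort,
)

EXPOSURE = 1 / 30


class TestScleraReflectance:
    def test_zero_tsb_is_baseline(self, grid):
        model = ScleraModel()
        s = sclera_reflectance(model, 0.0, grid)
        assert np.allclose(s.values, model.baseline(grid).values)

    def test_jeci_strictly_increasing_with_tsb(self, grid):
        model = ScleraModel()
        illum = illuminant_preset("screen_white", grid).spd
        cmfs = standard_observer(grid)
        vals = []
        for tsb in range(0, 501, 100):
            s = sclera_reflectance(model, float(tsb), grid)
            vals.append(jeci(xyz_to_chromaticity(spectrum_to_xyz(illum, s, cmfs))))
        assert np.all(np.diff(vals) > 0)

    def test_red_end_unaffected_by_bilirubin(self, grid):
        model = ScleraModel()
        idx = np.argmin(np.abs(grid - 650.0))
        r0 = sclera_reflectance(model, 0.0, grid).values[idx]
        r500 = sclera_reflectance(model, 500.0, grid).values[idx]
        assert abs(r0 - r500) < 1e-6

    def test_negative_tsb_is_error(self, grid):
        with pytest.raises(ValueError):
            sclera_reflectance(ScleraModel(), -1.0, grid)


class TestRenderPatch:
    def test_zero_reflectance_renders_black(self, grid, camera, screen_scaled):
        zero = Spectrum(grid, np.zeros_like(grid))
        assert render_patch(zero, [screen_scaled], camera, EXPOSURE) == (0, 0, 0)

    def test_linear_in_geometry(self, grid, camera, screen_scaled):
        refl = sclera_reflectance(ScleraModel(), 200.0, grid)
        a = np.asarray(render_patch(refl, [screen_scaled], camera, EXPOSURE, geometry_a=1.0))
        b = np.asarray(render_patch(refl, [screen_scaled], camera, EXPOSURE, geometry_a=2.0))
        assert np.allclose(b, 2 * a, rtol=1e-12)

    def test_illuminant_additivity(self, grid, camera, screen_scaled):
        """Joint render equals the sum of separate renders: the physical
        premise that makes flash/no-flash subtraction exact."""
        refl = sclera_reflectance(ScleraModel(), 300.0, grid)
        ambient = scale_preset_to_signal(
            illuminant_preset("warm_led_2700K", grid), camera, EXPOSURE, 0.3
        )
        joint = np.asarray(render_patch(refl, [ambient, screen_scaled], camera, EXPOSURE))
        separate = np.asarray(render_patch(refl, [ambient], camera, EXPOSURE)) + np.asarray(
            render_patch(refl, [screen_scaled], camera, EXPOSURE)
        )
        assert np.allclose(joint, separate, atol=1e-12)

    def test_chromaticity_invariant_to_exposure(self, grid, camera, screen_scaled, characterization):
        from scbkit.colorimetry import rgb_to_xyz

        refl = sclera_reflectance(ScleraModel(), 150.0, grid)
        chroms = []
        for t in (1 / 60, 1 / 15):
            rgb = render_patch(refl, [screen_scaled], camera, t)
            chroms.append(xyz_to_chromaticity(rgb_to_xyz(rgb, characterization)).as_array())
        assert np.allclose(chroms[0], chroms[1], atol=1e-12)


class TestMosaicAndQuantize:
    def test_noiseless_constant_field_is_exact_rounding(self, camera):
        rgb = (0.25, 0.50, 0.75)
        frame = mosaic_and_quantize(np.broadcast_to(rgb, (4, 4, 3)), camera, seed=0)
        span = camera.white_level - camera.black_level
        assert frame.mosaic[0, 0] == round(camera.black_level + 0.25 * span)  # R site
        assert frame.mosaic[0, 1] == round(camera.black_level + 0.50 * span)  # G site
        assert frame.mosaic[1, 1] == round(camera.black_level + 0.75 * span)  # B site

    def test_fixed_seed_is_bit_identical(self, camera):
        noisy = replace(camera, shot_noise=True, read_noise_sd=1.0)
        a = mosaic_and_quantize((0.3, 0.3, 0.3), noisy, seed=99)
        b = mosaic_and_quantize((0.3, 0.3, 0.3), noisy, seed=99)
        assert np.array_equal(a.mosaic, b.mosaic)

    def test_noisy_mean_consistent_with_noiseless_expectation(self, camera):
        """Monte-Carlo: the mean of many noisy renders converges on the
        noiseless expectation (within 3 standard errors)."""
        noisy = replace(camera, shot_noise=True, read_noise_sd=1.0, electrons_per_dn=10.0)
        value = 0.3
        span = camera.white_level - camera.black_level
        rng = np.random.default_rng(12)
        samples = np.concatenate(
            [
                mosaic_and_quantize((value,) * 3, noisy, seed=rng, shape=(4, 4)).mosaic.ravel()
                for _ in range(300)
            ]
        ).astype(float)
        expected_dn = camera.black_level + value * span
        se = samples.std(ddof=1) / np.sqrt(samples.size)
        assert abs(samples.mean() - expected_dn) < 3 * se + 0.5  # +0.5 DN rounding bias bound

    def test_clipping_at_white_level(self, camera):
        frame = mosaic_and_quantize((2.0, 2.0, 2.0), camera, seed=0)
        assert frame.mosaic.max() == camera.white_level


class TestMakeFlashPair:
    def test_zero_ambient_noflash_is_black_level_only(self, grid, camera, screen_scaled):
        refl = sclera_reflectance(ScleraModel(), 100.0, grid)
        dark = illuminant_preset("warm_led_2700K", grid).rescaled(0.0)
        pair = make_flash_pair(refl, dark, screen_scaled, camera, seed=1)
        assert np.all(pair.noflash_frame.mosaic == camera.black_level)

    def test_noiseless_pair_recovers_truth_chromaticity(
        self, grid, luther, screen_scaled, luther_characterization
    ):
        """End-to-end exactness: subtraction plus an exact (Luther)
        characterization recovers the flash-only chromaticity to within
        quantization (< 1e-3 per coordinate)."""
        from scbkit.colorimetry import rgb_to_xyz
        from scbkit.pipeline import full_frame_roi, process_pair

        ambient = scale_preset_to_signal(
            illuminant_preset("fluorescent", grid), luther, EXPOSURE, 0.25
        )
        for tsb in (0.0, 200.0, 450.0):
            refl = sclera_reflectance(ScleraModel(), tsb, grid)
            pair = make_flash_pair(
                refl, ambient, screen_scaled, luther, seed=2, truth_tsb=tsb, geometry_a=1.4
            )
            res = process_pair(pair.flash_frame, pair.noflash_frame, full_frame_roi(pair.flash_frame))
            assert res.valid
            got = xyz_to_chromaticity(rgb_to_xyz(res.flash_only_rgb, luther_characterization))
            truth = pair.truth_chromaticity_flash_only
            assert abs(got.x - truth.x) < 1e-3
            assert abs(got.y - truth.y) < 1e-3
            assert abs(got.z - truth.z) < 1e-3

    def test_warm_and_cool_ambient_disagree_but_subtractions_agree(
        self, grid, camera, screen_scaled, characterization
    ):
        """Ambient-only chromaticities under 2700 K and 6500 K lamps are
        far apart (> 0.02 in xy) while the ambient-subtracted estimates
        of the same sclera agree to < 5e-3."""
        from scbkit.colorimetry import rgb_to_xyz
        from scbkit.pipeline import full_frame_roi, process_pair

        refl = sclera_reflectance(ScleraModel(), 250.0, grid)
        subtracted, ambient_only = [], []
        for name in ("warm_led_2700K", "cool_led_6500K"):
            ambient = scale_preset_to_signal(illuminant_preset(name, grid), camera, EXPOSURE, 0.3)
            pair = make_flash_pair(refl, ambient, screen_scaled, camera, seed=4, shape=(16, 16))
            res = process_pair(pair.flash_frame, pair.noflash_frame, full_frame_roi(pair.flash_frame))
            subtracted.append(
                xyz_to_chromaticity(rgb_to_xyz(res.flash_only_rgb, characterization))
            )
            nf_rgb = extract_roi_rgb(pair.noflash_frame, full_frame_roi(pair.noflash_frame))
            ambient_only.append(xyz_to_chromaticity(rgb_to_xyz(nf_rgb, characterization)))
        assert ambient_only[0].xy_distance(ambient_only[1]) > 0.02
        assert subtracted[0].xy_distance(subtracted[1]) < 5e-3


class TestJECIChart:
    TARGETS = (0.01, 0.03, 0.05, 0.07, 0.09)

    def test_zero_target_is_white_patch(self, grid):
        (refl, truth), = make_jeci_chart([0.0], grid)
        assert np.allclose(refl.values, refl.values[0])
        assert jeci(truth) == pytest.approx(0.0, abs=1e-12)

    def test_targets_achieved(self, grid):
        chart = make_jeci_chart(self.TARGETS, grid)
        for target, (_, truth) in zip(self.TARGETS, chart):
            assert jeci(truth) == pytest.approx(target, abs=1e-4)

    def test_verified_on_fine_grid(self):
        """Independent check: re-integrate each patch on a 1 nm grid."""
        from scbkit.simulate import d65_like_illuminant

        coarse = default_grid(5.0)
        fine = default_grid(1.0)
        chart = make_jeci_chart([0.05], coarse)
        refl_coarse, _ = chart[0]
        refl_fine = Spectrum(fine, np.interp(fine, coarse, refl_coarse.values))
        illum = d65_like_illuminant(fine)
        ch = xyz_to_chromaticity(spectrum_to_xyz(illum, refl_fine, standard_observer(fine)))
        assert jeci(ch) == pytest.approx(0.05, abs=5e-4)

    def test_unattainable_target_is_error(self, grid):
        with pytest.raises(ValueError):
            make_jeci_chart([0.5], grid)


class TestCohort:
    def test_fixed_seed_reproduces_cohort(self):
        a = simulate_cohort(5, seed=3)
        b = simulate_cohort(5, seed=3)
        assert a.subjects.equals(b.subjects)
        for sid in a.pairs:
            for pa, pb in zip(a.pairs[sid], b.pairs[sid]):
                assert np.array_equal(pa.flash_frame.mosaic, pb.flash_frame.mosaic)
                assert np.array_equal(pa.noflash_frame.mosaic, pb.noflash_frame.mosaic)

    def test_low_noise_cohort_recovers_tsb_correlation(self):
        """At low noise, SCB_xy fitted on the estimated chromaticities
        correlates > 0.9 with true TSB."""
        from scbkit.pipeline import characterize_camera, cohort_to_records
        from scbkit.scb_models import fit_scb_xy

        cohort = simulate_cohort(60, seed=8, noise="low")
        M = characterize_camera(cohort.camera, cohort.screen)
        records, excluded = cohort_to_records(cohort, M)
        assert not excluded
        assert fit_scb_xy(records).pearson_r > 0.9

    def test_tsb_distribution_within_configured_range(self):
        cohort = simulate_cohort(100, seed=5)
        tsb = cohort.subjects["tsb_umol_per_L"]
        assert tsb.between(30, 500).all()
        assert 100 < tsb.median() < 300
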