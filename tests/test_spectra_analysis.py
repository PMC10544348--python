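"""ROI extraction, L1 normalisation, saturation rejection, dE00 reporting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import flat_scene

from lfhsi.camera_model import SensorConfig, simulate_capture
from lfhsi.colorimetry import ciede2000, spectrum_to_xyz, xyz_to_lab
from lfhsi.phantom_scenes import (
    ReflectanceSpectrum,
    make_tile_palette,
    render_tissue_scene,
)
from lfhsi.pipeline import run_checker_validation
from lfhsi.config import PipelineConfig
from lfhsi.reconstruction import CLIP_CEILING, Hypercube, reconstruct
from lfhsi.spectra_analysis import (
    DeltaEReport,
    LabelMask,
    extract_roi_spectra,
    l1_normalize,
    reject_saturated,
    tile_center_regions,
    validate_against_reference,
)


class TestRejectSaturated:
    def _capture(self, band_grid, default_bank, geometry, quiet_sensor,
                 smooth_illuminant):
        scene = flat_scene(band_grid, level=0.5, shape=(10, 10))
        return simulate_capture(
            scene, smooth_illuminant, default_bank, geometry, quiet_sensor,
            noise=False,
        )

    def test_unsaturated_capture_is_all_valid(
        self, band_grid, default_bank, geometry, quiet_sensor, smooth_illuminant
    ):
        cap = self._capture(band_grid, default_bank, geometry, quiet_sensor,
                            smooth_illuminant)
        assert cap.sample.max() < 4095
        assert reject_saturated(cap).all()

    def test_planted_specular_pixel_detected(
        self, band_grid, default_bank, geometry, quiet_sensor, smooth_illuminant
    ):
        cap = self._capture(band_grid, default_bank, geometry, quiet_sensor,
                            smooth_illuminant)
        # lenslet 27 (row 2, col 5 of the 6x11 lattice) has sub-half-pixel
        # disparity, so its saturation flag stays on the same pixel
        center = 27
        assert np.abs(cap.geometry.disparities(25.0)[center]).max() < 0.5
        cap.sample[center, 4, 7] = 4095
        valid = reject_saturated(cap)
        assert not valid[4, 7]
        assert valid.sum() == valid.size - 1

    def test_threshold_matches_brute_force_on_ramp(
        self, band_grid, default_bank, geometry, quiet_sensor, smooth_illuminant
    ):
        cap = self._capture(band_grid, default_bank, geometry, quiet_sensor,
                            smooth_illuminant)
        rng = np.random.default_rng(0)
        cap.sample = rng.integers(0, 4096, cap.sample.shape).astype(np.uint16)
        # drop the recorded depth so masks combine without shifting, as the
        # brute-force oracle does
        from lfhsi.camera_model import LensletGeometry

        cap.geometry = LensletGeometry(depth_cm=None)
        frac = 0.98
        valid = reject_saturated(cap, saturation_fraction=frac)
        brute = np.ones(valid.shape, bool)
        for i in range(cap.n_lenslets):
            for y in range(valid.shape[0]):
                for x in range(valid.shape[1]):
                    if cap.sample[i, y, x] >= frac * 4095:
                        brute[y, x] = False
        np.testing.assert_array_equal(valid, brute)

    def test_cube_fallback_uses_clip_ceiling(self, band_grid):
        vals = np.full((6, 6, 155), 0.5)
        vals[2, 3, 10] = CLIP_CEILING
        cube = Hypercube(values=vals, wavelengths=band_grid)
        valid = reject_saturated(cube)
        assert not valid[2, 3] and valid.sum() == 35


class TestExtractRoi:
    def test_constant_region_mean_and_zero_std(self, band_grid):
        vals = np.zeros((6, 6, 155))
        s = np.linspace(0.1, 0.9, 155)
        vals[1:4, 1:4] = s
        cube = Hypercube(values=vals, wavelengths=band_grid)
        mask = np.zeros((6, 6), int)
        mask[1:4, 1:4] = 1
        table = extract_roi_spectra(cube, LabelMask(mask))
        np.testing.assert_allclose(table.mean[0], s)
        np.testing.assert_allclose(table.std[0], 0.0, atol=1e-12)
        assert table.n_pixels_total[0] == table.n_pixels_valid[0] == 9

    def test_two_point_mean(self, band_grid):
        a = np.full(155, 0.2)
        b = np.full(155, 0.6)
        vals = np.zeros((2, 2, 155))
        vals[0, 0], vals[0, 1] = a, b
        cube = Hypercube(values=vals, wavelengths=band_grid)
        mask = np.array([[1, 1], [0, 0]])
        table = extract_roi_spectra(cube, LabelMask(mask))
        np.testing.assert_allclose(table.mean[0], 0.4)

    def test_matches_brute_force_oracle(self, band_grid):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 1, (12, 10, 155))
        cube = Hypercube(values=vals, wavelengths=band_grid)
        mask = rng.integers(0, 4, (12, 10))
        valid = rng.uniform(size=(12, 10)) > 0.2
        table = extract_roi_spectra(cube, LabelMask(mask), valid)
        for i, lab in enumerate(table.labels):
            px = [
                vals[y, x]
                for y in range(12)
                for x in range(10)
                if mask[y, x] == lab and valid[y, x]
            ]
            px = np.array(px)
            np.testing.assert_allclose(table.mean[i], px.mean(axis=0),
                                       atol=1e-12)
            np.testing.assert_allclose(table.std[i], px.std(axis=0, ddof=0),
                                       atol=1e-12)

    def test_label_with_no_valid_pixels_reported_nan(self, band_grid):
        cube = Hypercube(values=np.full((4, 4, 155), 0.5),
                         wavelengths=band_grid)
        mask = np.zeros((4, 4), int)
        mask[0, 0] = 2
        table = extract_roi_spectra(
            cube, LabelMask(mask), valid=np.zeros((4, 4), bool)
        )
        assert table.n_pixels_valid[0] == 0
        assert np.isnan(table.mean[0]).all()

    def test_dim_mismatch_rejected(self, band_grid):
        cube = Hypercube(values=np.zeros((4, 4, 155)), wavelengths=band_grid)
        with pytest.raises(ValueError):
            extract_roi_spectra(cube, LabelMask(np.zeros((5, 5), int)))


class TestL1Normalize:
    def test_arithmetic_example(self):
        np.testing.assert_allclose(
            l1_normalize(np.array([2.0, 2.0, 4.0])), [0.25, 0.25, 0.5]
        )

    def test_idempotent(self):
        v = l1_normalize(np.array([0.3, 0.5, 0.2]))
        np.testing.assert_allclose(l1_normalize(v), v, atol=1e-15)

    @given(
        st.lists(
            st.floats(0.0, 10.0, allow_subnormal=False), min_size=2,
            max_size=200,
        ),
        st.floats(1e-3, 1e3),
    )
    @settings(max_examples=1000, deadline=None)
    def test_unit_sum_and_scale_invariance(self, values, alpha):
        s = np.array(values)
        if s.sum() <= 0:
            with pytest.raises(ValueError):
                l1_normalize(s)
            return
        out = l1_normalize(s)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(l1_normalize(alpha * s), out, atol=1e-9)

    def test_rejects_negative_or_zero(self):
        with pytest.raises(ValueError):
            l1_normalize(np.array([0.5, -0.1]))
        with pytest.raises(ValueError):
            l1_normalize(np.zeros(5))


class TestTileCenterRegions:
    def test_full_fraction_keeps_rectangles(self):
        mask = np.zeros((20, 20), int)
        mask[2:10, 3:12] = 1
        out = tile_center_regions(LabelMask(mask), 1.0)
        np.testing.assert_array_equal(out.labels, mask)

    def test_half_fraction_on_16px_tile(self):
        mask = np.zeros((20, 20), int)
        mask[2:18, 2:18] = 1
        out = tile_center_regions(LabelMask(mask), 0.5)
        expected = np.zeros((20, 20), int)
        expected[6:14, 6:14] = 1
        np.testing.assert_array_equal(out.labels, expected)

    def test_irregular_region_matches_box_intersection_oracle(self):
        rng = np.random.default_rng(5)
        mask = np.zeros((30, 30), int)
        blob = rng.uniform(size=(30, 30)) > 0.6
        mask[blob] = 3
        out = tile_center_regions(LabelMask(mask), 0.5)
        ys, xs = np.nonzero(mask == 3)
        y0, y1 = ys.min(), ys.max() + 1
        x0, x1 = xs.min(), xs.max() + 1
        kh = max(1, round(0.5 * (y1 - y0)))
        kw = max(1, round(0.5 * (x1 - x0)))
        cy0 = y0 + (y1 - y0 - kh) // 2
        cx0 = x0 + (x1 - x0 - kw) // 2
        brute = np.zeros_like(mask)
        for y in range(30):
            for x in range(30):
                if mask[y, x] == 3 and cy0 <= y < cy0 + kh and cx0 <= x < cx0 + kw:
                    brute[y, x] = 3
        np.testing.assert_array_equal(out.labels, brute)


class TestValidateAgainstReference:
    def test_exact_match_gives_zero_everywhere(self, band_grid):
        pal = make_tile_palette(4, 2, seed=9, grid=band_grid)
        vals = np.stack([pal[k].reflectance for k in sorted(pal)])
        cube_vals = vals.reshape(1, 6, 155).repeat(4, axis=0)
        cube = Hypercube(values=cube_vals, wavelengths=band_grid)
        mask = np.tile(np.arange(1, 7), (4, 1))
        table = extract_roi_spectra(cube, LabelMask(mask))
        report = validate_against_reference(table, pal)
        assert report.max_delta_e == pytest.approx(0.0, abs=1e-9)
        assert (report.table["verdict"] == "imperceptible").all()

    def test_composed_stage_oracle_on_grays(self, band_grid):
        cube = Hypercube(values=np.full((4, 4, 155), 0.55),
                         wavelengths=band_grid)
        mask = np.ones((4, 4), int)
        table = extract_roi_spectra(cube, LabelMask(mask))
        ref = {1: ReflectanceSpectrum(band_grid, np.full(155, 0.5))}
        report = validate_against_reference(table, ref)
        lam = band_grid.values
        expected = ciede2000(
            xyz_to_lab(spectrum_to_xyz(lam, np.full(155, 0.55))),
            xyz_to_lab(spectrum_to_xyz(lam, np.full(155, 0.5))),
        )
        assert report.table["delta_e"][0] == pytest.approx(expected, abs=1e-9)

    def test_missing_reference_lists_labels(self, band_grid):
        cube = Hypercube(values=np.full((2, 2, 155), 0.5),
                         wavelengths=band_grid)
        mask = np.array([[1, 1], [2, 2]])
        table = extract_roi_spectra(cube, LabelMask(mask))
        with pytest.raises(KeyError, match="2"):
            validate_against_reference(
                table, {1: ReflectanceSpectrum(band_grid, np.full(155, 0.5))}
            )

    @pytest.mark.parametrize(
        "de,verdict",
        [(0.0, "imperceptible"), (1.99, "imperceptible"), (2.0, "acceptable"),
         (5.99, "acceptable"), (6.0, "unacceptable")],
    )
    def test_verdict_bins_are_half_open(self, de, verdict):
        assert DeltaEReport.verdict(de) == verdict


class TestBloodTint:
    def test_red_to_green_ratio_increases_with_blood_fraction(self, band_grid):
        """More surface blood shifts L1-normalised spectra toward the red."""
        classes = make_tile_palette(2, 0, seed=21, grid=band_grid)
        lam = band_grid.values
        red = (lam >= 620) & (lam <= 700)
        green = (lam >= 500) & (lam <= 580)
        ratios = []
        for f in (0.0, 0.25, 0.5, 0.75):
            scene = render_tissue_scene(
                classes, blob_count=4, blood_fraction=f, seed=13,
                shape=(48, 48),
            )
            cube = Hypercube(values=scene.cube, wavelengths=band_grid)
            table = extract_roi_spectra(cube, LabelMask(scene.truth_mask))
            norm = l1_normalize(table.mean[1])
            ratios.append(norm[red].sum() / norm[green].sum())
        assert all(a < b for a, b in zip(ratios, ratios[1:]))

    def test_red_shift_survives_the_full_pipeline(
        self, default_bank, geometry, smooth_illuminant, band_grid
    ):
        classes = make_tile_palette(2, 0, seed=21, grid=band_grid)
        lam = band_grid.values
        red = (lam >= 620) & (lam <= 700)
        green = (lam >= 500) & (lam <= 580)
        ratios = []
        for f in (0.0, 0.5):
            scene = render_tissue_scene(
                classes, blob_count=4, blood_fraction=f, seed=13, shape=(32, 32)
            )
            cap = simulate_capture(
                scene, smooth_illuminant, default_bank, geometry,
                SensorConfig(seed=1),
            )
            cube = reconstruct(cap)
            table = extract_roi_spectra(cube, LabelMask(scene.truth_mask))
            norm = l1_normalize(np.clip(table.mean[1], 1e-9, None))
            ratios.append(norm[red].sum() / norm[green].sum())
        assert ratios[0] < ratios[1]


class TestEndToEndFidelity:
    def test_noiseless_checker_is_imperceptible(self):
        run = run_checker_validation(PipelineConfig(noise=False, seed=0))
        assert len(run.report.table) == 24
        assert run.report.max_delta_e < 2.0

    def test_noisy_checker_is_commercially_acceptable(self):
        worst = max(
            run_checker_validation(
                PipelineConfig(noise=True), seed=s
            ).report.max_delta_e
            for s in range(5)
        )
        assert worst < 6.0
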