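"""Synthetic monolayer generation and cell-death-area measurement."""

import math

import numpy as np
import pytest

import pfacalc as pf
from pfacalc.imaging import UnsupportedChannelError

# noise level used for robustness checks: 10% of the rendered dynamic range
NOISE_10PCT = 0.08


@pytest.fixture(scope="module")
def clean_scene(study_map):
    return pf.generate_synthetic_monolayer(study_map, 7.66, seed=0)


class TestSyntheticGenerator:
    def test_noiseless_measurement_matches_ground_truth(self, clean_scene):
        res = pf.measure_death_area(clean_scene.calcein)
        px_mm = clean_scene.calcein.pixel_size / 1000.0
        # within one pixel ring around the region boundary
        perimeter_px = np.count_nonzero(
            clean_scene.death_mask ^ np.roll(clean_scene.death_mask, 1, axis=0)
        )
        tol = perimeter_px * px_mm**2
        assert abs(res.area - clean_scene.true_area) <= max(tol, px_mm**2)

    def test_fixed_seed_is_bit_identical(self, study_map):
        a = pf.generate_synthetic_monolayer(study_map, 7.66, noise_sd=0.1, seed=42)
        b = pf.generate_synthetic_monolayer(study_map, 7.66, noise_sd=0.1, seed=42)
        assert np.array_equal(a.calcein.pixels, b.calcein.pixels)
        assert np.array_equal(a.pi.pixels, b.pi.pixels)

    def test_geometry_must_fit_field_of_view(self, study_map):
        with pytest.raises(ValueError):
            pf.generate_synthetic_monolayer(study_map, 7.66, fov_mm=1.0)

    def test_region_must_fit_field_of_view(self, study_map):
        # a very low threshold paints a region larger than the image
        with pytest.raises(ValueError, match="border"):
            pf.generate_synthetic_monolayer(study_map, 0.5, fov_mm=4.0)

    def test_coarse_pixels_rejected(self, study_map):
        with pytest.raises(ValueError, match="20"):
            pf.generate_synthetic_monolayer(study_map, 7.66, pixel_size=30.0)


class TestAutomatedMeasurement:
    def test_recovery_within_two_percent_noiseless(self, clean_scene):
        res = pf.measure_death_area(clean_scene.calcein)
        assert res.area == pytest.approx(clean_scene.true_area, rel=0.02)

    def test_recovery_under_noise_and_uneven_illumination(self, study_map):
        errs = []
        for seed in range(20):
            scene = pf.generate_synthetic_monolayer(
                study_map, 7.66, noise_sd=NOISE_10PCT,
                illumination_gradient=0.1, seed=seed,
            )
            res = pf.measure_death_area(scene.calcein)
            errs.append(abs(res.area - scene.true_area) / scene.true_area)
        assert max(errs) <= 0.03

    def test_calcein_and_pi_channels_agree(self, study_map):
        scene = pf.generate_synthetic_monolayer(
            study_map, 7.66, noise_sd=0.05, illumination_gradient=0.05, seed=5
        )
        ca = pf.measure_death_area(scene.calcein).area
        pi = pf.measure_death_area(scene.pi).area
        assert abs(ca - pi) / ca <= 0.05

    def test_uniform_image_reports_zero_with_diagnostic(self):
        img = pf.MonolayerImage(np.full((200, 200), 0.9), 10.0, "calcein")
        res = pf.measure_death_area(img)
        assert res.area == 0.0
        assert res.diagnostic

    def test_invariant_to_linear_intensity_rescaling(self, clean_scene):
        base = pf.measure_death_area(clean_scene.calcein).area
        rescaled = pf.MonolayerImage(
            clean_scene.calcein.pixels * 37.0 + 5.0, 10.0, "calcein"
        )
        assert pf.measure_death_area(rescaled).area == pytest.approx(base, rel=1e-9)

    def test_measured_area_monotone_in_ground_truth(self, study_map):
        pairs = []
        for eft in (10.0, 7.66, 5.0, 3.5):
            scene = pf.generate_synthetic_monolayer(
                study_map, eft, noise_sd=0.05, seed=2
            )
            pairs.append((scene.true_area, pf.measure_death_area(scene.calcein).area))
        truths, measured = zip(*sorted(pairs))
        assert all(a <= b for a, b in zip(measured, measured[1:]))

    def test_hoechst_channel_unsupported(self, clean_scene):
        with pytest.raises(UnsupportedChannelError):
            pf.measure_death_area(clean_scene.hoechst)

    def test_wand_matches_automated_on_clean_scene(self, clean_scene):
        auto = pf.measure_death_area(clean_scene.calcein).area
        n = clean_scene.calcein.pixels.shape[0]
        wand = pf.measure_death_area(
            clean_scene.calcein, method="wand",
            wand_seed=(n // 2, n // 2), wand_tolerance=0.3,
        ).area
        assert wand == pytest.approx(auto, rel=0.02)


def _sham_image(radius_mm: float, geometry, pixel_size_um=10.0, fov_mm=6.0):
    px_mm = pixel_size_um / 1000.0
    n = int(round(fov_mm / px_mm))
    coords = (np.arange(n) + 0.5) * px_mm - fov_mm / 2
    X, Y = np.meshgrid(coords, coords, indexing="ij")
    half = geometry.center_distance / 2
    imprint = ((X - half) ** 2 + Y**2 <= radius_mm**2) | (
        (X + half) ** 2 + Y**2 <= radius_mm**2
    )
    return pf.MonolayerImage(np.where(imprint, 0.05, 0.85), pixel_size_um, "calcein")


class TestImprints:
    def test_sham_imprint_area(self, geometry):
        sham = _sham_image(geometry.radius, geometry)
        area = pf.quantify_imprint(sham)
        assert area == pytest.approx(2 * math.pi * geometry.radius**2, rel=0.03)

    def test_blank_sham_gives_zero(self):
        blank = pf.MonolayerImage(np.full((100, 100), 0.8), 10.0, "calcein")
        assert pf.quantify_imprint(blank) == 0.0

    def test_doubled_radius_quadruples_area(self, geometry):
        small = pf.quantify_imprint(_sham_image(0.2, geometry))
        large = pf.quantify_imprint(_sham_image(0.4, geometry))
        assert large == pytest.approx(4 * small, rel=0.05)

    def test_wrong_component_count_warns(self, geometry):
        px = np.full((200, 200), 0.85)
        px[50:70, 50:70] = 0.05  # a single square blot
        with pytest.warns(UserWarning, match="found 1"):
            pf.quantify_imprint(pf.MonolayerImage(px, 10.0, "calcein"))

    def test_subtraction_arithmetic(self):
        res = pf.DeathAreaResult(
            area=2.77, method="automated", imprint_subtracted=False, mask=None
        )
        out = pf.subtract_imprint(res, 0.77)
        assert out.area == pytest.approx(2.00)
        assert out.imprint_subtracted

    def test_subtraction_of_zero_is_identity(self):
        res = pf.DeathAreaResult(
            area=1.5, method="automated", imprint_subtracted=False, mask=None
        )
        assert pf.subtract_imprint(res, 0.0).area == 1.5

    def test_oversubtraction_floors_at_zero_with_warning(self):
        res = pf.DeathAreaResult(
            area=0.5, method="automated", imprint_subtracted=False, mask=None
        )
        with pytest.warns(UserWarning, match="clipping"):
            out = pf.subtract_imprint(res, 0.77)
        assert out.area == 0.0


class TestFileIO:
    def test_tiff_round_trip(self, clean_scene, tmp_path):
        path = tmp_path / "scene.tif"
        clean_scene.calcein.to_file(path)
        back = pf.MonolayerImage.from_file(path, pixel_size=10.0, channel="calcein")
        res = pf.measure_death_area(back)
        assert res.area == pytest.approx(clean_scene.true_area, rel=0.02)
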