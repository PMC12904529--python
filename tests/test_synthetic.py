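import numpy as np
import pytest

from turbimap.calibration import PAPER_CALIBRATION
from turbimap.errors import ValidationError
from turbimap.synthetic import (
    CameraModel,
    GrowthScenario,
    OpticalProperties,
    antibiotic_scenario,
    apply_camera,
    banded_scenario,
    fermentation_scenario,
    render_views,
    simulate_growth_series,
    surface_intensity,
    view_layout,
)
from turbimap.unwrapping import unwrap

from conftest import seam_margin_mask


def liquid_region(geometry, field):
    """Mask of pixels untouched by dark masks (liquid, non-baffle)."""
    from turbimap.synthetic import _dark_mask

    return _dark_mask(geometry) == 1.0


class TestSurfaceIntensity:
    def row_profile(self, geometry, mu_eff, spot):
        field = surface_intensity(
            geometry, OpticalProperties(mu_eff=mu_eff), spot, amplitude=1e6
        )
        row = int(np.argmin(np.abs(field.height_mm - spot[1])))
        d = geometry.circular_arc_difference(field.arc_mm, spot[0])
        return d, field.values[row], field

    def test_decay_ratio_closed_form(self, small_geometry, centered_spot):
        # I(d1)/I(d2) = (d2/d1)^2 * exp(mu * (d2 - d1)) at actual sample distances
        d, row, _ = self.row_profile(small_geometry, 0.1, centered_spot)
        near = np.argmin(np.abs(d - 5.0))
        far = np.argmin(np.abs(d - 10.0))
        d1, d2 = d[near], d[far]
        expected = (d2 / d1) ** 2 * np.exp(0.1 * (d2 - d1))
        assert row[near] / row[far] == pytest.approx(expected, rel=1e-12)
        # with d1, d2 ~ (5, 10) mm this ratio is ~4 * e^0.5 ~ 6.595
        assert row[near] / row[far] == pytest.approx(4 * np.exp(0.5), rel=2e-2)

    def test_pure_inverse_square_when_clear(self, small_geometry, centered_spot):
        d, row, _ = self.row_profile(small_geometry, 0.0, centered_spot)
        near = np.argmin(np.abs(d - 5.0))
        far = np.argmin(np.abs(d - 10.0))
        assert row[near] / row[far] == pytest.approx((d[far] / d[near]) ** 2, rel=1e-12)

    def test_log_slope_matches_mueff(self, small_geometry, centered_spot):
        # ln(I d^2) difference between ~5 and ~30 mm equals -mu * (d2 - d1)
        mu = 0.0998
        d, row, _ = self.row_profile(small_geometry, mu, centered_spot)
        near = np.argmin(np.abs(d - 5.0))
        far = np.argmin(np.abs(d - 30.0))
        lhs = np.log(row[far] * d[far] ** 2) - np.log(row[near] * d[near] ** 2)
        assert lhs == pytest.approx(-mu * (d[far] - d[near]), rel=1e-9)
        assert lhs == pytest.approx(-2.495, rel=2e-2)

    def test_strictly_decreasing_beyond_pitch(self, small_geometry, centered_spot):
        d, row, field = self.row_profile(small_geometry, 0.05, centered_spot)
        keep = liquid_region(small_geometry, field)[0] & (d > small_geometry.camera_pixel_pitch_mm)
        right = row[keep & (d > 0)]
        assert np.all(np.diff(right) < 0)

    def test_product_with_d_squared_constant_when_clear(self, small_geometry, centered_spot):
        field = surface_intensity(
            small_geometry, OpticalProperties(mu_eff=0.0), centered_spot, amplitude=1e6
        )
        ds = small_geometry.circular_arc_difference(field.arc_mm, centered_spot[0])
        dh = field.height_mm - centered_spot[1]
        d = np.hypot(dh[:, None], ds[None, :])
        keep = liquid_region(small_geometry, field) & (d > small_geometry.camera_pixel_pitch_mm)
        product = field.values[keep] * d[keep] ** 2
        assert np.ptp(product) / product.mean() < 1e-9

    def test_masks_darken_air_and_baffles(self, small_geometry, centered_spot):
        field = surface_intensity(
            small_geometry, OpticalProperties(mu_eff=0.1), centered_spot, amplitude=1e6
        )
        dark = ~liquid_region(small_geometry, field)
        assert dark.any()
        air_rows = field.height_mm < small_geometry.liquid_top_mm
        assert air_rows.any()
        # air-band pixels are attenuated relative to the same distance in liquid
        assert np.all(dark[air_rows, :])

    def test_invalid_inputs(self, small_geometry, centered_spot):
        with pytest.raises(ValidationError):
            surface_intensity(small_geometry, OpticalProperties(0.1), centered_spot, amplitude=0.0)
        with pytest.raises(ValidationError):
            surface_intensity(
                small_geometry, OpticalProperties(0.1),
                (centered_spot[0], 0.5 * small_geometry.liquid_top_mm),
            )


class TestOpticalProperties:
    def test_coefficient_consistency_enforced(self):
        ok = OpticalProperties.from_coefficients(0.01, 1.0)
        assert ok.mu_eff == pytest.approx(np.sqrt(0.03))
        with pytest.raises(ValidationError):
            OpticalProperties(mu_eff=0.5, mu_a=0.01, mu_s_prime=1.0)

    def test_background_floor_adds(self):
        opt = OpticalProperties(mu_eff=0.02, background_mu_eff=7.58e-2)
        assert opt.total_mu_eff == pytest.approx(0.0958)


class TestRenderViews:
    def test_uniform_field_renders_uniform_regions(self, small_geometry):
        u = np.full((small_geometry.n_rows, small_geometry.n_arc), 3.25)
        render = render_views(u, small_geometry)
        for reg in render.layout.regions:
            block = render.values[
                reg.row0 : reg.row0 + reg.n_rows, reg.col0 : reg.col0 + reg.n_cols
            ]
            np.testing.assert_allclose(block, 3.25, rtol=1e-12)

    def test_rear_marker_lands_in_one_mirror_region_flipped(self, small_geometry):
        geo = small_geometry
        u = np.zeros((geo.n_rows, geo.n_arc))
        theta_marker = 2.0  # rear-left sector
        col = int(np.argmin(np.abs(geo.theta_centers() - theta_marker)))
        u[geo.n_rows // 2, col] = 100.0
        render = render_views(u, geo)
        regions = {r.label: r for r in render.layout.regions}
        sums = {
            label: render.values[:, r.col0 : r.col0 + r.n_cols].sum()
            for label, r in regions.items()
        }
        assert sums["rear_left"] > 0
        assert sums["front"] == 0 and sums["rear_right"] == 0
        # hand-computed projection: x' = -R sin(theta - theta_c) inside rear_left
        reg = regions["rear_left"]
        theta_c = 0.5 * sum(reg.sector)
        xp = -geo.radius_mm * np.sin(theta_marker - theta_c)
        expected_col = reg.col0 + (xp + reg.x_half_mm) / (2 * reg.x_half_mm) * reg.n_cols
        _, got_col = np.unravel_index(np.argmax(render.values), render.values.shape)
        assert abs(got_col - expected_col) <= 1.5

    def test_round_trip_on_smooth_field(self, small_geometry, centered_spot):
        field = surface_intensity(
            small_geometry, OpticalProperties(mu_eff=0.08), centered_spot, amplitude=1e6
        )
        render = render_views(field, small_geometry)
        back = unwrap(render.values, render.layout.polygons(), small_geometry)
        rel = np.abs(back.values / field.values - 1)
        seam = seam_margin_mask(back.provenance)
        # also exclude dark-mask discontinuities and the spot singularity
        from turbimap.synthetic import _dark_mask
        from scipy.ndimage import binary_dilation

        dm = _dark_mask(small_geometry)
        edges = binary_dilation(
            (np.abs(np.diff(dm, axis=1, append=dm[:, :1])) > 0)
            | (np.abs(np.diff(dm, axis=0, append=dm[-1:, :])) > 0),
            iterations=3,
        )
        ds = small_geometry.circular_arc_difference(back.arc_mm, centered_spot[0])
        dh = back.height_mm - centered_spot[1]
        d = np.hypot(dh[:, None], ds[None, :])
        keep = ~seam & ~edges & (d > 3.0)
        assert np.sqrt(np.mean(rel[keep] ** 2)) < 0.02

    def test_regions_are_disjoint(self, small_geometry):
        layout = view_layout(small_geometry)
        spans = sorted((r.col0, r.col0 + r.n_cols) for r in layout.regions)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert a1 < b0  # padding columns between regions


class TestApplyCamera:
    def test_dark_scene_reads_black_level(self):
        frame = apply_camera(np.zeros((8, 8)), 1.0, read_noise_sd=0.0, seed=0)
        assert np.all(frame.values == 100)

    def test_mean_matches_expectation(self):
        rng = np.random.default_rng(42)
        scene = np.full((200, 200), 50.0)
        frame = apply_camera(scene, 4.0, gain=2.0, read_noise_sd=3.0,
                             full_well=1e9, rng=rng)
        expected = 100.0 + 2.0 * 50.0 * 4.0
        n = scene.size
        se = np.sqrt((2.0**2 * 200.0 + 3.0**2) / n)
        assert abs(frame.values.mean() - expected) < 3 * se + 0.5  # +quantisation

    def test_saturation_clamps_to_full_well(self):
        scene = np.full((4, 4), 1e6)
        frame = apply_camera(scene, 10.0, seed=1)
        assert np.all(frame.values == 65535)

    def test_seeded_determinism(self):
        scene = np.linspace(0, 100, 64).reshape(8, 8)
        a = apply_camera(scene, 2.0, seed=123)
        b = apply_camera(scene, 2.0, seed=123)
        np.testing.assert_array_equal(a.values, b.values)

    def test_negative_scene_rejected(self):
        with pytest.raises(ValidationError):
            apply_camera(np.array([[-1.0]]), 1.0, seed=0)


class TestGrowthScenarios:
    def test_constant_density_truth_is_unity(self):
        scen = antibiotic_scenario(n_timepoints=4)
        np.testing.assert_allclose(scen.truth_map().growth, 1.0)

    def test_uniform_doubling_truth(self):
        scen = GrowthScenario(
            density_profile=lambda h, t: 1e9 * (1.0 + (t > 0)),
            timepoints_h=(0.0, 1.0),
            laser_heights_mm=(20.0, 40.0),
        )
        np.testing.assert_allclose(scen.truth_map().growth[:, 1], 2.0)

    def test_fermentation_default_targets_twofold(self):
        truth = fermentation_scenario().truth_map()
        assert truth.growth[:, -1].mean() == pytest.approx(2.0, abs=0.01)

    def test_banded_scenario_has_three_bands(self):
        truth = banded_scenario().truth_map()
        final = truth.growth[:, -1]
        heights = truth.heights_mm
        assert final[heights < 45].mean() == pytest.approx(2.5, abs=0.01)
        assert final[(heights > 45) & (heights < 80)].mean() == pytest.approx(1.5, abs=0.01)

    def test_opacity_warning(self):
        scen = antibiotic_scenario(n_timepoints=2, rho0=1e12)
        with pytest.warns(UserWarning, match="opacity"):
            simulate_growth_series(scen)

    def test_dataset_stacks_are_reproducible(self, camera):
        scen = antibiotic_scenario(
            n_timepoints=2, rng_seed=5,
            laser_heights_mm=(30.0,), timepoints_h=(0.0, 1.0),
        )
        ds = simulate_growth_series(scen, calibration=PAPER_CALIBRATION, camera=camera)
        a = ds.stack_for(1, 0)
        b = ds.stack_for(1, 0)
        for fa, fb in zip(a.frames, b.frames):
            np.testing.assert_array_equal(fa.values, fb.values)
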