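import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from turbimap.errors import DegenerateDataError, InsufficientSamplesError, ValidationError
from turbimap.geometry import VesselGeometry
from turbimap.scattering import (
    IntensityProfile,
    acquisition_schedule,
    extract_profile,
    fit_mueff,
    fit_spot,
    linearize,
    mueff_from_coefficients,
    scan_plan,
)
from turbimap.synthetic import OpticalProperties, surface_intensity


def forward_profile(mu_eff, amplitude=1.0, d=None, noise_sd=0.0, seed=0):
    """Analytic exp(-mu d)/d^2 samples, optionally with lognormal noise."""
    if d is None:
        d = np.linspace(5.0, 30.0, 26)
    intensity = amplitude * np.exp(-mu_eff * d) / d**2
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity * np.exp(rng.normal(0.0, noise_sd, d.size))
    return IntensityProfile(distances=d, intensities=intensity, laser_spot=(0.0, 0.0),
                            window=(float(d.min()), float(d.max())))


def grid_search_mueff(d, y, lo=-0.1, hi=0.5, n=301, n_zoom=60):
    """Brute-force oracle: minimise SSE of y = -mu d + k over a refined grid."""
    best = None
    for _ in range(6):
        mus = np.linspace(lo, hi, n)
        sse = np.empty(n)
        for i, mu in enumerate(mus):
            k = np.mean(y + mu * d)
            sse[i] = np.sum((y - (-mu * d + k)) ** 2)
        i = int(np.argmin(sse))
        best = mus[i]
        half = (hi - lo) / n_zoom
        lo, hi = best - half, best + half
    return best


class TestLinearize:
    @pytest.mark.parametrize(
        "intensity, d, expected",
        [(1.0, 1.0, 0.0), (np.exp(-2) / 4.0, 2.0, -2.0)],
    )
    def test_point_values(self, intensity, d, expected):
        prof = IntensityProfile(distances=np.array([d, d + 1, d + 2]),
                                intensities=np.array([intensity, 1.0, 1.0]),
                                laser_spot=(0, 0), window=(d, d + 2))
        _, y = linearize(prof)
        assert y[0] == pytest.approx(expected, abs=1e-12)

    def test_forward_model_is_affine_in_d(self):
        mu, amp = 0.1, 7.3
        prof = forward_profile(mu, amplitude=amp)
        d, y = linearize(prof)
        np.testing.assert_allclose(y, -mu * d + np.log(amp), atol=1e-12)


class TestFitMueff:
    @pytest.mark.parametrize("mu", [0.02, 0.1, 0.3])
    def test_exact_on_noiseless_profiles(self, mu):
        fit = fit_mueff(forward_profile(mu))
        assert fit.mu_eff == pytest.approx(mu, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_inverse_square_gives_zero(self):
        fit = fit_mueff(forward_profile(0.0))
        assert fit.mu_eff == pytest.approx(0.0, abs=1e-12)

    def test_negative_mueff_reported_not_raised(self):
        # near-clear media can fit a negative slope; flagged, not an error
        fit = fit_mueff(forward_profile(-0.05))
        assert fit.mu_eff == pytest.approx(-0.05, rel=1e-9)
        assert not fit.scattering_detected

    def test_matches_grid_search_oracle_under_noise(self):
        prof = forward_profile(0.1, noise_sd=0.05, seed=42)
        fit = fit_mueff(prof)
        d, y = linearize(prof)
        oracle = grid_search_mueff(d, y)
        assert fit.mu_eff == pytest.approx(oracle, rel=1e-4)  # 4 significant figures
        assert abs(fit.mu_eff - 0.1) / 0.1 < 0.05

    def test_bias_vanishes_with_noise(self):
        biases = []
        for sd in (0.1, 0.05, 0.01):
            ests = [fit_mueff(forward_profile(0.1, noise_sd=sd, seed=s)).mu_eff
                    for s in range(60)]
            biases.append(abs(np.mean(ests) - 0.1))
        assert biases[2] < 0.001
        assert biases[2] <= biases[0] + 1e-4

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_intensity_scale_invariance(self, scale):
        base = forward_profile(0.1, noise_sd=0.05, seed=7)
        scaled = IntensityProfile(distances=base.distances,
                                  intensities=base.intensities * scale,
                                  laser_spot=base.laser_spot, window=base.window)
        f0, f1 = fit_mueff(base), fit_mueff(scaled)
        assert f1.mu_eff == pytest.approx(f0.mu_eff, abs=1e-12)
        assert f1.k - f0.k == pytest.approx(np.log(scale), abs=1e-9)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(c=st.floats(min_value=0.1, max_value=10.0))
    def test_distance_rescaling_equivariance(self, c):
        base = forward_profile(0.1, noise_sd=0.05, seed=9)
        rescaled = IntensityProfile(distances=base.distances * c,
                                    intensities=base.intensities,
                                    laser_spot=base.laser_spot,
                                    window=(base.window[0] * c, base.window[1] * c))
        f0 = fit_mueff(base)
        f1 = fit_mueff(rescaled)
        assert f1.mu_eff == pytest.approx(f0.mu_eff / c, rel=1e-9)

    def test_degenerate_distances_rejected(self):
        prof = IntensityProfile.__new__(IntensityProfile)  # bypass ordering check
        object.__setattr__(prof, "distances", np.array([5.0, 5.0, 5.0]))
        object.__setattr__(prof, "intensities", np.ones(3))
        object.__setattr__(prof, "laser_spot", (0, 0))
        object.__setattr__(prof, "window", (5.0, 5.0))
        with pytest.raises(DegenerateDataError):
            fit_mueff(prof)


class TestExtractProfile:
    def test_noiseless_scene_sampled_exactly(self, small_geometry, centered_spot, noiseless_scene):
        prof = extract_profile(noiseless_scene, centered_spot, side="right")
        expected = 1e6 * np.exp(-0.1 * prof.distances) / prof.distances**2
        np.testing.assert_allclose(prof.intensities, expected, rtol=1e-9)

    def test_sample_count_matches_pitch(self):
        geo = VesselGeometry(radius_mm=20.0, scan_window_height_mm=30.0,
                             liquid_top_mm=2.0, camera_pixel_pitch_mm=0.25,
                             baffles=())
        spot = (geo.front_arc_mm, float(geo.height_centers()[geo.n_rows // 2]))
        scene = surface_intensity(geo, OpticalProperties(mu_eff=0.1), spot)
        prof = extract_profile(scene, spot, side="right")
        assert 95 <= len(prof) <= 101  # ~(30-5)/0.25 samples per side

    def test_seam_adjacent_spot_uses_covered_side(self, small_geometry):
        geo = small_geometry
        spot = (10.0, float(geo.height_centers()[geo.n_rows // 2]))  # near arc = 0 seam
        scene = surface_intensity(geo, OpticalProperties(mu_eff=0.1), spot)
        prof = extract_profile(scene, spot)
        assert prof.side == "right"  # left window would run off the image start

    def test_too_few_valid_samples_raises(self, small_geometry, centered_spot, noiseless_scene):
        values = noiseless_scene.values.copy()
        row = int(np.argmin(np.abs(noiseless_scene.height_mm - centered_spot[1])))
        values[row, :] = np.nan
        broken = type(noiseless_scene)(values=values, arc_mm=noiseless_scene.arc_mm,
                                       height_mm=noiseless_scene.height_mm)
        with pytest.raises(InsufficientSamplesError):
            extract_profile(broken, centered_spot)

    def test_fit_spot_combines_both_sides(self, small_geometry, centered_spot, noiseless_scene):
        combined = fit_spot(noiseless_scene, centered_spot)
        left = fit_mueff(extract_profile(noiseless_scene, centered_spot, side="left"))
        right = fit_mueff(extract_profile(noiseless_scene, centered_spot, side="right"))
        assert combined.n_points == left.n_points + right.n_points
        lo, hi = sorted([left.mu_eff, right.mu_eff])
        assert lo <= combined.mu_eff <= hi


class TestMueffFromCoefficients:
    def test_zero_absorption(self):
        assert mueff_from_coefficients(0.0, 1.0) == 0.0
        assert mueff_from_coefficients(0.0, 1.0, "product") == 0.0

    def test_default_sqrt_convention(self):
        assert mueff_from_coefficients(0.01, 1.0) == pytest.approx(np.sqrt(0.03))

    def test_conventions_agree_at_fixed_point(self):
        assert mueff_from_coefficients(1 / 3, 1.0) == pytest.approx(1.0)
        assert mueff_from_coefficients(1 / 3, 1.0, "product") == pytest.approx(1.0)


class TestPlanners:
    def test_reference_scan_plan(self):
        heights = scan_plan(5.0, 125.0)
        assert len(heights) == 25
        np.testing.assert_allclose(np.diff(heights), 5.0)
        assert heights[0] == pytest.approx(2.5)

    def test_single_position(self):
        np.testing.assert_allclose(scan_plan(10.0, 10.0), [5.0])

    def test_non_multiple_span_floors_with_warning(self):
        with pytest.warns(UserWarning, match="not a multiple"):
            heights = scan_plan(5.0, 12.0)
        assert len(heights) == 2

    @pytest.mark.parametrize("spacing, span", [(0.0, 10.0), (5.0, 3.0)])
    def test_invalid_scan_inputs(self, spacing, span):
        with pytest.raises(ValidationError):
            scan_plan(spacing, span)

    @pytest.mark.parametrize(
        "interval_min, duration_h, expected",
        [(10.0, 23.0, 138), (60.0, 1.0, 1), (10.0, 1.05, 6)],
    )
    def test_schedule_counts(self, interval_min, duration_h, expected):
        times = acquisition_schedule(interval_min, duration_h)
        assert len(times) == expected
        assert times[0] == 0.0  # a T = 0 baseline always exists
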