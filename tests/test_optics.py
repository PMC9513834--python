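"""Interference-optics simulation: ray tracing, periods, duty cycle,
topography profiles and the position -> size calibration."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from nanomap import optics
from nanomap.optics import (
    ExposureParams,
    InterferometerGeometry,
    PositionNotIlluminatedError,
    TopographyProfile,
    build_topography_profile,
    exponential_profile,
    feature_size_to_position,
    fit_size_calibration,
    fringe_duty_cycle,
    grating_period_nm,
    local_period,
    position_to_feature_size,
    trace_reflected_angle,
)


def brute_force_reflected_angle(geometry, x_um, n=400_000):
    """Independent oracle: dense sweep of mirror points, reflect each ray,
    keep the one landing nearest the query position."""
    b = math.radians(geometry.beam_angle_deg)
    R = 2.0 * geometry.focal_length_mm
    d = np.array([-math.cos(b), -math.sin(b)])
    phi_max = math.pi / 2 - b if geometry.mirror_curvature_sign == "concave" \
        else math.radians(89.9)
    phis = np.linspace(1e-8, phi_max - 1e-9, n)
    if geometry.mirror_curvature_sign == "concave":
        P = np.stack([R - R * np.cos(phis), R * np.sin(phis)], 1)
        nrm = np.stack([np.cos(phis), -np.sin(phis)], 1)
    else:
        P = np.stack([-R + R * np.cos(phis), R * np.sin(phis)], 1)
        nrm = np.stack([np.cos(phis), np.sin(phis)], 1)
    dn = nrm @ d
    dp = d[None, :] - 2 * dn[:, None] * nrm
    ok = (dn < 0) & (dp[:, 1] < 0)
    t = -P[:, 1] / dp[:, 1]
    land_mm = P[:, 0] + t * dp[:, 0]
    # the public coordinate is distance from the foot on the patterned
    # (x<0) side for the concave gradient geometry
    target_mm = -x_um / 1000.0
    err = np.abs(land_mm - target_mm)
    err[~ok] = np.inf
    i = int(np.argmin(err))
    assert err[i] < 1e-3
    return math.degrees(math.atan2(-dp[i, 1], abs(dp[i, 0])))


class TestTraceReflectedAngle:
    def test_flat_mirror_limit_is_specular_everywhere(self):
        geom = InterferometerGeometry(focal_length_mm=1e7)
        angles = [trace_reflected_angle(geom, x) for x in (500, 3000, 9000)]
        for a in angles:
            assert a == pytest.approx(geom.beam_angle_deg, abs=1e-3)

    def test_matches_brute_force_sweep_at_midstrip(self, dlil_geometry,
                                                   dlil_profile):
        x = float(np.median(dlil_profile.positions_um))
        expected = brute_force_reflected_angle(dlil_geometry, x)
        assert trace_reflected_angle(dlil_geometry, x) == pytest.approx(
            expected, abs=0.05)

    def test_continuity_in_position(self, dlil_geometry, dlil_profile):
        x = float(np.median(dlil_profile.positions_um))
        a0 = trace_reflected_angle(dlil_geometry, x)
        for delta in (10.0, 1.0, 0.1):
            a1 = trace_reflected_angle(dlil_geometry, x + delta)
            assert abs(a1 - a0) < 0.5 * delta  # deg per um, generous slope
        assert abs(trace_reflected_angle(dlil_geometry, x + 0.1) - a0) < 1e-2

    def test_unilluminated_position_raises(self, dlil_geometry):
        # far beyond the gradient strip no reflected ray lands
        with pytest.raises(PositionNotIlluminatedError):
            trace_reflected_angle(dlil_geometry, 9_999_000.0)


class TestLocalPeriod:
    def test_symmetric_closed_forms(self):
        assert grating_period_nm(325.0, 30.0, 30.0) == pytest.approx(
            325.0, rel=1e-9)
        assert grating_period_nm(325.0, 90.0, 90.0) == pytest.approx(
            162.5, rel=1e-9)

    def test_period_at_least_half_wavelength(self, dlil_geometry,
                                             dlil_profile):
        lam_um = dlil_geometry.wavelength_nm * 1e-3
        assert np.all(dlil_profile.period_um >= lam_um / 2)

    def test_profile_span_matches_ray_tracing_oracle(self, dlil_geometry,
                                                     dlil_profile):
        # independently recompute min/max period from the brute-force sweep
        lam_um = dlil_geometry.wavelength_nm * 1e-3
        b = math.radians(dlil_geometry.beam_angle_deg)
        for x in (dlil_profile.positions_um[0],
                  dlil_profile.positions_um[-1]):
            theta2 = math.radians(brute_force_reflected_angle(
                dlil_geometry, float(x)))
            # reconstruct |dkx| from the grazing angle is ambiguous in
            # azimuth; accept either branch
            k2 = math.cos(theta2)
            candidates = [lam_um / abs(k2 + math.cos(b)),
                          lam_um / max(abs(k2 - math.cos(b)), 1e-12)]
            period = local_period(dlil_geometry, float(x))
            assert min(abs(period - c) / period for c in candidates) < 0.02


class TestFringeDutyCycle:
    @pytest.mark.parametrize("threshold,expected", [
        (1.0, 0.5),          # threshold at mean: symmetric sinusoid
        (2.0, 0.0),          # threshold at peak
        (0.5, 2.0 / 3.0),    # arccos(-1/2)/pi
    ])
    def test_closed_form_cases(self, threshold, expected):
        assert fringe_duty_cycle(1.0, 1.0, threshold) == pytest.approx(
            expected, abs=1e-12)

    def test_positive_tone_is_complement(self):
        d_neg = fringe_duty_cycle(1.0, 1.0, 0.5, "negative")
        d_pos = fringe_duty_cycle(1.0, 1.0, 0.5, "positive")
        assert d_neg + d_pos == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("mean,vis,thr", [
        (1.0, 1.0, 1.3), (1.0, 0.5, 0.8), (2.0, 1.5, 1.2), (1.0, 1.0, 0.1),
        (0.5, 0.2, 0.55),
    ])
    def test_agrees_with_quadrature(self, mean, vis, thr):
        d = fringe_duty_cycle(mean, vis, thr)
        crossing = math.acos(np.clip((thr - mean) / vis, -1, 1)) / (2 * math.pi)
        frac, _ = quad(lambda u: 1.0 if mean + vis * math.cos(
            2 * math.pi * u) > thr else 0.0, 0.0, 1.0,
            points=[crossing, 1.0 - crossing], limit=200)
        assert d == pytest.approx(frac, abs=1e-9)

    def test_zero_visibility_warns(self):
        with pytest.warns(UserWarning):
            assert fringe_duty_cycle(1.0, 0.0, 0.5) == 1.0
        with pytest.warns(UserWarning):
            assert fringe_duty_cycle(1.0, 0.0, 1.5) == 0.0


class TestBuildTopographyProfile:
    def test_lloyds_mode_constant_period(self):
        geom = InterferometerGeometry(focal_length_mm=1e7)
        prof = build_topography_profile(geom, 50)
        assert prof.span_ratio == pytest.approx(1.0, abs=1e-4)
        lam_um = geom.wavelength_nm * 1e-3
        expected = lam_um / (2 * math.cos(math.radians(geom.beam_angle_deg)))
        assert prof.period_um[0] == pytest.approx(expected, rel=1e-4)

    def test_gradient_span_at_screening_geometry(self, dlil_profile):
        assert dlil_profile.span_ratio >= 50.0

    def test_two_sample_profile_satisfies_invariants(self, dlil_geometry):
        prof = build_topography_profile(dlil_geometry, 2)
        assert len(prof.positions_um) == 2
        assert np.all(prof.period_um > 0)
        assert np.allclose(prof.linewidth_um,
                           prof.duty_cycle * prof.period_um)

    def test_span_strictly_narrows_with_beam_angle(self):
        spans = []
        for beta in (62.0, 67.0, 72.0):
            geom = InterferometerGeometry(beam_angle_deg=beta)
            spans.append(build_topography_profile(geom, 120).span_ratio)
        assert spans[0] > spans[1] > spans[2]

    def test_exposure_params_set_duty_cycle(self, dlil_geometry):
        prof = build_topography_profile(
            dlil_geometry, 20,
            exposure_params=ExposureParams(threshold=0.5))
        assert np.allclose(prof.duty_cycle, 2.0 / 3.0)

    def test_bad_n_samples(self, dlil_geometry):
        with pytest.raises(ValueError):
            build_topography_profile(dlil_geometry, 1)


class TestSizeCalibration:
    def test_exact_recovery_on_exponential_profile(self, exp_profile):
        cal = fit_size_calibration(exp_profile)
        k = math.log(20.0 / 0.2) / 10000.0
        assert cal.slope == pytest.approx(k, rel=1e-12)
        assert cal.intercept == pytest.approx(math.log(0.2), abs=1e-12)
        assert cal.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_profile_zero_slope_convention(self):
        prof = exponential_profile(1.0, 1.0, n_samples=20)
        cal = fit_size_calibration(prof)
        assert cal.slope == pytest.approx(0.0, abs=1e-12)
        assert cal.r_squared == 0.0

    def test_dlil_profile_log_linear_central_80pct(self, dlil_profile):
        cal = fit_size_calibration(dlil_profile, central_fraction=0.8)
        assert cal.r_squared >= 0.95

    def test_prediction_matches_profile_within_residual(self, exp_profile,
                                                        exp_calibration):
        pred = position_to_feature_size(exp_calibration,
                                        exp_profile.positions_um)
        assert np.allclose(pred, exp_profile.period_um, rtol=1e-9)

    def test_inverse_round_trip(self, exp_calibration):
        x = np.array([123.0, 4567.0, 9000.0])
        size = position_to_feature_size(exp_calibration, x)
        back = feature_size_to_position(exp_calibration, size)
        assert np.allclose(back, x, rtol=1e-9)

    def test_extrapolation_warns(self, exp_calibration):
        with pytest.warns(UserWarning):
            position_to_feature_size(exp_calibration, 1e6)

    def test_nonpositive_period_named_in_error(self):
        prof = exponential_profile(0.5, 5.0, n_samples=10)
        prof.period_um[3] = np.nan
        with pytest.raises(ValueError, match="index 3"):
            fit_size_calibration(prof)


class TestGeometryValidation:
    @pytest.mark.parametrize("kwargs", [
        {"wavelength_nm": -1}, {"beam_angle_deg": 0}, {"beam_angle_deg": 95},
        {"focal_length_mm": 0}, {"mirror_curvature_sign": "spherical"},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            InterferometerGeometry(**kwargs)

    def test_profile_rejects_inconsistent_linewidth(self):
        with pytest.raises(ValueError):
            TopographyProfile(np.array([0.0, 1.0]), np.array([1.0, 1.0]),
                              np.array([0.9, 0.9]), np.array([0.5, 0.5]))

    def test_profile_csv_round_trip(self, exp_profile, tmp_path):
        path = tmp_path / "profile.csv"
        exp_profile.to_csv(path)
        back = TopographyProfile.from_csv(path)
        assert np.allclose(back.period_um, exp_profile.period_um)
        assert np.allclose(back.positions_um, exp_profile.positions_um)
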