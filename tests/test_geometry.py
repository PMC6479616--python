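"""Tangential mirror-geometry model: maps, distortion bounds, fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirrorscan import (
    ScannerGeometry, angle_to_object_y, detect_grid_rows, fit_geometry,
    linear_range, linearized_object_y, object_to_pixel, path_elongation,
    pixel_to_object, rectify, residual_noise_sigma, row_to_angle, step_angle,
    width_scale,
)
from mirrorscan.geometry import FitError, GeometryError

from conftest import amsler_edge_rows, scan_amsler, small_geometry


# ---------------------------------------------------------------------------
# closed-form maps
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "s, n, expected",
    [
        (1, 19200, 2 * math.pi / 19200),       # reference drive resolution
        (19200, 19200, 2 * math.pi),           # full revolution
        (4, 19200, 1.3089969389957472e-3),     # 8*pi/19200
    ],
)
def test_step_angle(s, n, expected):
    assert step_angle(s, n) == pytest.approx(expected, rel=1e-12)


def test_step_angle_rejects_bad_inputs():
    with pytest.raises(GeometryError):
        step_angle(0, 19200)
    with pytest.raises(GeometryError):
        step_angle(1, 0)
    with pytest.raises(GeometryError):
        step_angle(1, 100.5)


def test_row_to_angle_offsets(geometry_225):
    g = geometry_225
    assert row_to_angle(g.y_pi4, g) == pytest.approx(math.pi / 4, abs=1e-15)
    # 384 native steps above the normal row
    g1 = ScannerGeometry(r_mm=225.0, microstep_factor=1.0, y_pi4=0.0,
                         n_rows=1200, n_cols=1200)
    assert row_to_angle(384.0, g1) == pytest.approx(math.pi / 4 + 0.12566370614359174, rel=1e-12)
    assert row_to_angle(-1.0, g1) == pytest.approx(math.pi / 4 - 3.272492347489368e-4, rel=1e-12)


@pytest.mark.parametrize(
    "theta, r, expected",
    [
        (math.pi / 4, 225.0, 0.0),
        (math.pi / 4 + math.pi / 16, 225.0, -93.19805153394637),  # 225*tan(-pi/8)
        (math.pi / 4 - math.pi / 16, 225.0, +93.19805153394637),  # antisymmetry
    ],
)
def test_angle_to_object_y(theta, r, expected):
    assert angle_to_object_y(theta, r) == pytest.approx(expected, abs=1e-9)


def test_angle_to_object_y_domain():
    for bad in (0.0, math.pi / 2, -0.1, 2.0):
        with pytest.raises(GeometryError):
            angle_to_object_y(bad, 225.0)


def test_path_elongation_values():
    assert path_elongation(math.pi / 4, 123.0) == pytest.approx(0.0, abs=1e-12)
    # 100*(1/sin(3*pi/8) - 1)
    assert path_elongation(3 * math.pi / 16, 100.0) == pytest.approx(8.239220029239402, rel=1e-12)


def test_relative_elongation_rounds_to_8pct_at_gamma_pi8():
    """Max dr/r over gamma in [-pi/8, +pi/8] rounds to the 8% design bound."""
    gammas = np.linspace(-math.pi / 8, math.pi / 8, 2001)
    thetas = (math.pi / 2 - gammas) / 2
    rel = np.array([path_elongation(t, 1.0) for t in thetas])
    assert round(rel.max() * 100) == 8
    assert rel.max() == pytest.approx(1 / math.cos(math.pi / 8) - 1, rel=1e-9)


def test_width_scale_values_and_symmetry():
    assert width_scale(math.pi / 4) == pytest.approx(1.0, rel=1e-15)
    assert width_scale(3 * math.pi / 16) == pytest.approx(1.082392200292394, rel=1e-12)
    assert width_scale(5 * math.pi / 16) == pytest.approx(width_scale(3 * math.pi / 16), rel=1e-12)


def test_linearized_object_y():
    assert linearized_object_y(math.pi / 4, 225.0) == 0.0
    assert linearized_object_y(math.pi / 4 + math.pi / 16, 225.0) == pytest.approx(
        -225.0 * math.pi / 8, rel=1e-12
    )
    # relative deviation from the exact tangent map at gamma = pi/8
    gamma = math.pi / 8
    theta = (math.pi / 2 - gamma) / 2
    exact = angle_to_object_y(theta, 225.0)
    approx = linearized_object_y(theta, 225.0)
    rel_dev = abs(exact - approx) / abs(exact)
    assert rel_dev == pytest.approx((math.tan(gamma) - gamma) / math.tan(gamma), rel=1e-9)
    assert rel_dev == pytest.approx(0.0517, abs=5e-4)


def test_pixel_to_object_composition(geometry_225):
    g = ScannerGeometry(r_mm=225.0, microstep_factor=1.0, y_pi4=600.0,
                        delta_x_mm=0.1, n_rows=1200, n_cols=1200)
    assert pixel_to_object(0.0, g.y_pi4, g) == (0.0, 0.0)
    x_d, y_d = pixel_to_object(100.0, g.y_pi4, g)
    assert (x_d, y_d) == (pytest.approx(10.0, rel=1e-12), pytest.approx(0.0, abs=1e-9))
    x_d, y_d = pixel_to_object(100.0, g.y_pi4 + 384, g)
    theta = math.pi / 4 + 384 * g.delta_theta
    assert x_d == pytest.approx(10.0 * width_scale(theta), rel=1e-12)
    assert y_d == pytest.approx(225.0 * math.tan(math.pi / 2 - 2 * theta), rel=1e-12)


def test_linear_range_inversion():
    assert linear_range(0.0).gamma_half_width == 0.0
    lr = linear_range(1 / math.sin(3 * math.pi / 8) - 1)
    assert lr.gamma_half_width == pytest.approx(math.pi / 8, abs=1e-10)
    # the rounded 8% tolerance also lands on (approximately) pi/8
    assert linear_range(0.0824).gamma_half_width == pytest.approx(math.pi / 8, rel=2e-3)
    with pytest.raises(GeometryError):
        linear_range(math.sqrt(2) - 1)
    with pytest.raises(GeometryError):
        linear_range(-0.01)


# ---------------------------------------------------------------------------
# invariants (property tests)
# ---------------------------------------------------------------------------

@settings(max_examples=200, derandomize=True)
@given(st.floats(min_value=0.05, max_value=math.pi / 2 - 0.05),
       st.floats(min_value=1.0, max_value=1000.0))
def test_elongation_width_scale_identity(theta, r):
    """r*(h(theta) - 1) equals the path elongation to machine precision."""
    assert r * (width_scale(theta) - 1.0) == pytest.approx(
        path_elongation(theta, r), rel=1e-12, abs=1e-12
    )


@settings(max_examples=100, derandomize=True)
@given(st.floats(min_value=-0.6, max_value=0.6))
def test_object_y_antisymmetric_about_normal(delta):
    y1 = angle_to_object_y(math.pi / 4 + delta, 300.0)
    y2 = angle_to_object_y(math.pi / 4 - delta, 300.0)
    assert y1 == pytest.approx(-y2, rel=1e-10, abs=1e-10)


@settings(max_examples=100, derandomize=True)
@given(st.floats(min_value=-30.0, max_value=30.0),
       st.floats(min_value=20.0, max_value=460.0))
def test_pixel_object_round_trip(x, row):
    """Object->pixel inverts pixel->object to sub-nanopixel accuracy."""
    g = small_geometry(225.0)
    x_d, y_d = pixel_to_object(x, row, g)
    x_back, row_back = object_to_pixel(x_d, y_d, g)
    assert x_back == pytest.approx(x, abs=1e-9)
    assert row_back == pytest.approx(row, abs=1e-9)


@settings(max_examples=50, derandomize=True)
@given(st.floats(min_value=1e-4, max_value=0.40))
def test_linear_range_elongation_mutual_inverse(tol):
    lr = linear_range(tol)
    theta_edge = lr.theta_interval[0]
    assert path_elongation(theta_edge, 1.0) == pytest.approx(tol, abs=1e-10)
    lr2 = linear_range(lr.max_rel_elongation)
    assert lr2.gamma_half_width == pytest.approx(lr.gamma_half_width, abs=1e-10)


# ---------------------------------------------------------------------------
# rectification
# ---------------------------------------------------------------------------

def test_rectify_restores_uniform_grid_spacing():
    """A noiseless Amsler scan rectifies to uniformly spaced grid lines."""
    cube, g = scan_amsler(348.73)
    rect, mask = rectify(cube.data[:, :, 0], g, target_pitch=0.25)
    assert mask.any()
    # grid-line centers along a clear column of the rectified image
    col = rect.shape[1] // 2 + 12
    prof = rect[:, col]
    prof = np.where(np.isfinite(prof), prof, np.nanmax(prof))
    centers = detect_grid_rows(prof)
    # innermost widths only: the outermost runs border the masked region
    widths = np.diff(centers)[1:-1] * 0.25  # mm
    cv = widths.std() / widths.mean()
    assert len(centers) >= 10
    assert widths.mean() == pytest.approx(6.0, rel=0.01)
    assert cv < 0.005


def test_rectify_identity_on_normal_row(geometry_225):
    g = geometry_225
    img = np.zeros((g.n_rows, g.n_cols))
    img[int(g.y_pi4), :] = 100.0
    rect, mask = rectify(img, g, target_pitch=g.delta_x_mm)
    # the bright feature survives, and the origin maps back to the normal row
    assert np.nansum(np.where(mask, rect, 0.0)) > 0
    _, row = object_to_pixel(0.0, 0.0, g)
    assert abs(row - g.y_pi4) < 1e-9


def test_rectify_masks_do_not_extrapolate(geometry_225):
    g = geometry_225
    img = np.ones((g.n_rows, g.n_cols))
    rect, mask = rectify(img, g, target_pitch=0.5)
    assert not np.isfinite(rect[~mask]).any()
    assert np.isfinite(rect[mask]).all()


def test_rectify_rejects_empty(geometry_225):
    with pytest.raises(GeometryError):
        rectify(np.empty((0, 0)), geometry_225, 0.1)


# ---------------------------------------------------------------------------
# geometry estimation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("r_true", [100.0, 225.0, 348.73])
def test_fit_geometry_recovers_r_noiseless(r_true):
    """Distance recovery to 0.1% from a noiseless simulated grid scan."""
    cube, g = scan_amsler(r_true)
    edges = amsler_edge_rows(cube, g)
    g0 = small_geometry(r_true * 1.3)
    fit = fit_geometry(edges, 6.0, g0)
    assert abs(fit.r_mm - r_true) / r_true < 1e-3


def test_fit_geometry_exact_on_analytic_edges():
    g = small_geometry(348.73)
    ks = np.arange(-20, 21)
    gam = np.arctan(ks * 6.0 / g.r_mm)
    theta = (math.pi / 2 - gam) / 2
    rows = (theta - math.pi / 4) / g.delta_theta + g.y_pi4
    fit = fit_geometry(rows, 6.0, small_geometry(250.0))
    assert fit.r_mm == pytest.approx(348.73, rel=1e-9)
    assert fit.rms_mm < 1e-9


def test_fit_geometry_residual_sigma_recovery(rng):
    """Gaussian edge jitter propagates into the residual series' sigma."""
    g = small_geometry(348.73)
    sigma_mm = 0.2
    ks = np.arange(-24, 25)
    positions = ks * 6.0 + rng.normal(0.0, sigma_mm, ks.size)
    gam = np.arctan(positions / g.r_mm)
    rows = ((math.pi / 2 - gam) / 2 - math.pi / 4) / g.delta_theta + g.y_pi4
    # stack several scans to reach n >= 200 residuals
    res_all = []
    for k in range(5):
        pos_k = ks * 6.0 + rng.normal(0.0, sigma_mm, ks.size)
        gam_k = np.arctan(pos_k / g.r_mm)
        rows_k = ((math.pi / 2 - gam_k) / 2 - math.pi / 4) / g.delta_theta + g.y_pi4
        fit = fit_geometry(rows_k, 6.0, g)
        res_all.append(fit.residuals_mm)
    res = np.concatenate(res_all)
    assert res.size >= 200
    assert np.std(res) == pytest.approx(sigma_mm, rel=0.15)


def test_fit_geometry_needs_three_edges():
    with pytest.raises(FitError):
        fit_geometry(np.array([100.0, 200.0]), 6.0, small_geometry(225.0))


# ---------------------------------------------------------------------------
# residual noise separation
# ---------------------------------------------------------------------------

def test_residual_noise_sigma_zero_series():
    sigma, trend = residual_noise_sigma(np.zeros(128))
    assert sigma == 0.0


def test_residual_noise_sigma_pure_gaussian():
    rng = np.random.default_rng(42)
    sigma, _ = residual_noise_sigma(rng.normal(0.0, 0.2, 1000))
    assert 0.18 <= sigma <= 0.22


def test_residual_noise_sigma_removes_cosine_trend():
    rng = np.random.default_rng(7)
    t = np.arange(1000)
    signal = 0.6 * np.cos(2 * math.pi * t / 1000 * 3) + rng.normal(0.0, 0.2, 1000)
    sigma, trend = residual_noise_sigma(signal)
    assert 0.17 <= sigma <= 0.23
    # the removed component carries most of the cosine's amplitude
    assert trend.max() > 0.4


def test_residual_noise_sigma_too_short():
    with pytest.raises(FitError):
        residual_noise_sigma(np.zeros(16))
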