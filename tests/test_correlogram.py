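"""Correlogram geometry: masked-Pearson oracle equality, field detection,
canonical axes, scale, and the ellipse fit."""

import math

import numpy as np
import pytest

from gridframe.correlogram import (
    CorrelationField,
    Correlogram,
    DegenerateGeometryError,
    analyze_geometry,
    autocorrelogram,
    canonical_axes,
    central_field,
    crosscorrelogram,
    detect_fields,
    fit_ellipse_index,
    grid_scale,
    surrounding_fields,
)
from gridframe.ratemap import rotate_rate_map

from conftest import make_ideal_map, map_from_array


def brute_force_crosscorrelogram(A, B, min_overlap):
    """Nested-loop masked Pearson correlations at every displacement."""
    ny, nx = A.shape
    out = np.full((2 * ny - 1, 2 * nx - 1), np.nan)
    for dy in range(-(ny - 1), ny):
        for dx in range(-(nx - 1), nx):
            pa, pb = [], []
            for i in range(ny):
                for j in range(nx):
                    ii, jj = i + dy, j + dx
                    if 0 <= ii < ny and 0 <= jj < nx:
                        a, b = A[i, j], B[ii, jj]
                        if np.isfinite(a) and np.isfinite(b):
                            pa.append(a)
                            pb.append(b)
            if len(pa) >= min_overlap:
                pa = np.asarray(pa)
                pb = np.asarray(pb)
                va = pa - pa.mean()
                vb = pb - pb.mean()
                den = math.sqrt((va @ va) * (vb @ vb))
                if den > 0:
                    out[dy + ny - 1, dx + nx - 1] = (va @ vb) / den
    return out


def test_crosscorrelogram_matches_brute_force_oracle():
    rng = np.random.default_rng(21)
    A = rng.uniform(0, 10, (15, 15))
    B = rng.uniform(0, 10, (15, 15))
    A[rng.random(A.shape) < 0.2] = np.nan
    B[rng.random(B.shape) < 0.2] = np.nan
    got = crosscorrelogram(map_from_array(A), map_from_array(B),
                           min_overlap=5).r
    want = brute_force_crosscorrelogram(A, B, min_overlap=5)
    np.testing.assert_allclose(got, want, atol=1e-10, equal_nan=True)


def test_center_bin_is_unity_and_overlap_rule():
    rng = np.random.default_rng(22)
    A = rng.uniform(0, 5, (15, 15))
    rm = map_from_array(A)
    corr = crosscorrelogram(rm, rm, min_overlap=100)
    assert corr.r[corr.center_index] == pytest.approx(1.0)
    # displacement (9, 0): overlap 6*15 = 90 < 100 -> invalid
    cy, cx = corr.center_index
    assert not corr.valid[cy, cx + 9]
    # displacement (7, 0): overlap 8*15 = 120 >= 100 -> valid
    assert corr.valid[cy, cx + 7]
    with pytest.raises(ValueError):
        crosscorrelogram(rm, map_from_array(A, bin_size=2.0))


def test_autocorrelogram_point_symmetry():
    rng = np.random.default_rng(23)
    A = rng.uniform(0, 5, (12, 14))
    A[rng.random(A.shape) < 0.15] = np.nan
    corr = autocorrelogram(map_from_array(A), min_overlap=10)
    np.testing.assert_allclose(corr.r, corr.r[::-1, ::-1], atol=1e-10,
                               equal_nan=True)


def test_displacement_sign_convention():
    """A field at displacement v means shifting map A by +v matches B."""
    yy, xx = np.mgrid[0:21, 0:21]
    A = np.exp(-((xx - 9.0) ** 2 + (yy - 9.0) ** 2) / 8.0)
    B = np.exp(-((xx - 13.0) ** 2 + (yy - 11.0) ** 2) / 8.0)  # +(4, 2) bins
    corr = crosscorrelogram(map_from_array(A), map_from_array(B),
                            min_overlap=150)
    iy, ix = np.unravel_index(np.nanargmax(corr.r), corr.r.shape)
    cy, cx = corr.center_index
    assert (iy - cy, ix - cx) == (2, 4)


# ---------------------------------------------------------------------------
# field detection
# ---------------------------------------------------------------------------

def _correlogram_from_r(r, bin_size=3.0):
    return Correlogram(r, np.isfinite(r), bin_size=bin_size)


def test_subthreshold_correlogram_has_no_fields():
    r = np.full((31, 31), 0.05)
    assert detect_fields(_correlogram_from_r(r)) == []


def test_minimum_field_size_is_enforced():
    r = np.full((41, 41), -0.2)
    r[2:21, 2] = 0.5  # 19 contiguous bins: excluded
    r[30:35, 30:34] = 0.5  # 20 contiguous bins: kept
    fields = detect_fields(_correlogram_from_r(r))
    assert len(fields) == 1
    assert fields[0].area == 20


def test_ideal_grid_autocorrelogram_fields(ideal_map_60):
    corr = autocorrelogram(ideal_map_60)
    fields = detect_fields(corr)
    assert len(fields) >= 7  # central + inner hexagon at minimum
    c = central_field(fields)
    assert c.distance < 1.0


# ---------------------------------------------------------------------------
# axes, scale, ellipse
# ---------------------------------------------------------------------------

def test_canonical_axes_of_axis_aligned_grid(ideal_map_60):
    geom = analyze_geometry(autocorrelogram(ideal_map_60))
    assert geom.ax0 == pytest.approx(0.0, abs=2.0)
    assert geom.ax1 == pytest.approx(60.0, abs=2.0)
    assert geom.ax2 == pytest.approx(-60.0, abs=2.0)
    assert geom.orientation == pytest.approx(0.0, abs=1.5)
    assert geom.scale == pytest.approx(60.0, rel=0.05)


def test_orientation_recovered_within_bin_resolution(ideal_map_60_o7):
    geom = analyze_geometry(autocorrelogram(ideal_map_60_o7))
    assert geom.orientation == pytest.approx(7.0, abs=1.5)


def test_thirty_degree_grid_sits_on_the_wrap_point():
    rm = make_ideal_map(scale=60.0, orientation=30.0)
    geom = analyze_geometry(autocorrelogram(rm))
    # -30 and +30 identify the same orientation
    assert min(abs(geom.orientation - 30.0), abs(geom.orientation + 30.0)) < 1.5
    again = analyze_geometry(autocorrelogram(rm))
    assert geom.ax0 == again.ax0  # deterministic tie-break


def test_axes_require_three_fields():
    with pytest.raises(DegenerateGeometryError):
        canonical_axes([CorrelationField((0.0, 0.0), 30, 1.0),
                        CorrelationField((10.0, 0.0), 25, 0.5)])


def test_scale_scales_homogeneously():
    g45 = analyze_geometry(autocorrelogram(make_ideal_map(scale=45.0)))
    g90 = analyze_geometry(autocorrelogram(make_ideal_map(scale=90.0)))
    assert g90.scale / g45.scale == pytest.approx(2.0, rel=0.06)


def test_scale_invariant_under_map_rotation(ideal_map_60):
    base = analyze_geometry(autocorrelogram(ideal_map_60))
    rot = rotate_rate_map(ideal_map_60, 13.0)
    geom = analyze_geometry(autocorrelogram(rot))
    assert geom.scale == pytest.approx(base.scale, rel=0.03)
    # orientation is equivariant: rotating the map CW subtracts 13 deg
    assert geom.orientation == pytest.approx(base.orientation - 13.0, abs=1.5)


def _ring_fields(radii_angles):
    fields = [CorrelationField((0.0, 0.0), 40, 1.0)]
    for r, a in radii_angles:
        fields.append(
            CorrelationField((r * math.cos(math.radians(a)),
                              r * math.sin(math.radians(a))), 30, 0.6)
        )
    return fields


def test_ellipse_index_circle_and_two_to_one():
    circle = _ring_fields([(60.0, a) for a in range(0, 360, 60)])
    A, B, idx, ang = fit_ellipse_index(circle)
    assert idx == pytest.approx(0.0, abs=1e-6)
    # points on an ellipse with A = 2B
    pts = []
    for a in range(0, 360, 60):
        th = math.radians(a)
        pts.append((80.0 * math.cos(th), 40.0 * math.sin(th)))
    fields = [CorrelationField((0.0, 0.0), 40, 1.0)] + [
        CorrelationField(p, 30, 0.6) for p in pts
    ]
    A, B, idx, ang = fit_ellipse_index(fields)
    assert idx == pytest.approx(0.5, abs=1e-6)
    assert ang == pytest.approx(0.0, abs=1e-3)
    with pytest.raises(DegenerateGeometryError):
        fit_ellipse_index(_ring_fields([(60.0, a) for a in (0, 60, 120)]))


def test_sheared_grid_matches_analytic_ellipse():
    rm = make_ideal_map(scale=60.0, elliptical_index_target=0.2)
    geom = analyze_geometry(autocorrelogram(rm))
    assert geom.elliptical_index == pytest.approx(0.2, abs=0.02)


def test_grid_scale_helper(ideal_map_60):
    fields = detect_fields(autocorrelogram(ideal_map_60))
    assert grid_scale(fields) == pytest.approx(60.0, rel=0.05)
    ring = surrounding_fields(fields, n=6)
    assert len(ring) == 6
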