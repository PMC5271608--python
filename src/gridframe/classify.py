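"""Gridness scoring and the seven-criterion bootstrap grid-cell classifier.

A rate map is accepted as a grid cell only if all of the following hold:

1. gridness score >= 0.1;
2. all six correlation fields defining the annulus are identified;
3. the angles subtended by adjacent canonical semi-axes are > 30 and < 90 deg;
4. the elliptical index of the autocorrelogram is < 0.5;
5. no field's distance from the fitted ellipse exceeds 20% of its distance
   from the autocorrelogram center;
6. the grid scale is < 125 cm;
7. the gridness score is >= 0.1 for at least 95 of 100 bootstrapped maps.

The gridness score is computed on the elliptically corrected map: if the
elliptical index exceeds 0.05 the rate map is stretched along the short-axis
direction to undo the distortion, and the autocorrelogram, fields and
centers of mass are recomputed.  The annulus containing the six inner
fields (radii D +/- 1.2 cR, where D is their mean distance from the center
and cR the equivalent radius of the central field) is correlated with
rotated copies of itself; the score is min(r60, r120) - max(r30, r90, r150).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .correlogram import (
    Correlogram,
    DegenerateGeometryError,
    GridGeometry,
    analyze_geometry,
    autocorrelogram,
    central_field,
    detect_fields,
    surrounding_fields,
)
from .ratemap import RateMap, resample_map

__all__ = [
    "CRITERIA_NAMES",
    "GridClassification",
    "elliptical_correction",
    "gridness_score",
    "classify_grid",
]

CRITERIA_NAMES = (
    "gridness",
    "six_fields",
    "axis_angles",
    "elliptical_index",
    "ellipse_distance",
    "scale",
    "bootstrap",
)


@dataclass
class GridClassification:
    """Outcome of the seven-criterion classifier for one rate map."""

    gridness: float | None
    criteria: dict = field(default_factory=dict)
    geometry: GridGeometry | None = None
    bootstrap_pass_count: int | None = None

    @property
    def passed(self) -> bool:
        return all(self.criteria.get(name) is True for name in CRITERIA_NAMES)

    def failures(self) -> list[str]:
        return [n for n in CRITERIA_NAMES if self.criteria.get(n) is not True]


def _stretch_matrix(factor: float, short_axis_deg: float) -> np.ndarray:
    """Matrix stretching the plane by ``factor`` along ``short_axis_deg``."""
    th = math.radians(short_axis_deg)
    c, s = math.cos(th), math.sin(th)
    R = np.array([[c, -s], [s, c]])  # maps x-axis onto the short axis
    return R @ np.diag([factor, 1.0]) @ R.T


def elliptical_correction(
    rmap: RateMap,
    geometry: GridGeometry | None = None,
    index_thresh: float = 0.05,
    min_overlap: int = 100,
    r_thresh: float = 0.1,
    min_bins: int = 20,
    max_iter: int = 3,
    max_stretch: float = 3.0,
) -> tuple[RateMap, GridGeometry]:
    """Stretch a rate map along its short ellipse axis to undo distortion.

    If the elliptical index is <= ``index_thresh`` the map is returned
    unchanged.  Otherwise the map is resampled with an affine stretch of
    the coordinates by A/B along the short-axis direction (iterating if a
    residual distortion remains), and the autocorrelogram geometry is
    recomputed from the corrected map.  A (cumulative) stretch beyond
    ``max_stretch`` — far outside any correctable grid distortion — raises
    :class:`DegenerateGeometryError`.
    """
    if geometry is None:
        geometry = analyze_geometry(autocorrelogram(rmap, min_overlap),
                                    r_thresh=r_thresh, min_bins=min_bins)
    out, geom = rmap, geometry
    total = 1.0
    for _ in range(max_iter):
        idx = geom.elliptical_index
        if not np.isfinite(idx) or idx <= index_thresh:
            break
        A, B = geom.ellipse_axes
        factor = A / B
        total *= factor if math.isfinite(factor) else math.inf
        if not math.isfinite(factor) or total > max_stretch:
            # far beyond any correctable grid distortion (the classifier
            # rejects indices >= 0.5, i.e. A/B >= 2): the field pattern is
            # not an interpretable lattice
            raise DegenerateGeometryError(
                f"elliptical stretch factor {factor:.2f} too extreme"
            )
        short_axis = geom.ellipse_angle + 90.0
        M = _stretch_matrix(factor, short_axis)
        x0, x1 = out.x_edges[0], out.x_edges[-1]
        y0, y1 = out.y_edges[0], out.y_edges[-1]
        grow = factor
        ext = tuple(
            math.copysign(
                math.ceil(abs(v) * grow / out.bin_size) * out.bin_size, v
            )
            for v in (x0, x1, y0, y1)
        )
        out = resample_map(out, M, out_extent=ext)
        geom = analyze_geometry(autocorrelogram(out, min_overlap),
                                r_thresh=r_thresh, min_bins=min_bins)
    return out, geom


def _rotate_masked(values: np.ndarray, valid: np.ndarray, deg: float):
    """Rotate an array (+mask) about its center pixel, bilinear."""
    ny, nx = values.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    th = math.radians(deg)
    c, s = math.cos(th), math.sin(th)
    yy, xx = np.mgrid[0:ny, 0:nx]
    u = xx - cx
    v = yy - cy
    src_x = c * u - s * v + cx
    src_y = s * u + c * v + cy
    coords = np.stack([src_y, src_x])
    filled = np.where(valid, values, 0.0)
    vals = map_coordinates(filled, coords, order=1, mode="constant", cval=0.0)
    mask = map_coordinates(valid.astype(float), coords, order=1,
                           mode="constant", cval=0.0)
    return vals, mask > 1.0 - 1e-6


def _annulus_rotation_correlations(
    corr: Correlogram,
    inner: float,
    outer: float,
    offsets_deg,
) -> dict:
    """Pearson r between the annulus and its rotated copies."""
    dy = corr.dy_cm[:, None]
    dx = corr.dx_cm[None, :]
    rho = np.hypot(dx, dy)
    annulus = (rho >= inner) & (rho <= outer)
    base_valid = corr.valid & annulus
    out = {}
    for deg in offsets_deg:
        vals, rot_valid = _rotate_masked(corr.r, corr.valid, deg)
        m = base_valid & rot_valid & annulus
        a = corr.r[m]
        b = vals[m]
        if a.size < 3:
            out[deg] = float("nan")
            continue
        a = a - a.mean()
        b = b - b.mean()
        denom = math.sqrt((a @ a) * (b @ b))
        out[deg] = float((a @ b) / denom) if denom > 0 else float("nan")
    return out


def gridness_score(
    rmap: RateMap,
    min_overlap: int = 100,
    r_thresh: float = 0.1,
    min_bins: int = 20,
    ellipse_thresh: float = 0.05,
    annulus_width_factor: float = 1.2,
    peak_offsets=(60.0, 120.0),
    trough_offsets=(30.0, 90.0, 150.0),
    return_geometry: bool = False,
):
    """Six-fold rotational-symmetry score of a rate map's autocorrelogram.

    Raises :class:`DegenerateGeometryError` when the annulus cannot be
    constructed (fewer than six surrounding correlation fields).
    """
    corrected, geom = elliptical_correction(
        rmap, index_thresh=ellipse_thresh, min_overlap=min_overlap,
        r_thresh=r_thresh, min_bins=min_bins,
    )
    acorr = autocorrelogram(corrected, min_overlap)
    fields = detect_fields(acorr, r_thresh=r_thresh, min_bins=min_bins)
    ring = surrounding_fields(fields, n=6)
    if len(ring) < 6:
        raise DegenerateGeometryError(
            f"annulus needs 6 surrounding fields, found {len(ring)}"
        )
    D = float(np.mean([f.distance for f in ring]))
    cf = central_field(fields)
    cR = math.sqrt(cf.area * acorr.bin_size**2 / math.pi)
    inner = max(0.0, D - annulus_width_factor * cR)
    outer = D + annulus_width_factor * cR
    offs = sorted(set(peak_offsets) | set(trough_offsets))
    rot = _annulus_rotation_correlations(acorr, inner, outer, offs)
    score = min(rot[o] for o in peak_offsets) - max(rot[o] for o in trough_offsets)
    if return_geometry:
        return float(score), geom
    return float(score)


def _ellipse_radial_distance(pt, A, B, angle_deg) -> float:
    """Radial distance from a point to an origin-centered ellipse."""
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)
    x = c * pt[0] + s * pt[1]
    y = -s * pt[0] + c * pt[1]
    r_pt = math.hypot(x, y)
    phi = math.atan2(y, x)
    r_e = (A * B) / math.sqrt((B * math.cos(phi)) ** 2 + (A * math.sin(phi)) ** 2)
    return abs(r_pt - r_e)


def classify_grid(
    rmap: RateMap,
    bootstraps=None,
    gridness_thresh: float = 0.1,
    min_overlap: int = 100,
    r_thresh: float = 0.1,
    min_bins: int = 20,
    ellipse_thresh: float = 0.05,
    max_ellipse_index: float = 0.5,
    max_ellipse_distance_frac: float = 0.2,
    max_scale: float = 125.0,
    min_bootstrap_pass: int = 95,
) -> GridClassification:
    """Evaluate the seven grid-cell criteria for one rate map.

    ``bootstraps`` are the rate maps from resampled spike trains (see
    :func:`gridframe.ratemap.bootstrap_rate_maps`), or a zero-argument
    callable producing them (invoked only if the other six criteria hold);
    when omitted, the bootstrap criterion is left unevaluated.  Criteria
    that cannot be evaluated because an earlier stage failed are reported
    as None.
    """
    crit: dict = {name: None for name in CRITERIA_NAMES}
    geom = None
    gridness = None
    try:
        acorr = autocorrelogram(rmap, min_overlap)
        geom = analyze_geometry(acorr, r_thresh=r_thresh, min_bins=min_bins)
    except DegenerateGeometryError:
        crit["six_fields"] = False
        return GridClassification(None, crit, None)

    sep1, sep2 = geom.axis_separations
    crit["axis_angles"] = bool(30.0 < sep1 < 90.0 and 30.0 < sep2 < 90.0)
    if np.isfinite(geom.elliptical_index):
        crit["elliptical_index"] = bool(geom.elliptical_index < max_ellipse_index)
    crit["scale"] = bool(geom.scale < max_scale)

    if np.isfinite(geom.elliptical_index):
        try:
            acorr_fields = detect_fields(acorr, r_thresh=r_thresh,
                                         min_bins=min_bins)
            ring = surrounding_fields(acorr_fields, n=6)
            A, B = geom.ellipse_axes
            ok = all(
                _ellipse_radial_distance(f.com, A, B, geom.ellipse_angle)
                <= max_ellipse_distance_frac * f.distance
                for f in ring
            )
            crit["ellipse_distance"] = bool(ok)
        except DegenerateGeometryError:
            crit["ellipse_distance"] = False

    try:
        gridness, _ = gridness_score(
            rmap, min_overlap=min_overlap, r_thresh=r_thresh,
            min_bins=min_bins, ellipse_thresh=ellipse_thresh,
            return_geometry=True,
        )
        crit["six_fields"] = True
        crit["gridness"] = bool(gridness >= gridness_thresh)
    except DegenerateGeometryError:
        crit["six_fields"] = False
        return GridClassification(None, crit, geom)

    result = GridClassification(gridness, crit, geom)
    early = [crit[n] for n in CRITERIA_NAMES[:-1]]
    if bootstraps is None or not all(v is True for v in early):
        return result  # bootstrap criterion not evaluated
    if callable(bootstraps):
        bootstraps = bootstraps()

    passes = 0
    for bmap in bootstraps:
        try:
            s = gridness_score(
                bmap, min_overlap=min_overlap, r_thresh=r_thresh,
                min_bins=min_bins, ellipse_thresh=ellipse_thresh,
            )
        except DegenerateGeometryError:
            continue
        if s >= gridness_thresh:
            passes += 1
    result.bootstrap_pass_count = passes
    result.criteria["bootstrap"] = bool(passes >= min_bootstrap_pass)
    return result
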