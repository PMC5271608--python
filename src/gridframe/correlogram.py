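"""Spatial cross/autocorrelograms and grid geometry.

The crosscorrelogram of two rate maps is the map of Pearson correlations
computed over their co-occupied bins for every discrete displacement of the
first map relative to the second; displacements whose overlap contains
fewer than 100 co-occupied bins are invalid.  The autocorrelogram of a grid
cell's rate map exposes the lattice geometry: its correlation fields (>= 20
contiguous bins with r > 0.1) define three canonical semi-axes, the grid
orientation and scale, and an ellipse fit to the six inner fields measures
elliptical distortion (index = 1 - B/A).

Sign conventions: displacements are in cm with y up; a correlation field of
``crosscorrelogram(a, b)`` at displacement v means translating map ``a`` by
+v aligns it with map ``b``.  Axis directions are deg CCW from +x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal
from skimage import measure

from .angles import wrap_grid_angle
from .ratemap import RateMap

__all__ = [
    "Correlogram",
    "CorrelationField",
    "GridGeometry",
    "DegenerateGeometryError",
    "crosscorrelogram",
    "autocorrelogram",
    "detect_fields",
    "central_field",
    "surrounding_fields",
    "canonical_axes",
    "grid_scale",
    "fit_ellipse_index",
    "analyze_geometry",
]


class DegenerateGeometryError(ValueError):
    """Too few correlation fields to measure the grid geometry."""


@dataclass
class Correlogram:
    """Pearson correlations indexed by (dx, dy) bin displacement."""

    r: np.ndarray  # [idy, idx]
    valid: np.ndarray
    bin_size: float
    n_overlap: np.ndarray | None = None

    @property
    def shape(self):
        return self.r.shape

    @property
    def dx_cm(self) -> np.ndarray:
        n = self.r.shape[1]
        return (np.arange(n) - (n - 1) // 2) * self.bin_size

    @property
    def dy_cm(self) -> np.ndarray:
        n = self.r.shape[0]
        return (np.arange(n) - (n - 1) // 2) * self.bin_size

    @property
    def center_index(self) -> tuple[int, int]:
        return ((self.r.shape[0] - 1) // 2, (self.r.shape[1] - 1) // 2)


@dataclass
class CorrelationField:
    """A connected region of suprathreshold correlogram bins."""

    com: tuple[float, float]  # (dx, dy) cm, correlation-weighted
    area: int  # bins
    peak_r: float
    label: int = 0

    @property
    def distance(self) -> float:
        return math.hypot(*self.com)

    @property
    def angle(self) -> float:
        """Direction of the center of mass, deg CCW from +x."""
        return math.degrees(math.atan2(self.com[1], self.com[0]))


@dataclass
class GridGeometry:
    """Geometry of one rate map's autocorrelogram."""

    ax0: float  # deg CCW from +x
    ax1: float
    ax2: float
    orientation: float  # deg, mod 60, reported in [-30, 30)
    scale: float  # cm
    elliptical_index: float
    ellipse_axes: tuple[float, float]  # (A, B) cm, A >= B
    ellipse_angle: float  # major-axis direction, deg CCW
    n_surrounding: int
    axis_separations: tuple[float, float]  # (ax1-ax0, ax0-ax2) deg
    gridness: float | None = None


def _corr_sums(A: np.ndarray, B: np.ndarray):
    """All-displacement sums needed for masked Pearson correlations.

    Returns (n, Sa, Sb, Saa, Sbb, Sab) as full-size arrays where index
    (idy, idx) corresponds to comparing A[i, j] with B[i + dy, j + dx],
    dy = idy - (nyA - 1), dx = idx - (nxA - 1).
    """
    MA = np.isfinite(A).astype(float)
    MB = np.isfinite(B).astype(float)
    A0 = np.where(np.isfinite(A), A, 0.0)
    B0 = np.where(np.isfinite(B), B, 0.0)
    Ar = A0[::-1, ::-1]
    Mr = MA[::-1, ::-1]

    def conv(x, y):
        return signal.convolve(x, y, mode="full", method="auto")

    n = conv(MB, Mr)
    Sa = conv(MB, Ar)
    Sb = conv(B0, Mr)
    Saa = conv(MB, (A0 * A0)[::-1, ::-1])
    Sbb = conv(B0 * B0, Mr)
    Sab = conv(B0, Ar)
    return n, Sa, Sb, Saa, Sbb, Sab


def crosscorrelogram(
    map_a: RateMap, map_b: RateMap, min_overlap: int = 100
) -> Correlogram:
    """Pearson correlation of two rate maps at all discrete displacements.

    Both maps must share the bin size.  A displacement is valid only when
    the overlapping region contains at least ``min_overlap`` co-occupied
    bins and both windows have nonzero variance.
    """
    if not math.isclose(map_a.bin_size, map_b.bin_size):
        raise ValueError("bin size mismatch between maps")
    n, Sa, Sb, Saa, Sbb, Sab = _corr_sums(map_a.rate, map_b.rate)
    n = np.round(n)
    num = n * Sab - Sa * Sb
    va = n * Saa - Sa * Sa
    vb = n * Sbb - Sb * Sb
    # guard against catastrophic cancellation on (near-)constant windows
    tol_a = 1e-9 * n * np.abs(Saa)
    tol_b = 1e-9 * n * np.abs(Sbb)
    va = np.where(va > tol_a, va, 0.0)
    vb = np.where(vb > tol_b, vb, 0.0)
    denom = np.sqrt(va * vb)
    valid = (n >= min_overlap) & (denom > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(valid, num / np.where(denom > 0, denom, 1.0), np.nan)
    r = np.clip(r, -1.0, 1.0)
    r = np.where(valid, r, np.nan)
    return Correlogram(r, valid, bin_size=map_a.bin_size, n_overlap=n)


def autocorrelogram(rmap: RateMap, min_overlap: int = 100) -> Correlogram:
    """Crosscorrelogram of a rate map with itself."""
    return crosscorrelogram(rmap, rmap, min_overlap=min_overlap)


def detect_fields(
    corr: Correlogram, r_thresh: float = 0.1, min_bins: int = 20
) -> list[CorrelationField]:
    """Connected components of bins with correlation above threshold.

    8-connectivity; components smaller than ``min_bins`` are discarded.
    Centers of mass are correlation-weighted and given in cm displacement
    from the correlogram center.  Fields are returned sorted by distance
    from the center.
    """
    above = np.where(corr.valid, corr.r > r_thresh, False)
    labels = measure.label(above, connectivity=2)
    dx = corr.dx_cm
    dy = corr.dy_cm
    fields = []
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        area = int(mask.sum())
        if area < min_bins:
            continue
        w = np.where(mask, corr.r, 0.0)
        tot = w.sum()
        com_x = float((w.sum(axis=0) @ dx) / tot)
        com_y = float((w.sum(axis=1) @ dy) / tot)
        fields.append(
            CorrelationField((com_x, com_y), area, float(np.nanmax(corr.r[mask])),
                             label=lab)
        )
    fields.sort(key=lambda f: (f.distance, -f.area))
    return fields


def central_field(fields: list[CorrelationField]) -> CorrelationField:
    """Field whose center of mass is nearest the correlogram center.

    Ties are broken toward the larger area (the sort in
    :func:`detect_fields` already encodes this tie-break).
    """
    if not fields:
        raise DegenerateGeometryError("no correlation fields")
    return min(fields, key=lambda f: (f.distance, -f.area))


def surrounding_fields(
    fields: list[CorrelationField], n: int = 6
) -> list[CorrelationField]:
    """The ``n`` non-central fields closest to the center."""
    if len(fields) < 2:
        raise DegenerateGeometryError("no surrounding correlation fields")
    c = central_field(fields)
    rest = sorted((f for f in fields if f is not c),
                  key=lambda f: (f.distance, -f.area))
    return rest[:n]


def canonical_axes(
    fields: list[CorrelationField],
) -> tuple[CorrelationField, CorrelationField, CorrelationField]:
    """Fields defining the canonical semi-axes (AX0, AX1, AX2).

    AX0 is the semi-axis closest in direction to the semi-positive
    abscissa (an exact tie at +/-30 deg resolves to the CCW candidate);
    AX1 is the first semi-axis CCW from AX0 and AX2 the first CW.
    """
    ring = surrounding_fields(fields, n=6)
    if len(ring) < 3:
        raise DegenerateGeometryError(
            f"need >= 3 surrounding fields, found {len(ring)}"
        )

    def wrapped(f):
        return (f.angle + 180.0) % 360.0 - 180.0

    def ax0_key(f):
        a = wrapped(f)
        return (abs(a), -a)  # tie at +/-30: prefer the CCW (positive) one

    f0 = min(ring, key=ax0_key)
    others = [f for f in ring if f is not f0]
    ccw_off = lambda f: (f.angle - f0.angle) % 360.0
    cw_off = lambda f: (f0.angle - f.angle) % 360.0
    f1 = min(others, key=ccw_off)
    f2 = min(others, key=cw_off)
    if f1 is f2:
        raise DegenerateGeometryError("axes collapsed onto one field")
    return f0, f1, f2


def _orientation_from_axes(ax_angles) -> float:
    """Circular mean of semi-axis directions in the 60-deg-periodic space."""
    z = np.exp(1j * np.radians(np.asarray(ax_angles) * 6.0))
    mean = np.degrees(np.angle(z.mean())) / 6.0
    return wrap_grid_angle(mean)


def grid_scale(fields: list[CorrelationField]) -> float:
    """Average distance (cm) of the three axis fields from the center."""
    f0, f1, f2 = canonical_axes(fields)
    return (f0.distance + f1.distance + f2.distance) / 3.0


def fit_ellipse_index(
    fields: list[CorrelationField],
) -> tuple[float, float, float, float]:
    """Ellipse fit to the 6 inner fields: (A, B, elliptical index, angle).

    A direct conic (least-squares) ellipse fit to the centers of mass of
    the six correlation fields most closely surrounding the central field;
    the index is 1 - B/A with B <= A, and ``angle`` is the major-axis
    direction (deg CCW).
    """
    ring = surrounding_fields(fields, n=6)
    if len(ring) < 6:
        raise DegenerateGeometryError(
            f"ellipse fit needs 6 surrounding fields, found {len(ring)}"
        )
    pts = np.array([f.com for f in ring])
    try:
        model = measure.EllipseModel.from_estimate(pts)
        if not model:
            raise DegenerateGeometryError("ellipse fit failed")
        xc, yc = model.center
        a, b = model.axis_lengths
        theta = model.theta
    except AttributeError:  # older scikit-image
        model = measure.EllipseModel()
        if not model.estimate(pts):
            raise DegenerateGeometryError("ellipse fit failed")
        xc, yc, a, b, theta = model.params
    if a >= b:
        A, B, ang = a, b, math.degrees(theta)
    else:
        A, B, ang = b, a, math.degrees(theta) + 90.0
    ang = (ang + 90.0) % 180.0 - 90.0
    return float(A), float(B), float(1.0 - B / A), float(ang)


def analyze_geometry(corr: Correlogram, r_thresh: float = 0.1,
                     min_bins: int = 20) -> GridGeometry:
    """Extract canonical axes, orientation, scale and ellipse measures."""
    fields = detect_fields(corr, r_thresh=r_thresh, min_bins=min_bins)
    f0, f1, f2 = canonical_axes(fields)
    ax0, ax1, ax2 = f0.angle, f1.angle, f2.angle
    orientation = _orientation_from_axes([ax0, ax1, ax2])
    scale = (f0.distance + f1.distance + f2.distance) / 3.0
    sep1 = (ax1 - ax0) % 360.0
    sep2 = (ax0 - ax2) % 360.0
    try:
        A, B, ell_index, ell_angle = fit_ellipse_index(fields)
    except DegenerateGeometryError:
        A = B = float("nan")
        ell_index = float("nan")
        ell_angle = float("nan")
    ring = surrounding_fields(fields, n=6)
    return GridGeometry(
        ax0=ax0, ax1=ax1, ax2=ax2, orientation=orientation, scale=scale,
        elliptical_index=ell_index, ellipse_axes=(A, B),
        ellipse_angle=ell_angle, n_surrounding=len(ring),
        axis_separations=(sep1, sep2),
    )
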