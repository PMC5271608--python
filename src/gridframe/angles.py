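"""Angle arithmetic for 60-degree-symmetric grids.

A hexagonal grid is invariant under rotations by multiples of 60 degrees, so
any grid rotation is only defined within a circular range of one sixth of a
turn.  We adopt the convention used throughout the package: rotations are
reported in degrees, clockwise positive, wrapped to the half-open interval
[-30, +30) where -30 and +30 identify the same rotation.

The "geometric" reference frame of a square platform is defined by the 90
degree symmetry of the square: a physical rotation is replaced by the
congruent rotation of minimal magnitude before it is expressed in grid
angular space.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_grid_angle",
    "wrap_half_turn",
    "to_grid_angle",
    "minimal_square_rotation",
    "geometric_frame_angle",
    "grid_angle_difference",
]


def wrap_grid_angle(angle_deg):
    """Wrap an angle (deg) into the grid's circular range [-30, +30)."""
    wrapped = (np.asarray(angle_deg, dtype=float) + 30.0) % 60.0 - 30.0
    if np.ndim(angle_deg) == 0:
        return float(wrapped)
    return wrapped


def wrap_half_turn(angle_deg: float) -> float:
    """Wrap an angle (deg) into [-180, +180)."""
    return (angle_deg + 180.0) % 360.0 - 180.0


def to_grid_angle(physical_rotation_cw_deg: float) -> float:
    """Express a physical rotation (deg, CW positive) in grid angular space.

    Because of the grid's 60 degree symmetry, a 70 degree CW platform
    rotation is equivalent to a +10 degree grid rotation and a 45 degree CW
    rotation to a -15 degree (15 CCW) grid rotation.

    Parameters
    ----------
    physical_rotation_cw_deg:
        Any finite rotation angle in degrees, clockwise positive.

    Returns
    -------
    float
        The equivalent rotation in [-30, +30), clockwise positive.
    """
    a = float(physical_rotation_cw_deg)
    if not np.isfinite(a):
        raise ValueError("rotation angle must be finite")
    return wrap_grid_angle(a)


def minimal_square_rotation(physical_rotation_cw_deg: float) -> float:
    """Minimal rotation congruent with a square's 90 degree symmetry.

    Among all rotations congruent to the physical rotation modulo 90
    degrees, return the one of minimal magnitude (deg, CW positive, in
    [-45, +45]).  An exact tie at +/-45 is resolved toward the candidate
    opposite in sign to the physical rotation, so a 45 CW physical rotation
    maps to the 45 CCW congruent configuration.
    """
    a = float(physical_rotation_cw_deg)
    if not np.isfinite(a):
        raise ValueError("rotation angle must be finite")
    reduced = a % 90.0
    candidates = (reduced, reduced - 90.0)
    lo, hi = sorted(candidates, key=abs)
    if abs(abs(lo) - abs(hi)) < 1e-12:  # tie at +/-45
        sign = -1.0 if a >= 0 else 1.0
        return sign * 45.0
    return lo


def geometric_frame_angle(physical_rotation_cw_deg: float) -> float:
    """Rotation of the square platform's geometric frame, in grid space.

    The geometric reference frame follows the 90-degree-congruent
    configuration of the square platform implying the smallest rotation;
    its angle is then expressed in the grid's [-30, +30) space.  For a 70
    degree CW platform rotation this is -20 (20 CCW); for 45 CW it is +15.
    """
    return wrap_grid_angle(minimal_square_rotation(physical_rotation_cw_deg))


def grid_angle_difference(a_deg: float, b_deg: float) -> float:
    """Wrapped difference a - b in grid angular space ([-30, +30))."""
    return wrap_grid_angle(float(a_deg) - float(b_deg))
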