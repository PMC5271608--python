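"""Rotation and phase-shift decomposition across reference frames.

A grid's response to a platform manipulation is decomposed against three
candidate reference frames: the room (distal cues), the physical platform,
and the platform's geometric (90-degree-symmetric) configuration.  The
measured grid rotation in the room is compared with the rotation each frame
predicts, and the residual phase shift is read off a rotation-adjusted
crosscorrelogram: the STD rate map is rotated by the frame's full physical
rotation plus the measured residual rotation, and the phase shift is the
displacement of the most central correlation field from the center.

For the SHIFT manipulation (platform translated by half its side, 68.5 cm
for a 137 cm platform) the room-relative phase follows a closed-form
circular algebra: the platform-frame phase predicted by a room-bound grid is

    alpha = 2*pi * 68.5 / (scale * cos(orientation))      (wrapped to (-pi, pi])

the observed platform-frame phase is beta = 2*pi * shift_x / (scale *
cos(orientation)), and gamma = beta - alpha (wrapped) converts back to a
room-frame shift in cm via gamma * scale * cos(orientation) / (2*pi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .angles import (
    geometric_frame_angle,
    minimal_square_rotation,
    to_grid_angle,
    wrap_grid_angle,
)
from .correlogram import (
    DegenerateGeometryError,
    GridGeometry,
    central_field,
    crosscorrelogram,
    detect_fields,
)
from .ratemap import RateMap, rotate_rate_map

__all__ = [
    "FrameResponse",
    "ShiftPhase",
    "FRAMES",
    "grid_rotation",
    "frame_physical_rotation",
    "frame_angle",
    "rotation_in_frame",
    "phase_shift_between_maps",
    "phase_shift_in_frame",
    "shift_alpha",
    "shift_beta",
    "room_phase_shift",
    "frame_responses",
    "shift_responses",
    "quadrant_minimum_phase",
]

FRAMES = ("room", "platform", "geometry")


@dataclass
class FrameResponse:
    """Rotation and phase shift of a grid relative to one reference frame."""

    frame: str
    rotation: float  # deg in [-30, 30), CW positive
    phase_shift: tuple[float, float]  # cm
    phase_fraction: float  # |shift| / grid period

    @property
    def phase_magnitude(self) -> float:
        return math.hypot(*self.phase_shift)


@dataclass
class ShiftPhase:
    """Closed-form phase decomposition for the SHIFT manipulation."""

    alpha: float  # rad, predicted platform-frame phase of a room-bound grid
    beta: float  # rad, observed platform-frame phase
    gamma: float  # rad, beta - alpha (room-frame phase)
    room_shift: float  # cm along the translation axis


def grid_rotation(std_geom: GridGeometry, m_geom: GridGeometry) -> float:
    """Measured grid rotation in the room (deg CW, wrapped to [-30, 30)).

    Computed as the difference of grid direction between the STD and the
    manipulated session.  Orientations are stored CCW-positive, so a
    clockwise rotation of the grid decreases the orientation.
    """
    return wrap_grid_angle(std_geom.orientation - m_geom.orientation)


def frame_physical_rotation(frame: str, platform_rotation_cw: float) -> float:
    """Full physical rotation (deg CW) performed by a reference frame."""
    if frame == "room":
        return 0.0
    if frame == "platform":
        return float(platform_rotation_cw)
    if frame == "geometry":
        return minimal_square_rotation(platform_rotation_cw)
    raise ValueError(f"unknown frame {frame!r}")


def frame_angle(frame: str, platform_rotation_cw: float) -> float:
    """Rotation of a reference frame expressed in grid angular space."""
    if frame == "room":
        return 0.0
    if frame == "platform":
        return to_grid_angle(platform_rotation_cw)
    if frame == "geometry":
        return geometric_frame_angle(platform_rotation_cw)
    raise ValueError(f"unknown frame {frame!r}")


def rotation_in_frame(room_rotation: float, frame_angle_deg: float) -> float:
    """Grid rotation relative to a reference frame (deg, [-30, 30)).

    The frame's rotation (in grid angular space) is subtracted from the
    measured grid rotation in the room; positive values are over-rotations
    and negative values under-rotations with respect to the frame.
    """
    return wrap_grid_angle(room_rotation - frame_angle_deg)


def phase_shift_between_maps(
    map_a: RateMap,
    map_b: RateMap,
    min_overlap: int = 100,
    r_thresh: float = 0.1,
    min_bins: int = 20,
) -> tuple[float, float]:
    """Displacement (cm) of the most central crosscorrelogram field.

    The returned vector is the translation of ``map_a`` that best aligns
    it with ``map_b``.
    """
    corr = crosscorrelogram(map_a, map_b, min_overlap=min_overlap)
    fields = detect_fields(corr, r_thresh=r_thresh, min_bins=min_bins)
    if not fields:
        raise DegenerateGeometryError("no correlation field in crosscorrelogram")
    return central_field(fields).com


def phase_shift_in_frame(
    std_map: RateMap,
    m_map: RateMap,
    total_rotation_cw: float,
    min_overlap: int = 100,
    r_thresh: float = 0.1,
    min_bins: int = 20,
) -> tuple[float, float]:
    """Phase shift after rotating the STD map by ``total_rotation_cw`` deg.

    ``total_rotation_cw`` is the frame's full physical rotation plus the
    grid's measured residual rotation in that frame (for the room frame,
    simply the measured room rotation), so that the grids in the two maps
    are directionally aligned before the crosscorrelogram is computed.
    """
    rotated = (
        std_map
        if abs(total_rotation_cw) < 1e-12
        else rotate_rate_map(std_map, total_rotation_cw)
    )
    return phase_shift_between_maps(rotated, m_map, min_overlap, r_thresh,
                                    min_bins)


def _period_projection(scale: float, orientation_deg: float) -> float:
    c = math.cos(math.radians(orientation_deg))
    if c <= 0:
        raise ValueError("cos(orientation) must be positive")
    return scale * c


def _wrap_pi(x: float) -> float:
    """Wrap to (-pi, pi]."""
    w = math.fmod(x, 2.0 * math.pi)
    if w > math.pi:
        w -= 2.0 * math.pi
    elif w <= -math.pi:
        w += 2.0 * math.pi
    return w


def shift_alpha(scale: float, orientation_deg: float,
                translation: float = 68.5) -> float:
    """Predicted platform-frame phase (rad) of a room-anchored grid in SHIFT.

    alpha = 2*pi * translation / (scale * cos(orientation)), wrapped to
    (-pi, pi].  ``orientation`` must satisfy cos(orientation) > 0.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    period = _period_projection(scale, orientation_deg)
    return _wrap_pi(2.0 * math.pi * translation / period)


def shift_beta(platform_shift_x: float, scale: float,
               orientation_deg: float) -> float:
    """Observed platform-frame phase (rad) from the measured x shift."""
    period = _period_projection(scale, orientation_deg)
    return _wrap_pi(2.0 * math.pi * platform_shift_x / period)


def room_phase_shift(
    platform_shift_x: float,
    scale: float,
    orientation_deg: float,
    translation: float = 68.5,
) -> ShiftPhase:
    """Room-frame phase shift (cm) implied by the observed platform shift.

    gamma = beta - alpha wrapped to (-pi, pi]; the room shift along the
    translation axis is gamma * scale * cos(orientation) / (2*pi).
    """
    alpha = shift_alpha(scale, orientation_deg, translation)
    beta = shift_beta(platform_shift_x, scale, orientation_deg)
    gamma = _wrap_pi(beta - alpha)
    period = _period_projection(scale, orientation_deg)
    return ShiftPhase(alpha, beta, gamma, gamma * period / (2.0 * math.pi))


def frame_responses(
    std_map: RateMap,
    m_map: RateMap,
    std_geom: GridGeometry,
    m_geom: GridGeometry,
    platform_rotation_cw: float,
    frames=FRAMES,
    min_overlap: int = 100,
    r_thresh: float = 0.1,
    min_bins: int = 20,
) -> dict[str, FrameResponse]:
    """Rotation + phase decomposition for a rotation-type manipulation.

    Both maps must be in the room (camera) frame on a common grid.  For
    each requested frame the STD map is rotated by the frame's physical
    rotation plus the measured residual, and the phase shift is read off
    the rotation-adjusted crosscorrelogram.
    """
    room_rot = grid_rotation(std_geom, m_geom)
    period = std_geom.scale
    out: dict[str, FrameResponse] = {}
    for fr in frames:
        resid = rotation_in_frame(room_rot, frame_angle(fr, platform_rotation_cw))
        total = frame_physical_rotation(fr, platform_rotation_cw) + resid
        shift = phase_shift_in_frame(std_map, m_map, total, min_overlap,
                                     r_thresh, min_bins)
        out[fr] = FrameResponse(fr, resid, shift,
                                math.hypot(*shift) / period)
    return out


def shift_responses(
    std_map: RateMap,
    m_map: RateMap,
    std_geom: GridGeometry,
    m_geom: GridGeometry,
    translation: float = 68.5,
    min_overlap: int = 100,
    r_thresh: float = 0.1,
    min_bins: int = 20,
) -> tuple[dict[str, FrameResponse], ShiftPhase]:
    """Rotation + phase decomposition for the SHIFT manipulation.

    Both maps are in their own camera's platform-centered frame, so the
    directly measured phase shift is relative to the platform (and the
    coincident geometric frame).  The room-frame x component follows the
    closed-form alpha/beta/gamma algebra; the y component (orthogonal to
    the translation) equals the platform-frame y component.
    """
    rot = grid_rotation(std_geom, m_geom)  # same for all frames in SHIFT
    plat_shift = phase_shift_in_frame(std_map, m_map, rot, min_overlap,
                                      r_thresh, min_bins)
    period = std_geom.scale
    # The measured shift is the displacement of the grid pattern from STD
    # to SHIFT in the platform frame; the alpha/beta algebra counts shifts
    # in the opposite sense (a perfectly room-bound grid satisfies
    # beta = alpha), so the sign flips on the way in and out.
    phase = room_phase_shift(-plat_shift[0], std_geom.scale,
                             std_geom.orientation, translation)
    room_vec = (-phase.room_shift, plat_shift[1])
    out = {
        "platform": FrameResponse("platform", rot, plat_shift,
                                  math.hypot(*plat_shift) / period),
        "geometry": FrameResponse("geometry", rot, plat_shift,
                                  math.hypot(*plat_shift) / period),
        "room": FrameResponse("room", rot, room_vec,
                              math.hypot(*room_vec) / period),
    }
    return out, phase


def quadrant_minimum_phase(
    std_map: RateMap,
    m_map: RateMap,
    room_rotation_cw: float,
    min_overlap: int = 100,
    r_thresh: float = 0.1,
    min_bins: int = 20,
) -> tuple[float, tuple[float, float]]:
    """Diagnostic: minimal phase shift over the four 90-degree alignments.

    Tests the hypothesis that a grid re-anchored to an arbitrary side of
    the square platform: the STD map is rotated by each 90-degree-congruent
    alignment (plus the measured residual) and the smallest resulting phase
    shift magnitude is returned with its vector.
    """
    best = None
    for k in range(4):
        total = room_rotation_cw + 90.0 * k
        try:
            shift = phase_shift_in_frame(std_map, m_map, total, min_overlap,
                                         r_thresh, min_bins)
        except DegenerateGeometryError:
            continue
        mag = math.hypot(*shift)
        if best is None or mag < best[0]:
            best = (mag, shift)
    if best is None:
        raise DegenerateGeometryError("no central field in any alignment")
    return best
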