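"""Geometric coupling of simultaneously recorded grid-cell pairs.

Pairs are formed among grids recorded in the same session that pass the
grid classifier in both the STD and the manipulated session and whose STD
rate maps are quantitatively distinct (Pearson r < 0.5).  Coupling is
measured by (1) the absolute difference of the two grids' rotations and
(2) a joint correlation: both STD maps are rigidly co-transformed by the
pair's average rotation and average phase-shift vector, stacked with the
manipulated-session maps, and compared by cosine similarity over bins
defined in both stacks.  Control distributions randomly perturb each map's
orientation and phase and re-run the measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .angles import wrap_grid_angle
from .correlogram import (
    DegenerateGeometryError,
    analyze_geometry,
    autocorrelogram,
)
from .frames import grid_rotation, phase_shift_in_frame
from .ratemap import (
    RateMap,
    pearson_overlap,
    rotate_rate_map,
    translate_rate_map,
)

__all__ = [
    "PairCoupling",
    "scale_ratio_class",
    "select_pairs",
    "rotation_difference",
    "mean_rotation",
    "joint_correlation",
    "measure_pair",
    "draw_perturbation",
    "control_distributions",
]

SR_EDGES = (1.3, 1.9)


@dataclass
class PairCoupling:
    """Coupling measures for one pair of simultaneously recorded grids."""

    unit_a: tuple
    unit_b: tuple
    scale_ratio: float
    sr_class: str
    rotation_difference: float  # deg, [0, 30]
    joint_correlation: float  # [-1, 1]


def scale_ratio_class(ratio: float, edges=SR_EDGES) -> str:
    if ratio <= edges[0]:
        return "SR1"
    if ratio <= edges[1]:
        return "SR2"
    return "SR3"


def select_pairs(
    unit_ids: list,
    std_maps: dict,
    passed: dict | None = None,
    max_corr: float = 0.5,
) -> list[tuple]:
    """Unordered pairs of units with distinct STD firing patterns.

    ``std_maps`` maps unit id -> STD rate map; ``passed`` (unit id ->
    bool) restricts to units passing classification in both sessions of
    the comparison.  Pairs whose STD maps correlate at or above
    ``max_corr`` are excluded.
    """
    eligible = [u for u in unit_ids
                if (passed is None or passed.get(u, False)) and u in std_maps]
    pairs = []
    for i, a in enumerate(eligible):
        for b in eligible[i + 1 :]:
            r = pearson_overlap(std_maps[a], std_maps[b])
            if np.isfinite(r) and r < max_corr:
                pairs.append((a, b))
    return pairs


def rotation_difference(rot_a: float, rot_b: float) -> float:
    """Wrapped absolute rotation difference (deg) in [0, 30]."""
    return abs(wrap_grid_angle(float(rot_a) - float(rot_b)))


def mean_rotation(rot_a: float, rot_b: float) -> float:
    """Circular mean of two grid rotations in the 60-deg-expanded space."""
    z = np.exp(1j * np.radians(np.array([rot_a, rot_b]) * 6.0))
    return wrap_grid_angle(np.degrees(np.angle(z.mean())) / 6.0)


def _center_normalize(rmap: RateMap) -> np.ndarray:
    v = rmap.rate.copy()
    m = np.isfinite(v)
    if m.sum() == 0:
        return v
    v[m] = v[m] - v[m].mean()
    norm = math.sqrt(float(np.sum(v[m] ** 2)))
    if norm > 0:
        v[m] = v[m] / norm
    return v


def joint_correlation(
    std_maps: tuple[RateMap, RateMap],
    m_maps: tuple[RateMap, RateMap],
    rotations: tuple[float, float],
    shifts: tuple[tuple[float, float], tuple[float, float]],
) -> float:
    """Cosine similarity of the rigidly co-transformed stacked map pairs.

    The two STD maps are rotated by the average rotation (circular mean in
    the 60-deg-expanded space) and translated by the average phase-shift
    vector, each map is mean-centered and normalized individually, the
    pairs are stacked, and the cosine is taken over entries defined in
    both stacked vectors.
    """
    rho = mean_rotation(*rotations)
    gbar = np.mean(np.asarray(shifts, dtype=float), axis=0)
    va, vm = [], []
    for smap, mmap in zip(std_maps, m_maps):
        transformed = rotate_rate_map(smap, rho)
        transformed = translate_rate_map(transformed, gbar[0], gbar[1])
        va.append(_center_normalize(transformed))
        vm.append(_center_normalize(mmap))
    va = np.concatenate([v.ravel() for v in va])
    vm = np.concatenate([v.ravel() for v in vm])
    both = np.isfinite(va) & np.isfinite(vm)
    if both.sum() < 2:
        raise DegenerateGeometryError("no overlap after the rigid transform")
    a, b = va[both], vm[both]
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0:
        raise DegenerateGeometryError("degenerate stacked vectors")
    return float(a @ b / denom)


def measure_pair(
    std_maps: tuple[RateMap, RateMap],
    m_maps: tuple[RateMap, RateMap],
    min_overlap: int = 100,
    r_thresh: float = 0.1,
    min_bins: int = 20,
) -> tuple[float, float, tuple[float, float], tuple]:
    """Measure rotations/phases of both grids and the coupling measures.

    Returns (rotation_difference, joint_correlation, (rot_a, rot_b),
    (shift_a, shift_b)); rotations and phase shifts are measured in the
    common (room) frame of the maps via each grid's own autocorrelogram
    geometry and rotation-adjusted crosscorrelogram.
    """
    rots = []
    shifts = []
    for smap, mmap in zip(std_maps, m_maps):
        sg = analyze_geometry(autocorrelogram(smap, min_overlap),
                              r_thresh=r_thresh, min_bins=min_bins)
        mg = analyze_geometry(autocorrelogram(mmap, min_overlap),
                              r_thresh=r_thresh, min_bins=min_bins)
        rot = grid_rotation(sg, mg)
        shift = phase_shift_in_frame(smap, mmap, rot, min_overlap, r_thresh,
                                     min_bins)
        rots.append(rot)
        shifts.append(shift)
    rd = rotation_difference(rots[0], rots[1])
    jc = joint_correlation(std_maps, m_maps, (rots[0], rots[1]),
                           (shifts[0], shifts[1]))
    return rd, jc, tuple(rots), tuple(shifts)


def draw_perturbation(rng: np.random.Generator, scale: float):
    """One control perturbation: (STD rotation deg, M direction deg, M distance cm).

    Rotation uniform on (-30, 30); shift direction uniform on (-180, 180)
    and distance uniform on (0, scale).
    """
    return (rng.uniform(-30.0, 30.0), rng.uniform(-180.0, 180.0),
            rng.uniform(0.0, scale))


def control_distributions(
    pairs: list[tuple[tuple[RateMap, RateMap], tuple[RateMap, RateMap]]],
    scales: list[tuple[float, float]],
    n_perturb: int = 10,
    seed: int | np.random.SeedSequence = 0,
    **measure_kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Coupling measures after random perturbation of each pair's alignment.

    Each replicate independently rotates each STD map by an angle drawn
    uniformly from (-30, 30) deg and shifts each manipulated-session map
    in a direction drawn uniformly from (-180, 180) deg by a distance
    drawn uniformly between 0 and that grid's scale, then re-runs the
    full pair measurement.  Returns arrays of shape (n_pairs, n_perturb)
    for rotation difference and joint correlation (NaN where the
    measurement degenerates).
    """
    rng = np.random.default_rng(seed)
    n_pairs = len(pairs)
    rd = np.full((n_pairs, n_perturb), np.nan)
    jc = np.full((n_pairs, n_perturb), np.nan)
    for ip, ((std_a, std_b), (m_a, m_b)) in enumerate(pairs):
        for k in range(n_perturb):
            p_std, p_m = [], []
            for smap, mmap, scale in zip((std_a, std_b), (m_a, m_b),
                                         scales[ip]):
                ang, direction, dist = draw_perturbation(rng, scale)
                p_std.append(rotate_rate_map(smap, ang))
                drad = math.radians(direction)
                p_m.append(
                    translate_rate_map(mmap, dist * math.cos(drad),
                                       dist * math.sin(drad))
                )
            try:
                rd[ip, k], jc[ip, k], _, _ = measure_pair(
                    (p_std[0], p_std[1]), (p_m[0], p_m[1]), **measure_kwargs
                )
            except (DegenerateGeometryError, ValueError):
                continue
    return rd, jc
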