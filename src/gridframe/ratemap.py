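"""Occupancy-normalized firing-rate maps.

The pipeline follows the standard open-field procedure: the tracked path is
smoothed with a clipped temporal Gaussian to estimate running speed,
immobility epochs (speed < 3 cm/s for > 500 ms) are expunged from the
*unsmoothed* trajectory and the spike train, positions are binned in
3 x 3 cm bins, bins with < 50 ms dwell are marked unoccupied, and the map
is smoothed with a clipped 5 x 5 Gaussian mask (variance 2 bin^2) that is
dynamically renormalized over occupied bins.  Bootstrap rate maps repeat
the whole procedure on spike trains resampled with replacement.

Missing values are IEEE NaN throughout; a bin is "occupied" iff its value
is finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.ndimage import map_coordinates

from .io import SpikeTrain, Trajectory

__all__ = [
    "RateMap",
    "estimate_speed",
    "filter_immobility",
    "compute_rate_map",
    "smooth_rate_map",
    "session_rate_map",
    "bootstrap_rate_maps",
    "split_half_correlation",
    "resample_map",
    "rotate_rate_map",
    "translate_rate_map",
    "pearson_overlap",
]


@dataclass
class RateMap:
    """Binned, smoothed firing-rate image with missing-value mask.

    ``rate[iy, ix]`` is in Hz, indexed with y increasing along rows (so the
    array is origin='lower' when displayed).  Unoccupied bins are NaN.
    """

    rate: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    bin_size: float = 3.0
    frame: str = "camera"
    occupancy: np.ndarray | None = None
    spike_count: np.ndarray | None = None

    def __post_init__(self):
        self.rate = np.asarray(self.rate, dtype=float)
        self.x_edges = np.asarray(self.x_edges, dtype=float)
        self.y_edges = np.asarray(self.y_edges, dtype=float)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.rate)

    @property
    def shape(self) -> tuple[int, int]:
        return self.rate.shape

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def with_rate(self, rate: np.ndarray) -> "RateMap":
        return replace(self, rate=np.asarray(rate, dtype=float),
                       occupancy=None, spike_count=None)


def _clipped_gaussian_kernel(sigma: float, half_width: int) -> np.ndarray:
    j = np.arange(-half_width, half_width + 1)
    return np.exp(-(j**2) / (2.0 * sigma**2))


def estimate_speed(
    traj: Trajectory, temporal_sigma: float = 0.3, clip_sigmas: float = 2.0
) -> np.ndarray:
    """Per-frame running speed (cm/s) from the Gaussian-smoothed path.

    Both position series are convolved with a clipped Gaussian mask
    (``temporal_sigma`` seconds, clipped at +/- ``clip_sigmas`` standard
    deviations) whose values are renormalized at each step near the series
    edges; the speed is the displacement between consecutive smoothed
    frames times the frame rate.  The first frame inherits the speed of the
    first interval.
    """
    n = len(traj)
    if n < 2:
        raise ValueError("need at least 2 samples to estimate speed")
    sigma_frames = temporal_sigma * traj.frame_rate
    hw = max(1, int(round(clip_sigmas * sigma_frames)))
    w = _clipped_gaussian_kernel(sigma_frames, hw)
    norm = np.convolve(np.ones(n), w, mode="same")
    xs = np.convolve(traj.x, w, mode="same") / norm
    ys = np.convolve(traj.y, w, mode="same") / norm
    disp = np.hypot(np.diff(xs), np.diff(ys))
    speed = np.empty(n)
    speed[1:] = disp * traj.frame_rate
    speed[0] = speed[1]
    return speed


def _immobility_mask(
    traj: Trajectory, v_thresh: float, min_dur: float, temporal_sigma: float
) -> np.ndarray:
    """True for frames inside an expunged immobility epoch."""
    speed = estimate_speed(traj, temporal_sigma=temporal_sigma)
    slow = speed < v_thresh
    dt = 1.0 / traj.frame_rate
    remove = np.zeros(len(traj), dtype=bool)
    i = 0
    n = len(traj)
    while i < n:
        if slow[i]:
            j = i
            while j + 1 < n and slow[j + 1]:
                j += 1
            if (j - i + 1) * dt > min_dur:  # strictly longer than min_dur
                remove[i : j + 1] = True
            i = j + 1
        else:
            i += 1
    return remove


def filter_immobility(
    traj: Trajectory,
    spikes: SpikeTrain | None = None,
    v_thresh: float = 3.0,
    min_dur: float = 0.5,
    temporal_sigma: float = 0.3,
):
    """Expunge immobility epochs from trajectory and spike train.

    Epochs strictly longer than ``min_dur`` seconds during which the
    smoothed-path speed stays strictly below ``v_thresh`` cm/s are removed
    from the original (unsmoothed) trajectory; spikes falling within a
    removed frame's time slot are dropped.  Returns the filtered
    (trajectory, spike train); the spike train is None if none was given.
    """
    remove = _immobility_mask(traj, v_thresh, min_dur, temporal_sigma)
    keep = ~remove
    out_traj = Trajectory(traj.t[keep], traj.x[keep], traj.y[keep],
                          frame_rate=traj.frame_rate, frame=traj.frame)
    out_spikes = None
    if spikes is not None:
        frame_idx = _nearest_frame(traj.t, spikes.spike_times)
        out_spikes = SpikeTrain(spikes.unit_id,
                                spikes.spike_times[keep[frame_idx]],
                                depth_um=spikes.depth_um)
    return out_traj, out_spikes


def _nearest_frame(t: np.ndarray, times: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(t, times)
    idx = np.clip(idx, 1, len(t) - 1)
    left = times - t[idx - 1] < t[idx] - times
    return np.where(left, idx - 1, idx)


def _infer_extent(traj: Trajectory, bin_size: float) -> tuple[float, float, float, float]:
    m = max(np.max(np.abs(traj.x)), np.max(np.abs(traj.y)))
    half = math.ceil(m / bin_size + 1e-9) * bin_size
    return (-half, half, -half, half)


def compute_rate_map(
    traj: Trajectory,
    spikes: SpikeTrain,
    bin_size: float = 3.0,
    min_dwell: float = 0.05,
    extent: tuple[float, float, float, float] | None = None,
    frame: str = "camera",
) -> RateMap:
    """Unsmoothed rate map: spike count / dwell time per bin.

    ``extent`` is (x0, x1, y0, y1) in cm; when omitted it is a square
    symmetric about the origin snapped to whole bins.  Bins with dwell
    below ``min_dwell`` seconds are unoccupied (NaN).  Inputs are expected
    to be immobility-filtered.
    """
    if len(traj) == 0:
        raise ValueError("cannot bin an empty trajectory")
    if extent is None:
        extent = _infer_extent(traj, bin_size)
    x0, x1, y0, y1 = extent
    nx = int(round((x1 - x0) / bin_size))
    ny = int(round((y1 - y0) / bin_size))
    x_edges = x0 + np.arange(nx + 1) * bin_size
    y_edges = y0 + np.arange(ny + 1) * bin_size
    dt = 1.0 / traj.frame_rate
    occ = np.histogram2d(traj.x, traj.y, bins=[x_edges, y_edges])[0].T * dt
    sx = np.interp(spikes.spike_times, traj.t, traj.x)
    sy = np.interp(spikes.spike_times, traj.t, traj.y)
    cnt = np.histogram2d(sx, sy, bins=[x_edges, y_edges])[0].T
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occ >= min_dwell, cnt / occ, np.nan)
    return RateMap(rate, x_edges, y_edges, bin_size=bin_size, frame=frame,
                   occupancy=occ, spike_count=cnt)


def _smoothing_kernels(size: int, variance: float):
    hw = size // 2
    j = np.arange(-hw, hw + 1)
    K = np.exp(-(j[:, None] ** 2 + j[None, :] ** 2) / (2.0 * variance))
    return K, np.ones((size, size))


def smooth_rate_map(
    rmap: RateMap, size: int = 5, variance: float = 2.0, min_occupied: int = 5
) -> RateMap:
    """Smooth with a clipped 2-D Gaussian mask renormalized over occupied bins.

    The mask is ``size`` x ``size`` bins with the given variance (bin^2).
    At each step the mask weights are renormalized over the occupied bins it
    covers; if fewer than ``min_occupied`` occupied bins fall within the
    mask, the output bin is unoccupied.
    """
    K, ones = _smoothing_kernels(size, variance)
    valid = rmap.valid.astype(float)
    filled = np.where(rmap.valid, rmap.rate, 0.0)
    num = signal.convolve(filled, K, mode="same", method="direct")
    den = signal.convolve(valid, K, mode="same", method="direct")
    cnt = signal.convolve(valid, ones, mode="same", method="direct")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(np.round(cnt) >= min_occupied, num / den, np.nan)
    return rmap.with_rate(out)


def session_rate_map(
    traj: Trajectory,
    spikes: SpikeTrain,
    bin_size: float = 3.0,
    min_dwell: float = 0.05,
    v_thresh: float = 3.0,
    min_dur: float = 0.5,
    temporal_sigma: float = 0.3,
    smooth_size: int = 5,
    smooth_variance: float = 2.0,
    min_occupied: int = 5,
    extent: tuple[float, float, float, float] | None = None,
    frame: str = "camera",
) -> RateMap:
    """Full pipeline: immobility filter, binning, smoothing."""
    ftraj, fspikes = filter_immobility(traj, spikes, v_thresh, min_dur,
                                       temporal_sigma)
    raw = compute_rate_map(ftraj, fspikes, bin_size, min_dwell, extent, frame)
    return smooth_rate_map(raw, smooth_size, smooth_variance, min_occupied)


def bootstrap_rate_maps(
    traj: Trajectory,
    spikes: SpikeTrain,
    n: int = 100,
    seed: int | np.random.SeedSequence = 0,
    **pipeline_kwargs,
) -> list[RateMap]:
    """Rate maps from ``n`` spike trains resampled with replacement.

    Each replicate draws a spike train of the original size (with
    replacement, preserving each spike's position) and reapplies the whole
    filter -> bin -> smooth pipeline.  The occupancy (trajectory) side of
    the pipeline is identical across replicates, so it is computed once;
    the per-replicate spike binning and smoothing are exactly those of the
    full pipeline.
    """
    if len(spikes) == 0:
        raise ValueError("bootstrap requires at least one spike")
    rng = np.random.default_rng(seed)
    kw = dict(pipeline_kwargs)
    bin_size = kw.get("bin_size", 3.0)
    min_dwell = kw.get("min_dwell", 0.05)
    extent = kw.get("extent")
    frame = kw.get("frame", "camera")
    ftraj, _ = filter_immobility(traj, None, kw.get("v_thresh", 3.0),
                                 kw.get("min_dur", 0.5),
                                 kw.get("temporal_sigma", 0.3))
    base = compute_rate_map(
        ftraj, SpikeTrain(spikes.unit_id, np.empty(0)), bin_size, min_dwell,
        extent, frame,
    )
    occ = base.occupancy
    ny, nx = occ.shape
    occupied = occ >= min_dwell

    # per-original-spike flat bin index (or -1 if dropped by the filter /
    # outside the extent), so each resample is a bincount
    remove = _immobility_mask(traj, kw.get("v_thresh", 3.0),
                              kw.get("min_dur", 0.5),
                              kw.get("temporal_sigma", 0.3))
    frame_idx = _nearest_frame(traj.t, spikes.spike_times)
    kept = ~remove[frame_idx]
    sx = np.interp(spikes.spike_times, ftraj.t, ftraj.x)
    sy = np.interp(spikes.spike_times, ftraj.t, ftraj.y)
    ix = np.floor((sx - base.x_edges[0]) / bin_size).astype(int)
    iy = np.floor((sy - base.y_edges[0]) / bin_size).astype(int)
    inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny) & kept
    flat = np.where(inside, iy * nx + ix, nx * ny)  # overflow slot for dropped

    size = kw.get("smooth_size", 5)
    variance = kw.get("smooth_variance", 2.0)
    min_occupied = kw.get("min_occupied", 5)
    K, ones = _smoothing_kernels(size, variance)
    validf = occupied.astype(float)
    den = signal.convolve(validf, K, mode="same", method="direct")
    cntv = np.round(signal.convolve(validf, ones, mode="same", method="direct"))

    n_spikes = len(spikes)
    maps: list[RateMap] = []
    for _ in range(n):
        pick = rng.integers(0, n_spikes, n_spikes)
        counts = np.bincount(flat[pick], minlength=nx * ny + 1)[:-1].reshape(ny, nx)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(occupied, counts / occ, 0.0)
        num = signal.convolve(rate, K, mode="same", method="direct")
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(cntv >= min_occupied, num / den, np.nan)
        maps.append(RateMap(out, base.x_edges, base.y_edges, bin_size=bin_size,
                            frame=frame))
    return maps


def pearson_overlap(a: RateMap | np.ndarray, b: RateMap | np.ndarray) -> float:
    """Pearson r over bins occupied in both maps."""
    ra = a.rate if isinstance(a, RateMap) else np.asarray(a, dtype=float)
    rb = b.rate if isinstance(b, RateMap) else np.asarray(b, dtype=float)
    m = np.isfinite(ra) & np.isfinite(rb)
    if m.sum() < 2:
        return float("nan")
    va, vb = ra[m], rb[m]
    va = va - va.mean()
    vb = vb - vb.mean()
    denom = math.sqrt((va @ va) * (vb @ vb))
    if denom == 0:
        return float("nan")
    return float((va @ vb) / denom)


class InsufficientDataError(ValueError):
    """Session too short (or too sparse) for the requested analysis."""


def split_half_correlation(
    traj: Trajectory,
    spikes: SpikeTrain,
    min_duration: float = 1800.0,
    **pipeline_kwargs,
) -> float:
    """Pearson r between rate maps of the session's two halves.

    Only sessions longer than ``min_duration`` seconds (30 min by default)
    are eligible; shorter sessions raise :class:`InsufficientDataError` so
    callers can skip them with a logged reason.
    """
    if traj.duration < min_duration:
        raise InsufficientDataError(
            f"session lasts {traj.duration:.0f} s < {min_duration:.0f} s"
        )
    kw = dict(pipeline_kwargs)
    if kw.get("extent") is None:
        kw["extent"] = _infer_extent(traj, kw.get("bin_size", 3.0))
    mid = 0.5 * (traj.t[0] + traj.t[-1])
    first = traj.t <= mid
    halves = []
    for sel in (first, ~first):
        sub_t = traj.t[sel]
        sub = Trajectory(sub_t, traj.x[sel], traj.y[sel],
                         frame_rate=traj.frame_rate, frame=traj.frame)
        ssel = (spikes.spike_times >= sub_t[0]) & (spikes.spike_times <= sub_t[-1])
        sspk = SpikeTrain(spikes.unit_id, spikes.spike_times[ssel])
        halves.append(session_rate_map(sub, sspk, **kw))
    return pearson_overlap(*halves)


# ---------------------------------------------------------------------------
# NaN-aware geometric resampling of maps
# ---------------------------------------------------------------------------

def resample_map(
    rmap: RateMap,
    matrix: np.ndarray,
    out_extent: tuple[float, float, float, float] | None = None,
) -> RateMap:
    """Geometrically transform map content: out(x) = in(matrix^-1 @ x).

    ``matrix`` maps input spatial coordinates (cm, about the origin) to
    output coordinates.  Bilinear interpolation; any output bin whose
    interpolation stencil touches a missing input bin is missing.
    """
    Minv = np.linalg.inv(np.asarray(matrix, dtype=float))
    if out_extent is None:
        x_edges, y_edges = rmap.x_edges, rmap.y_edges
    else:
        x0, x1, y0, y1 = out_extent
        nx = int(round((x1 - x0) / rmap.bin_size))
        ny = int(round((y1 - y0) / rmap.bin_size))
        x_edges = x0 + np.arange(nx + 1) * rmap.bin_size
        y_edges = y0 + np.arange(ny + 1) * rmap.bin_size
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    X, Y = np.meshgrid(xc, yc)
    src = np.tensordot(Minv, np.stack([X, Y]), axes=(1, 0))
    # spatial -> fractional pixel indices of the input grid
    fx = (src[0] - rmap.x_edges[0]) / rmap.bin_size - 0.5
    fy = (src[1] - rmap.y_edges[0]) / rmap.bin_size - 0.5
    coords = np.stack([fy, fx])
    filled = np.where(rmap.valid, rmap.rate, 0.0)
    vals = map_coordinates(filled, coords, order=1, mode="constant", cval=0.0)
    mask = map_coordinates(rmap.valid.astype(float), coords, order=1,
                           mode="constant", cval=0.0)
    out = np.where(mask > 1.0 - 1e-6, vals, np.nan)
    return RateMap(out, x_edges, y_edges, bin_size=rmap.bin_size,
                   frame=rmap.frame)


def rotate_rate_map(rmap: RateMap, rotation_cw_deg: float) -> RateMap:
    """Rotate map content clockwise about the spatial origin."""
    th = math.radians(rotation_cw_deg)
    c, s = math.cos(th), math.sin(th)
    M = np.array([[c, s], [-s, c]])  # CW rotation of content
    return resample_map(rmap, M)


def translate_rate_map(rmap: RateMap, dx: float, dy: float) -> RateMap:
    """Translate map content by (dx, dy) cm (interpolated, same grid)."""
    # out(x) = in(x - d): affine with identity linear part handled directly
    shifted = RateMap(rmap.rate, rmap.x_edges + dx, rmap.y_edges + dy,
                      bin_size=rmap.bin_size, frame=rmap.frame)
    ident = np.eye(2)
    return resample_map(shifted, ident,
                        out_extent=(rmap.x_edges[0], rmap.x_edges[-1],
                                    rmap.y_edges[0], rmap.y_edges[-1]))
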