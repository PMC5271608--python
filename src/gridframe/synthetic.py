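"""Synthetic foraging sessions with known grid/boundary ground truth.

The generator emulates the experimental setting the analysis pipeline is
built for: a rat foraging on a square platform (137 cm) inside a larger
room, with the platform rotated (20/30/45/70 deg CW) or translated by half
its side between sessions.  Grid cells are simulated as inhomogeneous
Poisson processes driven by an ideal hexagonal firing-rate lattice whose
anchoring policy (room-, platform-, or geometry-bound, with configurable
under-rotation and phase lag) determines how the lattice responds to the
manipulation.  Because every lattice parameter is known, each downstream
analysis stage can be validated by parameter recovery.

Coordinate frames: "platform" has its origin at the platform center and
axes along the platform sides; "room" is the STD camera frame (platform and
room frames coincide in STD); the "camera" frame equals the room frame for
all rotation sessions (a single room-fixed camera) and equals the platform
frame in SHIFT (a second camera centered over the shifted platform).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .angles import minimal_square_rotation
from .io import SceneConfig, Session, SessionManifest, SpikeTrain, Trajectory, Day, link_references

__all__ = [
    "GridGroundTruth",
    "MotionParams",
    "simulate_trajectory",
    "grid_rate_function",
    "boundary_rate_function",
    "generate_spikes",
    "apply_manipulation",
    "make_session",
    "make_day",
    "platform_to_room",
    "room_to_camera",
    "derive_seed",
]


def derive_seed(master: int, *keys) -> np.random.SeedSequence:
    """Stable per-stage seed derivation from one master seed."""
    ints = [int(master) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, (tuple, list)):
            ints.extend(int(v) & 0x7FFFFFFF for v in k)
        elif isinstance(k, str):
            ints.append(sum((i + 1) * b for i, b in enumerate(k.encode())) & 0x7FFFFFFF)
        else:
            ints.append(int(k) & 0x7FFFFFFF)
    return np.random.SeedSequence(ints)


def _rot_cw(deg: float) -> np.ndarray:
    """2x2 matrix rotating points clockwise by ``deg`` (x right, y up)."""
    th = math.radians(deg)
    c, s = math.cos(th), math.sin(th)
    return np.array([[c, s], [-s, c]])


def platform_to_room(scene: SceneConfig, xy: np.ndarray) -> np.ndarray:
    """Map platform-frame coordinates to room coordinates."""
    R = _rot_cw(scene.platform_rotation)
    return np.asarray(xy) @ R.T + np.asarray(scene.translation_vector)


def room_to_camera(scene: SceneConfig, xy: np.ndarray) -> np.ndarray:
    """Map room coordinates to the session's camera frame.

    Rotation sessions are captured by the room-fixed camera; SHIFT sessions
    by a second camera centered over the translated platform.
    """
    xy = np.asarray(xy)
    if scene.manipulation == "SHIFT":
        return xy - np.asarray(scene.translation_vector)
    return xy


def camera_to_room(scene: SceneConfig, xy: np.ndarray) -> np.ndarray:
    xy = np.asarray(xy)
    if scene.manipulation == "SHIFT":
        return xy + np.asarray(scene.translation_vector)
    return xy


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GridGroundTruth:
    """Parameters of one simulated grid cell, in room coordinates.

    ``scale`` is the lattice vertex spacing (cm); ``orientation`` the
    direction of one lattice axis (deg CCW from +x, meaningful mod 60);
    ``phase`` places one lattice vertex (cm).  ``anchoring`` selects which
    reference frame the lattice follows under a platform manipulation, with
    ``under_rotation`` (deg CW) and ``phase_lag`` (cm) modelling the
    systematic undershoot exerted by the competing frame.  A nonzero
    ``elliptical_index_target`` shears positions before rate evaluation to
    emulate elliptically distorted grids.
    """

    scale: float = 60.0
    orientation: float = 0.0
    phase: tuple[float, float] = (0.0, 0.0)
    peak_rate: float = 15.0
    anchoring: str = "platform"
    under_rotation: float = 0.0
    phase_lag: tuple[float, float] = (0.0, 0.0)
    elliptical_index_target: float = 0.0
    distortion_angle: float = 0.0
    model: str = "cosine"
    sharpness: float = 2.0

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("grid scale must be positive")
        if self.anchoring not in ("room", "platform", "geometry"):
            raise ValueError(f"unknown anchoring {self.anchoring!r}")
        if not (-30.0 < self.under_rotation < 30.0):
            raise ValueError("under_rotation must lie in (-30, 30) deg")
        if not (0.0 <= self.elliptical_index_target < 1.0):
            raise ValueError("elliptical_index_target must lie in [0, 1)")
        if self.model not in ("cosine", "bumps"):
            raise ValueError(f"unknown rate model {self.model!r}")
        self.phase = tuple(float(v) for v in self.phase)
        self.phase_lag = tuple(float(v) for v in self.phase_lag)


def _lattice_pattern(u: np.ndarray, scale: float, model: str, sharpness: float) -> np.ndarray:
    """Normalized (0..1) hexagonal pattern for axis-aligned lattice coords."""
    if model == "cosine":
        k = 4.0 * math.pi / (math.sqrt(3.0) * scale)
        angles = np.radians([90.0, 210.0, 330.0])
        s = np.zeros(u.shape[:-1])
        for a in angles:
            kv = k * np.array([math.cos(a), math.sin(a)])
            s += np.cos(u @ kv)
        return ((s + 1.5) / 4.5) ** sharpness
    # Gaussian bumps on the lattice, normalized to 1 at a vertex
    sigma = 0.18 * scale
    b1 = np.array([scale, 0.0])
    b2 = np.array([scale * 0.5, scale * math.sqrt(3.0) / 2.0])
    B = np.column_stack([b1, b2])
    n = u @ np.linalg.inv(B).T
    n0 = np.floor(n)
    val = np.zeros(u.shape[:-1])
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            vert = (n0 + [di, dj]) @ B.T
            d2 = np.sum((u - vert) ** 2, axis=-1)
            val += np.exp(-d2 / (2.0 * sigma**2))
    # value at an exact vertex (for peak normalization)
    ref = 1.0 + 6.0 * math.exp(-(scale**2) / (2.0 * sigma**2))
    return val / ref


def grid_rate_function(position: np.ndarray, truth: GridGroundTruth) -> np.ndarray:
    """Firing rate (Hz) of an ideal hexagonal grid at room position(s).

    The rate is a rectified, sharpened sum of three plane-wave cosines at 60
    degree separations (or, alternatively, Gaussian bumps on the lattice),
    scaled so the maximum equals ``truth.peak_rate`` at every lattice vertex
    and invariant under translation by any lattice vector.
    """
    if truth.scale <= 0:
        raise ValueError("grid scale must be positive")
    pos = np.atleast_2d(np.asarray(position, dtype=float))
    u = pos - np.asarray(truth.phase)
    if truth.elliptical_index_target > 0.0:
        # inverse of the lattice distortion: the observed lattice is the
        # ideal one compressed by (1 - e) along the distortion axis
        e = truth.elliptical_index_target
        R = _rot_cw(-truth.distortion_angle)
        E = R.T @ np.diag([1.0, 1.0 / (1.0 - e)]) @ R
        u = u @ E.T
    u = u @ _rot_cw(truth.orientation).T  # undo orientation (CCW convention)
    rate = truth.peak_rate * _lattice_pattern(u, truth.scale, truth.model, truth.sharpness)
    if np.ndim(position) == 1:
        return float(rate[0])
    return rate


def boundary_rate_function(
    position: np.ndarray,
    wall: str,
    width: float,
    peak: float,
    platform_side: float = 137.0,
) -> np.ndarray:
    """Firing rate (Hz) of a boundary cell along one platform wall.

    ``position`` is in platform coordinates; the field is at ``peak``
    within ``width`` cm of the wall and decays to ~0 toward the platform
    interior.
    """
    if width <= 0:
        raise ValueError("boundary field width must be positive")
    walls = {"N": (1, +1), "S": (1, -1), "E": (0, +1), "W": (0, -1)}
    if wall not in walls:
        raise ValueError(f"wall must be one of {sorted(walls)}")
    axis, sign = walls[wall]
    pos = np.atleast_2d(np.asarray(position, dtype=float))
    d = platform_side / 2.0 - sign * pos[:, axis]  # distance from the wall
    sigma = width / 2.0
    rate = np.where(d <= width, peak, peak * np.exp(-0.5 * ((d - width) / sigma) ** 2))
    if np.ndim(position) == 1:
        return float(rate[0])
    return rate


def apply_manipulation(
    truth: GridGroundTruth, scene_std: SceneConfig, scene_m: SceneConfig
) -> GridGroundTruth:
    """Ground truth of the manipulated session, in room coordinates.

    A room-anchored lattice is unchanged in room coordinates.  A
    platform-anchored lattice rotates and translates with the platform,
    minus the configured under-rotation and phase lag.  A geometry-anchored
    lattice follows the minimal 90-degree-congruent configuration of the
    square platform.
    """
    if scene_std.manipulation not in ("STD", "STD2"):
        raise ValueError("reference scene must be in the STD configuration")
    if scene_m.manipulation in ("STD", "STD2"):
        return replace(truth)  # standard configuration: lattice unchanged
    rho = scene_m.platform_rotation  # deg CW
    if truth.anchoring == "room":
        anchor_rot = 0.0
        anchor_t = np.zeros(2)
    elif truth.anchoring == "platform":
        anchor_rot = rho
        anchor_t = np.asarray(scene_m.translation_vector)
    else:  # geometry
        anchor_rot = minimal_square_rotation(rho)
        anchor_t = np.asarray(scene_m.translation_vector)
    eff_rot_cw = anchor_rot - truth.under_rotation
    eff_t = anchor_t - np.asarray(truth.phase_lag)
    R = _rot_cw(eff_rot_cw)
    new_phase = R @ np.asarray(truth.phase) + eff_t
    return replace(
        truth,
        orientation=truth.orientation - eff_rot_cw,  # CCW convention
        phase=(float(new_phase[0]), float(new_phase[1])),
        distortion_angle=truth.distortion_angle - eff_rot_cw,
    )


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

@dataclass
class MotionParams:
    """Foraging-motion settings for the smoothed random-walk model.

    Defaults aim at the continuous, spatially uniform sampling the
    pellet-chasing task encourages: brisk, ballistic-dominated running
    (~30 cm/s) with moderate heading diffusion and reflective walls (a
    mildly noisy billiard, whose stationary spatial distribution is close
    to uniform and mixes within a few platform crossings), plus occasional
    pauses (~3 per minute, ~1 s each) producing the immobility epochs the
    speed filter must handle.  ``steer_gain`` > 0 adds explicit steering
    toward randomly renewed waypoints.
    """

    mean_speed: float = 32.0  # cm/s
    speed_sd: float = 3.0  # cm/s, spread of per-epoch target speeds
    speed_tau: float = 0.4  # s, velocity relaxation time constant
    speed_noise: float = 0.5  # cm/s/sqrt(s), within-epoch speed jitter
    heading_sigma: float = 0.7  # rad / sqrt(s), heading diffusion
    steer_gain: float = 0.0  # 1/s, optional steering toward thrown pellets
    waypoint_radius: float = 12.0  # cm, arrival distance for waypoint renewal
    waypoint_timeout: float = 8.0  # s, resample the waypoint regardless
    epoch_mean: float = 2.0  # s, mean duration of a constant-target epoch
    pause_rate: float = 0.05  # 1/s, probability rate of entering a pause
    pause_mean: float = 1.2  # s, mean pause duration
    pause_min: float = 0.6  # s, minimum pause duration
    pause_speed: float = 0.8  # cm/s, residual jitter speed while paused
    wall_margin: float = 0.5  # cm, reflective margin inside the walls


def simulate_trajectory(
    duration: float,
    scene: SceneConfig | None = None,
    motion: MotionParams | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> Trajectory:
    """Simulate a foraging trajectory on the platform.

    The animal follows a smoothed random walk: per-epoch target speeds with
    velocity relaxation, heading diffusion, reflective walls, and explicit
    pause states (speed below the immobility threshold for >500 ms).  The
    returned trajectory is in platform coordinates, sampled at the scene's
    frame rate; identical (parameters, seed) give identical output.
    """
    if duration < 0:
        raise ValueError("duration must be nonnegative")
    scene = scene or SceneConfig()
    motion = motion or MotionParams()
    if scene.platform_side <= 0:
        raise ValueError("platform side must be positive")
    rng = np.random.default_rng(seed)
    dt = 1.0 / scene.frame_rate
    n = int(round(duration * scene.frame_rate))
    half = scene.platform_side / 2.0 - motion.wall_margin

    t = np.arange(n) * dt
    x = np.empty(n)
    y = np.empty(n)
    if n == 0:
        return Trajectory(t, x, y, frame_rate=scene.frame_rate, frame="platform")

    px = rng.uniform(-half * 0.8, half * 0.8)
    py = rng.uniform(-half * 0.8, half * 0.8)
    heading = rng.uniform(0.0, 2.0 * math.pi)
    target = max(2.0, rng.normal(motion.mean_speed, motion.speed_sd))
    speed = target
    epoch_left = rng.exponential(motion.epoch_mean)
    pause_left = 0.0
    # waypoint model of the pellet-chasing task: the animal steers toward
    # semi-random locations, renewed on arrival or after a timeout
    wx = rng.uniform(-half, half)
    wy = rng.uniform(-half, half)
    way_left = motion.waypoint_timeout
    sq_dt = math.sqrt(dt)
    normals = rng.standard_normal(2 * n)  # heading, speed noise
    uniforms = rng.random(n)
    for i in range(n):
        paused = pause_left > 0.0
        if paused:
            pause_left -= dt
            step_speed = motion.pause_speed * abs(normals[2 * i + 1])
        else:
            if uniforms[i] < motion.pause_rate * dt:
                pause_left = motion.pause_min + rng.exponential(
                    max(motion.pause_mean - motion.pause_min, 1e-6)
                )
            epoch_left -= dt
            if epoch_left <= 0.0:
                target = max(2.0, rng.normal(motion.mean_speed, motion.speed_sd))
                epoch_left = rng.exponential(motion.epoch_mean)
            if motion.steer_gain > 0.0:
                way_left -= dt
                if (way_left <= 0.0
                        or (wx - px) ** 2 + (wy - py) ** 2
                        < motion.waypoint_radius**2):
                    wx = rng.uniform(-half, half)
                    wy = rng.uniform(-half, half)
                    way_left = motion.waypoint_timeout
                desired = math.atan2(wy - py, wx - px)
                err = (desired - heading + math.pi) % (2.0 * math.pi) - math.pi
                heading += err * min(1.0, motion.steer_gain * dt)
            heading += motion.heading_sigma * sq_dt * normals[2 * i]
            speed += (target - speed) * dt / motion.speed_tau
            speed = max(0.0, speed + motion.speed_noise * sq_dt * normals[2 * i + 1])
            step_speed = speed
        px += step_speed * dt * math.cos(heading)
        py += step_speed * dt * math.sin(heading)
        # reflective walls
        if px > half:
            px = 2.0 * half - px
            heading = math.pi - heading
        elif px < -half:
            px = -2.0 * half - px
            heading = math.pi - heading
        if py > half:
            py = 2.0 * half - py
            heading = -heading
        elif py < -half:
            py = -2.0 * half - py
            heading = -heading
        x[i] = px
        y[i] = py
    return Trajectory(t, x, y, frame_rate=scene.frame_rate, frame="platform")


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def generate_spikes(
    traj: Trajectory,
    rate_fn,
    rate_max: float,
    seed: int | np.random.SeedSequence = 0,
    unit_id: tuple[int, int, int, int] = (1, 1, 1, 1),
    depth_um: float = float("nan"),
    positions: np.ndarray | None = None,
) -> SpikeTrain:
    """Inhomogeneous-Poisson spike train by thinning.

    Candidate spikes are drawn as a homogeneous Poisson process at
    ``rate_max`` over the trajectory time span and kept with probability
    rate/rate_max at the interpolated animal position.  ``positions``
    overrides the trajectory coordinates (e.g. to evaluate the rate in room
    coordinates while the trajectory is stored in another frame).
    """
    if rate_max <= 0 or not math.isfinite(rate_max):
        raise ValueError("rate_max must be positive and finite")
    if len(traj) < 2:
        return SpikeTrain(unit_id, np.empty(0), depth_um=depth_um)
    rng = np.random.default_rng(seed)
    t0, t1 = float(traj.t[0]), float(traj.t[-1])
    n_cand = rng.poisson(rate_max * (t1 - t0))
    times = np.sort(rng.uniform(t0, t1, n_cand))
    pos = traj.positions if positions is None else np.asarray(positions)
    xs = np.interp(times, traj.t, pos[:, 0])
    ys = np.interp(times, traj.t, pos[:, 1])
    rates = np.asarray(rate_fn(np.column_stack([xs, ys])), dtype=float)
    if np.any(rates < -1e-9):
        raise ValueError("rate function returned negative rates")
    if np.any(rates > rate_max * (1.0 + 1e-9)):
        raise ValueError("rate function exceeds declared rate_max")
    keep = rng.random(n_cand) < np.clip(rates, 0.0, rate_max) / rate_max
    # strictly within the span: candidates at exact endpoints are dropped
    spike_t = times[keep]
    spike_t = spike_t[(spike_t > t0) & (spike_t < t1)]
    return SpikeTrain(unit_id, spike_t, depth_um=depth_um)


# ---------------------------------------------------------------------------
# sessions and days
# ---------------------------------------------------------------------------

@dataclass
class UnitSpec:
    """One simulated unit: a grid, boundary, or spatially uniform cell."""

    unit_id: tuple[int, int, int, int]
    kind: str = "grid"  # grid | boundary | uniform
    truth: GridGroundTruth | None = None
    wall: str = "N"
    width: float = 12.0
    peak: float = 10.0
    rate: float = 3.0  # uniform cells
    depth_um: float = float("nan")

    def __post_init__(self):
        if self.kind not in ("grid", "boundary", "uniform", "degraded_grid"):
            raise ValueError(f"unknown unit kind {self.kind!r}")
        if self.kind in ("grid", "degraded_grid") and self.truth is None:
            self.truth = GridGroundTruth()


def make_session(
    scene: SceneConfig,
    units: list[UnitSpec],
    duration: float,
    seed: int = 0,
    motion: MotionParams | None = None,
    session_id: str = "s1",
    order_in_day: int = 0,
    scene_std: SceneConfig | None = None,
    camera_error: tuple[float, float, float] | None = None,
) -> Session:
    """Simulate one session: trajectory plus one spike train per unit.

    Grid-cell rates are evaluated in room coordinates after applying the
    unit's anchoring policy to the manipulation; boundary cells are
    evaluated in platform coordinates (they track the platform geometry).
    The stored trajectory is in the session's camera frame; if
    ``camera_error`` is given, that rigid offset is injected into the
    stored data and its exact inverse recorded as the manifest's
    camera correction.
    """
    scene_std = scene_std or SceneConfig(
        platform_side=scene.platform_side, room_size=scene.room_size,
        frame_rate=scene.frame_rate,
    )
    traj_platform = simulate_trajectory(
        duration, scene, motion, seed=derive_seed(seed, session_id, "traj")
    )
    pos_room = platform_to_room(scene, traj_platform.positions)
    pos_camera = room_to_camera(scene, pos_room)

    trains = []
    for k, u in enumerate(units):
        sseq = derive_seed(seed, session_id, "spikes", u.unit_id)
        if u.kind == "degraded_grid" and scene.manipulation == "ROT70":
            # multi-field but non-hexagonal firing: Gaussian bumps at
            # strongly jittered lattice positions (fixed per unit)
            jrng = np.random.default_rng(derive_seed(seed, "degrade", u.unit_id))
            half = scene.platform_side / 2.0
            n_bumps = max(4, int((scene.platform_side / u.truth.scale) ** 2 * 1.3))
            centers = jrng.uniform(-half, half, size=(n_bumps, 2))
            sigma = 0.18 * u.truth.scale
            peak = u.truth.peak_rate

            def fn(p, c=centers, s=sigma, pk=peak):
                p2 = np.atleast_2d(p)
                d2 = np.sum((p2[:, None, :] - c[None, :, :]) ** 2, axis=-1)
                return pk * np.clip(np.exp(-d2 / (2 * s**2)).sum(axis=1), 0, 1)

            st = generate_spikes(traj_platform, fn, u.truth.peak_rate, sseq,
                                 unit_id=u.unit_id, depth_um=u.depth_um,
                                 positions=pos_room)
        elif u.kind in ("grid", "degraded_grid"):
            truth_m = apply_manipulation(u.truth, scene_std, scene)
            fn = lambda p, tr=truth_m: grid_rate_function(p, tr)
            st = generate_spikes(traj_platform, fn, truth_m.peak_rate, sseq,
                                 unit_id=u.unit_id, depth_um=u.depth_um,
                                 positions=pos_room)
        elif u.kind == "boundary":
            fn = lambda p, uu=u: boundary_rate_function(
                p, uu.wall, uu.width, uu.peak, platform_side=scene.platform_side
            )
            st = generate_spikes(traj_platform, fn, u.peak, sseq,
                                 unit_id=u.unit_id, depth_um=u.depth_um,
                                 positions=traj_platform.positions)
        else:
            fn = lambda p, uu=u: np.full(np.atleast_2d(p).shape[0], uu.rate)
            st = generate_spikes(traj_platform, fn, u.rate, sseq,
                                 unit_id=u.unit_id, depth_um=u.depth_um)
        trains.append(st)

    traj_camera = Trajectory(traj_platform.t, pos_camera[:, 0], pos_camera[:, 1],
                             frame_rate=scene.frame_rate, frame="camera")
    correction = (0.0, 0.0, 0.0)
    if camera_error is not None:
        from .io import apply_camera_correction, invert_camera_correction

        traj_camera = apply_camera_correction(traj_camera, camera_error)
        correction = invert_camera_correction(camera_error)
    manifest = SessionManifest(
        session_id=session_id,
        scene=scene,
        camera_correction=correction,
        duration=duration,
        order_in_day=order_in_day,
        extra={"seed": int(seed)},
    )
    return Session(manifest, traj_camera, trains)


def make_day(
    manipulations: list[str],
    units: list[UnitSpec],
    duration: float = 1200.0,
    seed: int = 0,
    motion: MotionParams | None = None,
    scene_kwargs: dict | None = None,
) -> Day:
    """Simulate a full experiment day (an STD-first sequence of sessions)."""
    scene_kwargs = scene_kwargs or {}
    sessions = []
    for i, manip in enumerate(manipulations):
        scene = SceneConfig(manipulation=manip, **scene_kwargs)
        scene_std = SceneConfig(manipulation="STD", **scene_kwargs)
        sessions.append(
            make_session(
                scene, units, duration, seed=seed, motion=motion,
                session_id=f"s{i + 1}_{manip}", order_in_day=i,
                scene_std=scene_std,
            )
        )
    return link_references(Day(sessions))
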