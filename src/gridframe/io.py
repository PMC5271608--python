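"""Session I/O: tracking, spike trains, manifests, and day assembly.

All coordinate data are carried in cm in a declared frame (camera, platform
or room).  The origin is the platform center in the standard (STD) camera
frame, x rightward, y upward; rotations are positive clockwise, matching the
reporting convention of the analysis modules.

File formats are deliberately plain: delimited text (CSV) with header rows
for tracking and spikes, YAML for session manifests, dense numeric grids
with NaN missing-value markers for rate maps.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "ConfigurationError",
    "SceneConfig",
    "Trajectory",
    "SpikeTrain",
    "SessionManifest",
    "Session",
    "Day",
    "MANIPULATION_ROTATIONS",
    "STD_LIKE",
    "read_tracking",
    "write_tracking",
    "read_spikes",
    "write_spikes",
    "read_units",
    "write_units",
    "read_manifest",
    "write_manifest",
    "apply_camera_correction",
    "load_day",
    "write_rate_map_grid",
    "read_rate_map_grid",
]


class FormatError(ValueError):
    """A data file violates the expected format."""


class ConfigurationError(ValueError):
    """A session/day configuration is inconsistent."""


#: Physical platform rotation (deg CW) implied by each manipulation label.
MANIPULATION_ROTATIONS = {
    "STD": 0.0,
    "STD2": 0.0,
    "ROT20": 20.0,
    "ROT30": 30.0,
    "ROT45": 45.0,
    "ROT70": 70.0,
    "SHIFT": 0.0,
}

#: Sessions in the standard platform configuration (usable as references).
STD_LIKE = ("STD", "STD2")


@dataclass
class SceneConfig:
    """Geometry of room, platform and the manipulation applied to it.

    The platform is a square of side ``platform_side`` cm sitting in a room
    of ``room_size`` cm.  ``platform_rotation`` is the physical rotation of
    the platform (deg, CW positive) and ``translation_vector`` its
    translation in room coordinates; for the SHIFT manipulation the
    translation magnitude is half the platform side along +x (the room's
    longer axis).
    """

    platform_side: float = 137.0
    room_size: tuple[float, float] = (355.0, 280.0)
    manipulation: str = "STD"
    platform_rotation: float | None = None
    translation_vector: tuple[float, float] | None = None
    frame_rate: float = 30.0

    def __post_init__(self):
        if self.manipulation not in MANIPULATION_ROTATIONS:
            raise ConfigurationError(f"unknown manipulation {self.manipulation!r}")
        if self.platform_rotation is None:
            self.platform_rotation = MANIPULATION_ROTATIONS[self.manipulation]
        if self.translation_vector is None:
            if self.manipulation == "SHIFT":
                self.translation_vector = (self.platform_side / 2.0, 0.0)
            else:
                self.translation_vector = (0.0, 0.0)
        self.translation_vector = tuple(float(v) for v in self.translation_vector)
        expected_rot = MANIPULATION_ROTATIONS[self.manipulation]
        if not math.isclose(self.platform_rotation, expected_rot, abs_tol=1e-9):
            raise ConfigurationError(
                f"{self.manipulation} implies a {expected_rot} deg rotation, "
                f"got {self.platform_rotation}"
            )
        if self.manipulation == "SHIFT":
            mag = math.hypot(*self.translation_vector)
            if not math.isclose(mag, self.platform_side / 2.0, rel_tol=1e-9):
                raise ConfigurationError(
                    "SHIFT translation magnitude must equal platform_side/2"
                )
        half_diag = self.platform_side * math.sqrt(2.0) / 2.0
        tx, ty = self.translation_vector
        if (abs(tx) + half_diag > self.room_size[0] / 2.0) or (
            abs(ty) + half_diag > self.room_size[1] / 2.0
        ):
            raise ConfigurationError("platform does not fit in the room")

    @property
    def shift_magnitude(self) -> float:
        return math.hypot(*self.translation_vector)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["room_size"] = list(self.room_size)
        d["translation_vector"] = list(self.translation_vector)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        if "room_size" in d:
            d["room_size"] = tuple(d["room_size"])
        if "translation_vector" in d and d["translation_vector"] is not None:
            d["translation_vector"] = tuple(d["translation_vector"])
        return cls(**d)


@dataclass
class Trajectory:
    """Timestamped 2-D path of the animal, cm, in a declared frame."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate: float = 30.0
    frame: str = "camera"

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise FormatError("t, x, y must have equal length")
        if self.t.size and not np.all(np.diff(self.t) > 0):
            raise FormatError("timestamps must be strictly increasing")
        if self.t.size and not (
            np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))
        ):
            raise FormatError("coordinates must be finite")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class SpikeTrain:
    """Spike timestamps of one unit.

    ``unit_id`` follows the (rat, day, tetrode, cluster) naming convention;
    ``depth_um`` is the estimated recording depth along the tetrode track.
    """

    unit_id: tuple[int, int, int, int]
    spike_times: np.ndarray
    depth_um: float = float("nan")

    def __post_init__(self):
        self.unit_id = tuple(int(v) for v in self.unit_id)
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size and np.any(np.diff(self.spike_times) < 0):
            self.spike_times = np.sort(self.spike_times)

    @property
    def label(self) -> str:
        r, d, t, c = self.unit_id
        return f"r{r}d{d}t{t}c{c}"

    def __len__(self) -> int:
        return self.spike_times.size


@dataclass
class SessionManifest:
    """Descriptor of one recording session."""

    session_id: str
    scene: SceneConfig
    camera_id: str = "cam0"
    camera_correction: tuple[float, float, float] = (0.0, 0.0, 0.0)
    duration: float = 0.0
    order_in_day: int = 0
    tracking_file: str | None = None
    spikes_file: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.camera_correction = tuple(float(v) for v in self.camera_correction)
        if not all(math.isfinite(v) for v in self.camera_correction):
            raise ConfigurationError("camera correction must be finite")

    @property
    def manipulation(self) -> str:
        return self.scene.manipulation

    def to_dict(self) -> dict:
        return {
            "session_id": self.session_id,
            "scene": self.scene.to_dict(),
            "camera_id": self.camera_id,
            "camera_correction": list(self.camera_correction),
            "duration": float(self.duration),
            "order_in_day": int(self.order_in_day),
            "tracking_file": self.tracking_file,
            "spikes_file": self.spikes_file,
            "extra": dict(self.extra),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionManifest":
        d = dict(d)
        d["scene"] = SceneConfig.from_dict(d["scene"])
        if "camera_correction" in d:
            d["camera_correction"] = tuple(d["camera_correction"])
        return cls(**d)


@dataclass
class Session:
    """A session manifest together with its tracking and spike data."""

    manifest: SessionManifest
    trajectory: Trajectory
    spike_trains: list[SpikeTrain] = field(default_factory=list)
    reference: "Session | None" = None  # most recent prior STD-configuration

    @property
    def manipulation(self) -> str:
        return self.manifest.manipulation

    def spike_train(self, unit_id) -> SpikeTrain:
        unit_id = tuple(int(v) for v in unit_id)
        for st in self.spike_trains:
            if st.unit_id == unit_id:
                return st
        raise KeyError(f"unit {unit_id} not in session {self.manifest.session_id}")


@dataclass
class Day:
    """Ordered sessions of one experiment day."""

    sessions: list[Session]

    def __iter__(self):
        return iter(self.sessions)

    def __len__(self):
        return len(self.sessions)

    @property
    def unit_ids(self) -> list[tuple[int, int, int, int]]:
        seen: dict = {}
        for s in self.sessions:
            for st in s.spike_trains:
                seen.setdefault(st.unit_id, None)
        return list(seen)


# ---------------------------------------------------------------------------
# tracking / spikes / units tables
# ---------------------------------------------------------------------------

def write_tracking(traj: Trajectory, path) -> None:
    df = pd.DataFrame({"t": traj.t, "x": traj.x, "y": traj.y})
    df.to_csv(path, index=False, float_format="%.6f")


def read_tracking(path, frame_rate: float = 30.0, frame: str = "camera") -> Trajectory:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - delegated parsing
        raise FormatError(str(exc)) from exc
    missing = {"t", "x", "y"} - set(df.columns)
    if missing:
        raise FormatError(f"tracking file missing columns: {sorted(missing)}")
    return Trajectory(
        df["t"].to_numpy(), df["x"].to_numpy(), df["y"].to_numpy(),
        frame_rate=frame_rate, frame=frame,
    )


def write_spikes(trains: Sequence[SpikeTrain], path) -> None:
    rows = []
    for st in trains:
        for t in st.spike_times:
            rows.append((st.label, t))
    df = pd.DataFrame(rows, columns=["unit_id", "t"])
    df.to_csv(path, index=False, float_format="%.6f")


def _parse_unit_label(label: str) -> tuple[int, int, int, int]:
    import re

    m = re.fullmatch(r"r(\d+)d(\d+)t(\d+)c(\d+)", label)
    if not m:
        raise FormatError(f"bad unit id {label!r}")
    return tuple(int(g) for g in m.groups())


def read_spikes(path, units_meta: pd.DataFrame | None = None) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    missing = {"unit_id", "t"} - set(df.columns)
    if missing:
        raise FormatError(f"spikes file missing columns: {sorted(missing)}")
    depth_by_unit: dict = {}
    if units_meta is not None:
        for _, row in units_meta.iterrows():
            key = (int(row["rat"]), int(row["day"]), int(row["tetrode"]),
                   int(row["cluster"]))
            depth_by_unit[key] = float(row.get("depth_um", float("nan")))
    trains = []
    for label, grp in df.groupby("unit_id", sort=True):
        uid = _parse_unit_label(str(label))
        trains.append(
            SpikeTrain(uid, np.sort(grp["t"].to_numpy()),
                       depth_um=depth_by_unit.get(uid, float("nan")))
        )
    return trains


def write_units(units: pd.DataFrame, path) -> None:
    cols = ["rat", "day", "tetrode", "cluster", "depth_um"]
    units.loc[:, [c for c in cols if c in units.columns]].to_csv(path, index=False)


def read_units(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"rat", "day", "tetrode", "cluster"} - set(df.columns)
    if missing:
        raise FormatError(f"units file missing columns: {sorted(missing)}")
    return df


def write_manifest(manifest: SessionManifest, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest.to_dict(), fh, sort_keys=False)


def read_manifest(path) -> SessionManifest:
    with open(path) as fh:
        return SessionManifest.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# coordinate corrections and day assembly
# ---------------------------------------------------------------------------

def apply_camera_correction(
    traj: Trajectory, correction: tuple[float, float, float]
) -> Trajectory:
    """Apply a rigid (rotation deg CW, dx cm, dy cm) camera correction.

    The correction rotates the tracked positions clockwise about the origin
    and then translates them.  The identity correction is a no-op.
    """
    rot_cw, dx, dy = (float(v) for v in correction)
    if not all(math.isfinite(v) for v in (rot_cw, dx, dy)):
        raise ValueError("camera correction must be finite")
    theta = -math.radians(rot_cw)  # CW positive -> negative CCW angle
    c, s = math.cos(theta), math.sin(theta)
    x = c * traj.x - s * traj.y + dx
    y = s * traj.x + c * traj.y + dy
    return Trajectory(traj.t.copy(), x, y, frame_rate=traj.frame_rate,
                      frame=traj.frame)


def invert_camera_correction(
    correction: tuple[float, float, float]
) -> tuple[float, float, float]:
    """Rigid inverse such that applying both recovers the input exactly."""
    rot_cw, dx, dy = (float(v) for v in correction)
    theta = math.radians(rot_cw)  # inverse rotation is CCW by the same angle
    c, s = math.cos(theta), math.sin(theta)
    # inverse: rotate by -rot, translate by -R(-rot)^{-1} d
    return (-rot_cw, -(c * dx - s * dy), -(s * dx + c * dy))


def load_day(
    manifests: Sequence[SessionManifest],
    base_dir=None,
    units_meta: pd.DataFrame | None = None,
) -> Day:
    """Assemble a Day from session manifests, attaching data and references.

    Sessions are ordered by ``order_in_day``.  Every manipulated session is
    paired with the most recent prior session run in the standard platform
    configuration (STD or a repeated STD2), which serves as its reference
    for rotation/phase measurements.
    """
    if not manifests:
        raise ConfigurationError("no sessions in day")
    manifests = sorted(manifests, key=lambda m: m.order_in_day)
    if manifests[0].manipulation not in STD_LIKE:
        raise ConfigurationError("day must begin with an STD session")
    base = Path(base_dir) if base_dir is not None else None
    sessions: list[Session] = []
    last_std: Session | None = None
    for m in manifests:
        if m.tracking_file is None or m.spikes_file is None:
            raise ConfigurationError(
                f"session {m.session_id} has no data files attached"
            )
        tpath = (base / m.tracking_file) if base else Path(m.tracking_file)
        spath = (base / m.spikes_file) if base else Path(m.spikes_file)
        traj = read_tracking(tpath, frame_rate=m.scene.frame_rate)
        trains = read_spikes(spath, units_meta=units_meta)
        sess = Session(m, traj, trains)
        if sessions and last_std is None:
            raise ConfigurationError("manipulated session precedes any STD")
        if sessions:
            sess.reference = last_std
        sessions.append(sess)
        if m.manipulation in STD_LIKE:
            last_std = sess
    return Day(sessions)


def link_references(day: Day) -> Day:
    """(Re)attach the most recent prior STD-configuration reference."""
    last_std: Session | None = None
    for sess in day.sessions:
        sess.reference = last_std if sess is not day.sessions[0] else None
        if sess.manipulation in STD_LIKE:
            last_std = sess
    if day.sessions and day.sessions[0].manipulation not in STD_LIKE:
        raise ConfigurationError("day must begin with an STD session")
    return day


# ---------------------------------------------------------------------------
# day directories
# ---------------------------------------------------------------------------

def units_table(day: Day) -> pd.DataFrame:
    """Units metadata (rat, day, tetrode, cluster, depth_um) for a day."""
    rows = {}
    for sess in day.sessions:
        for st in sess.spike_trains:
            rows.setdefault(st.unit_id, st.depth_um)
    return pd.DataFrame(
        [(r, d, t, c, depth) for (r, d, t, c), depth in rows.items()],
        columns=["rat", "day", "tetrode", "cluster", "depth_um"],
    )


def write_day(day: Day, out_dir) -> Path:
    """Persist a day as a directory of CSV/YAML files.

    Layout: ``day.yaml`` (ordered list of manifest files), one manifest +
    tracking + spikes CSV per session, and ``units.csv`` metadata.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_files = []
    for sess in day.sessions:
        m = sess.manifest
        stem = f"{m.order_in_day:02d}_{m.session_id}"
        m.tracking_file = f"{stem}_tracking.csv"
        m.spikes_file = f"{stem}_spikes.csv"
        write_tracking(sess.trajectory, out / m.tracking_file)
        write_spikes(sess.spike_trains, out / m.spikes_file)
        mf = f"{stem}_manifest.yaml"
        write_manifest(m, out / mf)
        manifest_files.append(mf)
    write_units(units_table(day), out / "units.csv")
    with open(out / "day.yaml", "w") as fh:
        yaml.safe_dump({"manifests": manifest_files}, fh)
    return out


def read_day(day_dir) -> Day:
    """Load a day previously written by :func:`write_day`."""
    base = Path(day_dir)
    with open(base / "day.yaml") as fh:
        index = yaml.safe_load(fh)
    manifests = [read_manifest(base / mf) for mf in index["manifests"]]
    units = read_units(base / "units.csv") if (base / "units.csv").exists() else None
    return load_day(manifests, base_dir=base, units_meta=units)


# ---------------------------------------------------------------------------
# dense grids (rate maps / correlograms)
# ---------------------------------------------------------------------------

def write_rate_map_grid(values: np.ndarray, path) -> None:
    """Serialize a dense 2-D grid with NaN missing-value markers."""
    np.savetxt(path, np.asarray(values, dtype=float), fmt="%.8g", delimiter=",")


def read_rate_map_grid(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))
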