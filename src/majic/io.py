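"""File round-tripping and run configuration.

CSV schemas
-----------
IMU stream (one file per sensor, header mandatory)::

    time_s,gyro_x,gyro_y,gyro_z,accel_x,accel_y,accel_z,mag_x,mag_y,mag_z

Orientation series::

    time_s,q_w,q_x,q_y,q_z,frame_from,frame_to

Observability trace::

    time_s,o_J,o_K,o_joint,mag_used

Numeric values are written with 9 significant digits, which round-trips
bit-stably at the stated precision.

The run configuration is a YAML mapping with flat scalar keys plus a
``sensors`` list of flat per-sensor entries (``file, segment, joint,
r_x, r_y, r_z``).  Unknown keys are rejected with the offending key and
line; applied defaults are logged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .filters import DEFAULT_THRESHOLD, NoiseConfig
from .series import OrientationSeries
from .virtual_sensor import ImuStream, SensorMount

__all__ = [
    "IMU_COLUMNS",
    "RunConfig",
    "SensorEntry",
    "load_run_config",
    "save_run_config",
    "read_imu_csv",
    "write_imu_csv",
    "read_orientation_csv",
    "write_orientation_csv",
    "write_observability_csv",
    "write_manifest",
]

logger = logging.getLogger("majic")

IMU_COLUMNS = [
    "time_s",
    "gyro_x", "gyro_y", "gyro_z",
    "accel_x", "accel_y", "accel_z",
    "mag_x", "mag_y", "mag_z",
]
_FLOAT_FMT = "%.9g"


# ---------------------------------------------------------------------------
# CSV round-tripping
# ---------------------------------------------------------------------------

def read_imu_csv(path: str | Path) -> ImuStream:
    """Read one sensor stream; strictly increasing time is enforced."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) and not np.all(np.diff(t) > 0):
        row = int(np.argmax(np.diff(t) <= 0)) + 3  # 1-based, +1 header, offending sample
        raise ValueError(f"{path}: time_s not strictly increasing at row {row}")
    return ImuStream(
        time=t,
        gyro=df[["gyro_x", "gyro_y", "gyro_z"]].to_numpy(dtype=float),
        accel=df[["accel_x", "accel_y", "accel_z"]].to_numpy(dtype=float),
        mag=df[["mag_x", "mag_y", "mag_z"]].to_numpy(dtype=float),
    )


def write_imu_csv(stream: ImuStream, path: str | Path) -> None:
    df = pd.DataFrame(
        np.column_stack([stream.time, stream.gyro, stream.accel, stream.mag]),
        columns=IMU_COLUMNS,
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_orientation_csv(path: str | Path) -> OrientationSeries:
    path = Path(path)
    df = pd.read_csv(path)
    needed = ["time_s", "q_w", "q_x", "q_y", "q_z", "frame_from", "frame_to"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        return OrientationSeries(np.zeros(0), np.zeros((0, 4)), "", "")
    frames = df[["frame_from", "frame_to"]].drop_duplicates()
    if len(frames) > 1:
        raise ValueError(f"{path}: inconsistent frame labels")
    quat = df[["q_w", "q_x", "q_y", "q_z"]].to_numpy(dtype=float)
    quat = quat / np.linalg.norm(quat, axis=1, keepdims=True)
    return OrientationSeries(
        time=df["time_s"].to_numpy(dtype=float),
        quat=quat,
        frame_from=str(df["frame_from"].iloc[0]),
        frame_to=str(df["frame_to"].iloc[0]),
    )


def write_orientation_csv(series: OrientationSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        np.column_stack([series.time, series.quat]),
        columns=["time_s", "q_w", "q_x", "q_y", "q_z"],
    )
    df["frame_from"] = series.frame_from
    df["frame_to"] = series.frame_to
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_observability_csv(trace, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "o_J": trace.o_J,
            "o_K": trace.o_K,
            "o_joint": trace.o_joint,
            "mag_used": trace.mag_used.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class SensorEntry:
    """One sensor file with its mount (offset sensor -> joint center)."""

    file: str
    segment: str
    joint: str
    r_x: float = 0.0
    r_y: float = 0.0
    r_z: float = 0.0

    def mount(self) -> SensorMount:
        return SensorMount(self.segment, self.joint, np.array([self.r_x, self.r_y, self.r_z]))


@dataclass
class RunConfig:
    """Validated configuration for one filter run."""

    sensors: list[SensorEntry]
    method: str = "majic"
    threshold: float = DEFAULT_THRESHOLD
    smooth_cutoff: float = 10.0
    seed: int = 0
    output_dir: str = "out"
    gyro_noise: float = 0.005
    accel_noise: float = 0.5
    mag_noise: float = 0.05
    init_std_deg: float = 5.0

    def noise(self) -> NoiseConfig:
        return NoiseConfig(
            gyro_noise=self.gyro_noise,
            accel_noise=self.accel_noise,
            mag_noise=self.mag_noise,
            init_std=np.deg2rad(self.init_std_deg),
        )

    def validate(self, base_dir: Path | None = None) -> None:
        if self.method not in ("ekf", "magoff", "magon", "majic"):
            raise ValueError(f"config key 'method': unknown method {self.method!r}")
        if not self.threshold >= 0:
            raise ValueError("config key 'threshold': must be >= 0")
        if len(self.sensors) != 2:
            raise ValueError(
                f"config key 'sensors': need exactly 2 entries (one per segment), "
                f"got {len(self.sensors)}"
            )
        for entry in self.sensors:
            p = Path(entry.file)
            if base_dir is not None and not p.is_absolute():
                p = base_dir / p
            if not p.exists():
                raise ValueError(f"config key 'sensors.file': {p} does not exist")


_SCALAR_KEYS = {
    "method": str, "threshold": float, "smooth_cutoff": float, "seed": int,
    "output_dir": str, "gyro_noise": float, "accel_noise": float,
    "mag_noise": float, "init_std_deg": float,
}
_SENSOR_KEYS = {"file": str, "segment": str, "joint": str,
                "r_x": float, "r_y": float, "r_z": float}


def _key_lines(path: Path) -> dict[str, int]:
    """Best-effort 1-based line numbers of top-level and sensor keys."""
    lines = {}
    try:
        node = yaml.compose(path.read_text())
    except yaml.YAMLError:
        return lines
    if node is None or not hasattr(node, "value"):
        return lines

    def walk(n):
        if isinstance(n, yaml.MappingNode):
            for k, v in n.value:
                lines.setdefault(k.value, k.start_mark.line + 1)
                walk(v)
        elif isinstance(n, yaml.SequenceNode):
            for item in n.value:
                walk(item)

    walk(node)
    return lines


def load_run_config(path: str | Path, check_files: bool = True) -> RunConfig:
    """Load and validate a run configuration; applied defaults are logged."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"run config {path} does not exist")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: run config must be a mapping")
    key_lines = _key_lines(path)

    def _fail(key: str, msg: str):
        line = key_lines.get(key)
        where = f"{path}:{line}" if line else str(path)
        raise ValueError(f"{where}: config key {key!r} {msg}")

    kwargs = {}
    for key, val in raw.items():
        if key == "sensors":
            continue
        if key not in _SCALAR_KEYS:
            _fail(key, "is not a recognized key")
        try:
            kwargs[key] = _SCALAR_KEYS[key](val)
        except (TypeError, ValueError):
            _fail(key, f"has invalid value {val!r}")
    sensors = []
    for i, entry in enumerate(raw.get("sensors", [])):
        if not isinstance(entry, dict):
            _fail("sensors", f"entry {i} must be a mapping")
        ekwargs = {}
        for k, v in entry.items():
            if k not in _SENSOR_KEYS:
                _fail(k, f"is not recognized in sensors entry {i}")
            try:
                ekwargs[k] = _SENSOR_KEYS[k](v)
            except (TypeError, ValueError):
                _fail(k, f"has invalid value {v!r} in sensors entry {i}")
        for req in ("file", "segment", "joint"):
            if req not in ekwargs:
                _fail("sensors", f"entry {i} is missing required key {req!r}")
        sensors.append(SensorEntry(**ekwargs))

    for key, default in (
        ("method", "majic"), ("threshold", DEFAULT_THRESHOLD), ("seed", 0),
    ):
        if key not in kwargs:
            logger.info("config %s: applying default %s = %r", path, key, default)
    cfg = RunConfig(sensors=sensors, **kwargs)
    try:
        cfg.validate(base_dir=path.parent if check_files else None)
    except ValueError as exc:
        # re-raise with the key's line when we know it
        msg = str(exc)
        for key, line in key_lines.items():
            if f"'{key}'" in msg:
                raise ValueError(f"{path}:{line}: {msg}") from exc
        raise
    if check_files:
        cfg.sensors = [
            SensorEntry(
                file=str((path.parent / e.file) if not Path(e.file).is_absolute() else e.file),
                segment=e.segment, joint=e.joint, r_x=e.r_x, r_y=e.r_y, r_z=e.r_z,
            )
            for e in cfg.sensors
        ]
    return cfg


def _plain(cfg: RunConfig) -> dict:
    """Config as builtin scalars (YAML/JSON-safe)."""
    data = {k: _SCALAR_KEYS[k](getattr(cfg, k)) for k in _SCALAR_KEYS}
    data["sensors"] = [
        {k: _SENSOR_KEYS[k](getattr(e, k)) for k in _SENSOR_KEYS}
        for e in cfg.sensors
    ]
    return data


def save_run_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_plain(cfg), sort_keys=False))


def config_hash(cfg: RunConfig) -> str:
    data = _plain(cfg)
    return hashlib.sha256(
        json.dumps(data, sort_keys=True).encode()
    ).hexdigest()[:16]


def write_manifest(path: str | Path, **entries) -> None:
    """Machine-readable record (JSON) sufficient to reproduce a run."""
    import scipy

    from . import __version__

    manifest = {
        "majic_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        **entries,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
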