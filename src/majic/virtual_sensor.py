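"""Project physical IMU readings to a virtual sensor at the joint center.

A sensor rigidly mounted on a segment at a known offset ``r`` from the joint
center measures a specific force ``a`` that differs from the specific force
at the joint center by the rotational terms of rigid-body dynamics:

    a_hat = a + alpha x r + omega x (omega x r)

with ``omega`` the measured angular velocity and ``alpha`` its time
derivative, all expressed in the sensor frame.  For the magnetic field the
gradient across the joint is assumed negligible, so the virtual field equals
the raw reading, ``b_hat = b``.

Specific-force convention: accelerometers output ``f = R^T (a_world + g_up)``
with world z-up and ``g_up = [0, 0, 9.81] m/s^2``; a stationary level sensor
reads ``[0, 0, 9.81]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "ImuSample",
    "ImuStream",
    "SensorMount",
    "VirtualReading",
    "angular_acceleration",
    "joint_center_acceleration",
    "joint_center_field",
    "project_stream",
    "lowpass",
    "GRAVITY",
    "G_UP",
]

GRAVITY = 9.81
G_UP = np.array([0.0, 0.0, GRAVITY])


class ImuSample(NamedTuple):
    """One timestamped gyro/accel/mag triple for one sensor (sensor frame)."""

    time: float          # s
    gyro: np.ndarray     # rad/s
    accel: np.ndarray    # m/s^2, specific force
    mag: np.ndarray      # arbitrary consistent field units


@dataclass
class ImuStream:
    """Array-backed stream of IMU samples for one sensor.

    ``time`` is strictly increasing; all arrays are finite with matching
    lengths.
    """

    time: np.ndarray     # (N,)
    gyro: np.ndarray     # (N, 3)
    accel: np.ndarray    # (N, 3)
    mag: np.ndarray      # (N, 3)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.mag = np.asarray(self.mag, dtype=float)
        n = len(self.time)
        for name in ("gyro", "accel", "mag"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3), got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if n and not np.all(np.diff(self.time) > 0):
            bad = int(np.argmax(np.diff(self.time) <= 0)) + 1
            raise ValueError(f"time must be strictly increasing (violated at row {bad})")

    def __len__(self) -> int:
        return len(self.time)

    def __iter__(self):
        for i in range(len(self)):
            yield ImuSample(self.time[i], self.gyro[i], self.accel[i], self.mag[i])

    @classmethod
    def from_samples(cls, samples: Iterable[ImuSample]) -> "ImuStream":
        samples = list(samples)
        return cls(
            time=np.array([s.time for s in samples], dtype=float),
            gyro=np.array([s.gyro for s in samples], dtype=float),
            accel=np.array([s.accel for s in samples], dtype=float),
            mag=np.array([s.mag for s in samples], dtype=float),
        )

    @property
    def rate(self) -> float:
        """Mean sample rate in Hz."""
        if len(self) < 2:
            raise ValueError("need at least 2 samples to infer a rate")
        return (len(self) - 1) / (self.time[-1] - self.time[0])


@dataclass
class SensorMount:
    """Ties a physical sensor to a segment and a joint center.

    ``r`` points from the sensor origin to the joint center, in meters,
    expressed in the sensor frame.  Human limb offsets are well under a
    meter; larger values indicate a unit error.
    """

    segment: str
    joint: str
    r: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.shape != (3,) or not np.all(np.isfinite(self.r)):
            raise ValueError("mount offset r must be a finite 3-vector")
        if np.linalg.norm(self.r) >= 1.0:
            raise ValueError(
                f"mount offset ||r|| = {np.linalg.norm(self.r):.3f} m >= 1 m; "
                "offsets are sensor->joint-center distances on a human limb"
            )


@dataclass
class VirtualReading:
    """Virtual sensor reading at the joint center, in the sensor frame."""

    time: float
    a_hat: np.ndarray   # m/s^2
    b_hat: np.ndarray   # field units
    segment: str


def lowpass(x: np.ndarray, fs: float, cutoff: float, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth low-pass along axis 0; identity if cutoff is None/0."""
    if cutoff is None or cutoff <= 0 or cutoff >= fs / 2:
        return np.asarray(x, dtype=float)
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=0)


def _central_diff(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Derivative along axis 0: central differences, one-sided at the ends."""
    return np.gradient(x, t, axis=0)


def angular_acceleration(
    gyro_series: Sequence | np.ndarray,
    time: np.ndarray | None = None,
    smooth_cutoff: float | None = 10.0,
) -> np.ndarray:
    """Per-sample angular acceleration from a gyro stream, rad/s^2.

    Central differences (one-sided at the ends) after optional zero-phase
    low-pass smoothing of the gyro stream.  ``gyro_series`` may be a
    sequence of ``(time, omega)`` pairs or an (N, 3) array with ``time``
    given separately.
    """
    if time is None:
        pairs = list(gyro_series)
        time = np.array([p[0] for p in pairs], dtype=float)
        gyro = np.array([p[1] for p in pairs], dtype=float)
    else:
        time = np.asarray(time, dtype=float)
        gyro = np.asarray(gyro_series, dtype=float)
    if len(time) < 3:
        raise ValueError("angular acceleration needs at least 3 samples")
    if not np.all(np.diff(time) > 0):
        raise ValueError("time must be strictly increasing")
    fs = (len(time) - 1) / (time[-1] - time[0])
    smoothed = lowpass(gyro, fs, smooth_cutoff)
    return _central_diff(smoothed, time)


def joint_center_acceleration(
    a: np.ndarray, omega: np.ndarray, alpha: np.ndarray, r: np.ndarray
) -> np.ndarray:
    """Specific force at the joint center: ``a + alpha x r + omega x (omega x r)``.

    All quantities in the sensor frame.  Vectorized over leading axes.
    """
    a = np.asarray(a, dtype=float)
    omega = np.asarray(omega, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    r = np.asarray(r, dtype=float)
    for name, arr in (("a", a), ("omega", omega), ("alpha", alpha), ("r", r)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} contains non-finite values")
    return a + np.cross(alpha, r) + np.cross(omega, np.cross(omega, r))


def joint_center_field(b: np.ndarray, mount: SensorMount | None = None) -> np.ndarray:
    """Magnetic field at the joint center.

    The field gradient across the joint is assumed negligible, so the
    projection is the identity regardless of the mount offset.  Unit
    normalization, where wanted, is applied downstream.
    """
    b = np.asarray(b, dtype=float)
    if not np.all(np.isfinite(b)):
        raise ValueError("b contains non-finite values")
    return b


def project_stream(
    samples: ImuStream | Iterable[ImuSample],
    mount: SensorMount,
    smooth_cutoff: float | None = 10.0,
    alpha: np.ndarray | None = None,
) -> list[VirtualReading]:
    """Project a sensor stream to virtual readings at the joint center.

    ``alpha`` overrides the numerically differentiated angular acceleration
    (e.g. with simulator ground truth); otherwise central differences on the
    optionally smoothed gyro stream are used.
    """
    stream = samples if isinstance(samples, ImuStream) else ImuStream.from_samples(samples)
    if alpha is None:
        alpha = angular_acceleration(stream.gyro, stream.time, smooth_cutoff)
    else:
        alpha = np.asarray(alpha, dtype=float)
        if alpha.shape != stream.gyro.shape:
            raise ValueError("alpha must match the gyro stream shape")
    a_hat = joint_center_acceleration(stream.accel, stream.gyro, alpha, mount.r)
    b_hat = joint_center_field(stream.mag, mount)
    return [
        VirtualReading(stream.time[i], a_hat[i], b_hat[i], mount.segment)
        for i in range(len(stream))
    ]


def project_arrays(
    stream: ImuStream,
    mount: SensorMount,
    smooth_cutoff: float | None = 10.0,
    alpha: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Array form of :func:`project_stream`: ``(a_hat (N,3), b_hat (N,3))``."""
    if alpha is None:
        alpha = angular_acceleration(stream.gyro, stream.time, smooth_cutoff)
    a_hat = joint_center_acceleration(stream.accel, stream.gyro, alpha, mount.r)
    b_hat = joint_center_field(stream.mag, mount)
    return a_hat, b_hat
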