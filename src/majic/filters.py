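"""Error-state Kalman filters for segment orientations from IMU streams.

The core is a *relative* error-state filter that directly estimates the
orientation between two segments J and K joined by a ball joint.  Its state
holds nominal orientations ``R_WJ``, ``R_WK`` and a 6x6 covariance of the
stacked small-angle errors ``[eta_J; eta_K]``, with the true orientation
modeled as ``R = R_nominal exp([eta x])``.

Prediction integrates the gyroscopes.  The update exploits that the
acceleration (and, when used, the magnetic field) projected to the shared
joint center must coincide once rotated into a common frame:

    h = R_WJ y_J - R_WK y_K  ~  0     per virtual sensor y

This implicit measurement constrains four of the six error degrees of
freedom with acceleration alone; the relative rotation about the joint
center acceleration axis stays unobservable and drifts.  A scalar
observability

    o = || a_hat x (d a_hat/dt + omega x a_hat) ||_2        [m^2/s^5]

measures how well the acceleration history disambiguates the rotation; the
per-joint value is the minimum over the two segments.  Three relative
variants share the same machinery and differ only in when the joint-center
magnetic field enters the update:

* ``magoff`` — never (magnetometer-free; drifts when o is low),
* ``magon``  — always (sensitive to field differences across the joint),
* ``majic``  — adaptively, whenever o drops below a threshold
  (default 150 m^2/s^5).

A conventional per-segment global EKF (gravity + magnetic-north references)
is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

from . import rotations
from .rotations import exp_map, skew
from .series import OrientationSeries
from .virtual_sensor import (
    G_UP,
    ImuStream,
    SensorMount,
    angular_acceleration,
    joint_center_acceleration,
    joint_center_field,
    lowpass,
)

__all__ = [
    "DEFAULT_THRESHOLD",
    "NoiseConfig",
    "RelativeFilterState",
    "ObservabilityTrace",
    "FilterOutput",
    "predict",
    "measurement_residual",
    "measurement_jacobian",
    "kalman_gain",
    "update",
    "observability",
    "gate_sensors",
    "run_relative_filter",
    "run_global_ekf",
    "triad",
]

DEFAULT_THRESHOLD = 150.0  # m^2/s^5; observability below this gates the mag on
_METHODS = ("magoff", "magon", "majic")


@dataclass(frozen=True)
class NoiseConfig:
    """Noise magnitudes for the filters.

    Parameters
    ----------
    gyro_noise : float
        Gyroscope white-noise density, rad/s/sqrt(Hz), applied per segment.
    accel_noise : float
        Accelerometer measurement noise sigma_a, m/s^2 (per sensor; it also
        absorbs rigid-body projection and differentiation error).
    mag_noise : float
        Magnetometer noise sigma_b applied to the unit-normalized field.
    init_std : float
        Initial orientation uncertainty sigma_0, rad.

    Defaults are typical MEMS-grade values.
    """

    gyro_noise: float = 0.005
    accel_noise: float = 0.5
    mag_noise: float = 0.05
    init_std: float = np.deg2rad(5.0)

    def __post_init__(self) -> None:
        for name in ("gyro_noise", "accel_noise", "mag_noise", "init_std"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class RelativeFilterState:
    """Nominal orientation pair and stacked error covariance."""

    R_WJ: np.ndarray                 # (3, 3)
    R_WK: np.ndarray                 # (3, 3)
    P: np.ndarray                    # (6, 6), rad^2
    t: float = 0.0

    def validate(self) -> None:
        if not rotations.is_rotation(self.R_WJ, 1e-6) or not rotations.is_rotation(
            self.R_WK, 1e-6
        ):
            raise ValueError("nominal orientations left SO(3)")
        if not np.allclose(self.P, self.P.T, atol=1e-9):
            raise ValueError("covariance P is not symmetric")
        if np.linalg.eigvalsh((self.P + self.P.T) / 2).min() < -1e-12:
            raise ValueError("covariance P is not positive semidefinite")


@dataclass
class ObservabilityTrace:
    """Per-timestep observability and the resulting magnetometer gating."""

    time: np.ndarray        # (N,)
    o_J: np.ndarray         # (N,) m^2/s^5
    o_K: np.ndarray         # (N,)
    mag_used: np.ndarray    # (N,) bool

    @property
    def o_joint(self) -> np.ndarray:
        """Joint observability: per-sample minimum over the two segments."""
        return np.minimum(self.o_J, self.o_K)


class FilterOutput(NamedTuple):
    """Result of one relative-filter run."""

    orientations: OrientationSeries          # R_JK, frame J -> K
    observability: ObservabilityTrace
    global_J: OrientationSeries              # nominal world->J (gauge-dependent)
    global_K: OrientationSeries
    P_trace: np.ndarray                      # (N,) trace of error covariance


# ---------------------------------------------------------------------------
# core steps
# ---------------------------------------------------------------------------

def predict(
    state: RelativeFilterState,
    gyro_J: np.ndarray,
    gyro_K: np.ndarray,
    dt: float,
    noise: NoiseConfig,
) -> RelativeFilterState:
    """Gyro integration step with first-order error-covariance propagation."""
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    gyro_J = np.asarray(gyro_J, dtype=float)
    gyro_K = np.asarray(gyro_K, dtype=float)
    dR_J = exp_map(gyro_J * dt)
    dR_K = exp_map(gyro_K * dt)
    # right-multiplied error transforms as eta+ = dR^T eta under R <- R dR
    F = np.zeros((6, 6))
    F[:3, :3] = dR_J.T
    F[3:, 3:] = dR_K.T
    q = noise.gyro_noise**2 * dt
    P = F @ state.P @ F.T + q * np.eye(6)
    return RelativeFilterState(
        R_WJ=state.R_WJ @ dR_J,
        R_WK=state.R_WK @ dR_K,
        P=(P + P.T) / 2,
        t=state.t + dt,
    )


def _stack(vectors: Sequence[np.ndarray]) -> list[np.ndarray]:
    out = [np.asarray(v, dtype=float) for v in vectors]
    for v in out:
        if v.shape != (3,):
            raise ValueError("each reading must be a 3-vector")
    return out


def measurement_residual(
    state: RelativeFilterState,
    y_J: Sequence[np.ndarray],
    y_K: Sequence[np.ndarray],
) -> np.ndarray:
    """Stacked implicit-measurement residual ``h = R_WJ y_J - R_WK y_K``.

    Zero exactly when both segments map their joint-center readings to the
    same world vector.
    """
    y_J, y_K = _stack(y_J), _stack(y_K)
    if len(y_J) != len(y_K) or len(y_J) == 0:
        raise ValueError(
            f"need equal nonzero sensor counts, got {len(y_J)} and {len(y_K)}"
        )
    return np.concatenate(
        [state.R_WJ @ yj - state.R_WK @ yk for yj, yk in zip(y_J, y_K)]
    )


def measurement_jacobian(
    state: RelativeFilterState,
    y_J: Sequence[np.ndarray],
    y_K: Sequence[np.ndarray],
) -> np.ndarray:
    """Jacobian of :func:`measurement_residual` w.r.t. ``[eta_J; eta_K]``.

    Row block n is ``[-R_WJ [y_nJ x], +R_WK [y_nK x]]``; the sign convention
    is fixed by agreement with central finite differences of the residual
    under ``R <- R exp([eta x])`` perturbations.
    """
    y_J, y_K = _stack(y_J), _stack(y_K)
    if len(y_J) != len(y_K) or len(y_J) == 0:
        raise ValueError(
            f"need equal nonzero sensor counts, got {len(y_J)} and {len(y_K)}"
        )
    H = np.zeros((3 * len(y_J), 6))
    for n, (yj, yk) in enumerate(zip(y_J, y_K)):
        H[3 * n : 3 * n + 3, :3] = -state.R_WJ @ skew(yj)
        H[3 * n : 3 * n + 3, 3:] = state.R_WK @ skew(yk)
    return H


def kalman_gain(P: np.ndarray, H: np.ndarray, Rm: np.ndarray) -> np.ndarray:
    """``K = P H^T (H P H^T + Rm)^{-1}`` via a linear solve."""
    P = np.asarray(P, dtype=float)
    H = np.asarray(H, dtype=float)
    Rm = np.asarray(Rm, dtype=float)
    S = H @ P @ H.T + Rm
    S = (S + S.T) / 2
    try:
        K_T = np.linalg.solve(S, H @ P.T)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "innovation covariance H P H^T + Rm is singular"
        ) from exc
    return K_T.T


def update(
    state: RelativeFilterState,
    residual: np.ndarray,
    H: np.ndarray,
    Rm: np.ndarray,
) -> RelativeFilterState:
    """Error-state correction and Joseph-form covariance update.

    The correction is ``eta = -K h`` (the implicit measurement targets
    ``h = 0``, so the innovation is ``-h``); ``eta`` is injected with the
    exact exponential map and reset to zero.
    """
    K = kalman_gain(state.P, H, Rm)
    eta = -K @ np.asarray(residual, dtype=float)
    IKH = np.eye(6) - K @ H
    P = IKH @ state.P @ IKH.T + K @ Rm @ K.T
    P = (P + P.T) / 2
    new = RelativeFilterState(
        R_WJ=rotations.orthonormalize(state.R_WJ @ exp_map(eta[:3])),
        R_WK=rotations.orthonormalize(state.R_WK @ exp_map(eta[3:])),
        P=P,
        t=state.t,
    )
    if np.linalg.eigvalsh(P).min() < -1e-9:
        raise ValueError("covariance lost positive semidefiniteness in update")
    return new


def observability(
    a_hat: np.ndarray,
    gyro: np.ndarray,
    time: np.ndarray,
    smooth_cutoff: float | None = None,
) -> np.ndarray:
    """Acceleration observability ``o = ||a x (da/dt + w x a)||`` per sample.

    All quantities in the local segment frame; ``da/dt`` by central
    differences (one-sided at the ends).  ``smooth_cutoff`` optionally
    low-passes ``a_hat`` first (zero-phase).
    """
    a_hat = np.asarray(a_hat, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    time = np.asarray(time, dtype=float)
    if len(time) < 3:
        raise ValueError("observability needs at least 3 samples")
    if smooth_cutoff:
        fs = (len(time) - 1) / (time[-1] - time[0])
        a_hat = lowpass(a_hat, fs, smooth_cutoff)
    da = np.gradient(a_hat, time, axis=0)
    return np.linalg.norm(np.cross(a_hat, da + np.cross(gyro, a_hat)), axis=1)


def gate_sensors(o_joint: float, threshold: float = DEFAULT_THRESHOLD) -> frozenset:
    """Sensor set for the adaptive update: mag joins when o drops below threshold."""
    if o_joint < 0:
        raise ValueError("observability must be nonnegative")
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    return frozenset({"accel", "mag"}) if o_joint < threshold else frozenset({"accel"})


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def triad(accel: np.ndarray, mag: np.ndarray) -> np.ndarray:
    """World-from-sensor rotation from one accel (tilt) + mag (heading) pair.

    The accel direction defines world up; the horizontal component of the
    field defines world +x.  If the field is (near-)parallel to the accel,
    an arbitrary horizontal axis is substituted.
    """
    up = np.asarray(accel, dtype=float)
    n = np.linalg.norm(up)
    if n == 0:
        raise ValueError("cannot initialize tilt from a zero accelerometer reading")
    up = up / n
    m = np.asarray(mag, dtype=float)
    horiz = m - (m @ up) * up
    if np.linalg.norm(horiz) < 1e-8:
        horiz = np.array([1.0, 0.0, 0.0]) - up[0] * up
        if np.linalg.norm(horiz) < 1e-8:
            horiz = np.array([0.0, 1.0, 0.0]) - up[1] * up
    x = horiz / np.linalg.norm(horiz)
    y = np.cross(up, x)
    return np.vstack([x, y, up])  # rows = world basis in sensor coords


# ---------------------------------------------------------------------------
# filter runners
# ---------------------------------------------------------------------------

def _check_aligned(t_J: np.ndarray, t_K: np.ndarray) -> None:
    if len(t_J) != len(t_K):
        raise ValueError(f"streams differ in length: {len(t_J)} vs {len(t_K)}")
    if len(t_J) < 3:
        raise ValueError("streams must contain at least 3 samples")
    dt = np.median(np.diff(t_J))
    if np.max(np.abs(t_J - t_K)) > dt / 10:
        raise ValueError(
            "stream timestamps are misaligned beyond dt/10; resample explicitly"
        )


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 1e-12 else v


def _mag_usage(
    method: str,
    o_joint: np.ndarray,
    threshold: float,
    hysteresis: float,
) -> np.ndarray:
    if method == "magoff":
        return np.zeros(len(o_joint), dtype=bool)
    if method == "magon":
        return np.ones(len(o_joint), dtype=bool)
    if hysteresis <= 0:
        return o_joint < threshold
    lo, hi = threshold - hysteresis / 2, threshold + hysteresis / 2
    used = np.zeros(len(o_joint), dtype=bool)
    on = bool(o_joint[0] < threshold)
    for i, o in enumerate(o_joint):
        if on and o > hi:
            on = False
        elif not on and o < lo:
            on = True
        used[i] = on
    return used


def run_relative_filter(
    stream_J: ImuStream,
    stream_K: ImuStream,
    mount_J: SensorMount,
    mount_K: SensorMount,
    noise: NoiseConfig | None = None,
    method: str = "majic",
    threshold: float = DEFAULT_THRESHOLD,
    smooth_cutoff: float | None = 10.0,
    hysteresis: float = 0.0,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    alpha_J: np.ndarray | None = None,
    alpha_K: np.ndarray | None = None,
) -> FilterOutput:
    """Run one relative filter (``magoff`` | ``magon`` | ``majic``) over a pair
    of time-aligned streams.

    Per timestep: gyro predict (trapezoidal angular rate), rigid-body
    projection to the joint center, sensor-set selection, implicit update,
    and emission of ``R_JK``.  ``init`` optionally supplies the initial
    world orientations (e.g. ground truth in tests); otherwise both are
    initialized from the first accel + mag sample.  ``alpha_*`` optionally
    replace the differentiated angular accelerations with known values.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}, got {method!r}")
    noise = noise or NoiseConfig()
    _check_aligned(stream_J.time, stream_K.time)
    t = stream_J.time
    N = len(t)

    def _project(stream: ImuStream, mount: SensorMount, alpha):
        if alpha is None:
            alpha = angular_acceleration(stream.gyro, stream.time, smooth_cutoff)
        a_hat = joint_center_acceleration(stream.accel, stream.gyro, alpha, mount.r)
        b_hat = joint_center_field(stream.mag, mount)
        return a_hat, b_hat

    a_J, b_J = _project(stream_J, mount_J, alpha_J)
    a_K, b_K = _project(stream_K, mount_K, alpha_K)

    o_J = observability(a_J, stream_J.gyro, t, smooth_cutoff)
    o_K = observability(a_K, stream_K.gyro, t, smooth_cutoff)
    o_joint = np.minimum(o_J, o_K)
    mag_used = _mag_usage(method, o_joint, threshold, hysteresis)

    if init is not None:
        R_WJ, R_WK = np.asarray(init[0], dtype=float), np.asarray(init[1], dtype=float)
    else:
        R_WJ = triad(stream_J.accel[0], stream_J.mag[0])
        R_WK = triad(stream_K.accel[0], stream_K.mag[0])
    state = RelativeFilterState(
        R_WJ=R_WJ, R_WK=R_WK, P=noise.init_std**2 * np.eye(6), t=float(t[0])
    )

    Rm_accel = 2.0 * noise.accel_noise**2 * np.eye(3)
    Rm_mag = 2.0 * noise.mag_noise**2 * np.eye(3)

    rel = np.empty((N, 3, 3))
    glob_J = np.empty((N, 3, 3))
    glob_K = np.empty((N, 3, 3))
    P_trace = np.empty(N)
    for k in range(N):
        if k > 0:
            dt = float(t[k] - t[k - 1])
            w_J = 0.5 * (stream_J.gyro[k - 1] + stream_J.gyro[k])
            w_K = 0.5 * (stream_K.gyro[k - 1] + stream_K.gyro[k])
            state = predict(state, w_J, w_K, dt, noise)
        y_J, y_K = [a_J[k]], [a_K[k]]
        blocks = [Rm_accel]
        if mag_used[k]:
            bj, bk = _unit(b_J[k]), _unit(b_K[k])
            y_J.append(bj)
            y_K.append(bk)
            blocks.append(Rm_mag)
        h = measurement_residual(state, y_J, y_K)
        H = measurement_jacobian(state, y_J, y_K)
        Rm = np.zeros((3 * len(blocks), 3 * len(blocks)))
        for i, blk in enumerate(blocks):
            Rm[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = blk
        state = update(state, h, H, Rm)
        rel[k] = rotations.relative(state.R_WJ, state.R_WK)
        glob_J[k] = state.R_WJ
        glob_K[k] = state.R_WK
        P_trace[k] = np.trace(state.P)

    return FilterOutput(
        orientations=OrientationSeries.from_matrices(
            t, rel, mount_J.segment, mount_K.segment
        ),
        observability=ObservabilityTrace(t, o_J, o_K, mag_used),
        global_J=OrientationSeries.from_matrices(t, glob_J, "world", mount_J.segment),
        global_K=OrientationSeries.from_matrices(t, glob_K, "world", mount_K.segment),
        P_trace=P_trace,
    )


def run_global_ekf(
    stream: ImuStream,
    noise: NoiseConfig | None = None,
    segment: str = "segment",
    mag_ref: np.ndarray | None = None,
    static_window: float = 2.0,
) -> OrientationSeries:
    """Traditional per-segment global orientation EKF.

    Gyro predict; update assuming the accelerometer measures gravity and the
    magnetometer measures a fixed world field.  The world field direction is
    estimated from an initial static window (mean reading rotated by the
    initial tilt/heading estimate) unless ``mag_ref`` is given explicitly.
    Relative joint series are obtained by combining two global series with
    :func:`majic.rotations.relative`.
    """
    noise = noise or NoiseConfig()
    t = stream.time
    if len(t) < 3:
        raise ValueError("stream must contain at least 3 samples")

    if mag_ref is None:
        in_window = t <= t[0] + static_window
        if in_window.sum() < 2:
            raise ValueError(
                "no static window available to estimate the world magnetic field; "
                "pass mag_ref explicitly"
            )
        a0 = stream.accel[in_window].mean(axis=0)
        m0 = stream.mag[in_window].mean(axis=0)
        R0 = triad(a0, m0)
        mag_ref = _unit(R0 @ m0)
    else:
        mag_ref = _unit(np.asarray(mag_ref, dtype=float))
        R0 = triad(stream.accel[0], stream.mag[0])

    R = R0
    P = noise.init_std**2 * np.eye(3)
    Rm = np.zeros((6, 6))
    Rm[:3, :3] = noise.accel_noise**2 * np.eye(3)
    Rm[3:, 3:] = noise.mag_noise**2 * np.eye(3)

    out = np.empty((len(t), 3, 3))
    for k in range(len(t)):
        if k > 0:
            dt = float(t[k] - t[k - 1])
            w = 0.5 * (stream.gyro[k - 1] + stream.gyro[k])
            dR = exp_map(w * dt)
            R = R @ dR
            F = dR.T
            P = F @ P @ F.T + noise.gyro_noise**2 * dt * np.eye(3)
            P = (P + P.T) / 2
        # predicted readings: gravity and world field rotated into the sensor
        pred_a = R.T @ G_UP
        pred_m = R.T @ mag_ref
        nu = np.concatenate(
            [stream.accel[k] - pred_a, _unit(stream.mag[k]) - pred_m]
        )
        H = np.vstack([skew(pred_a), skew(pred_m)])
        K = kalman_gain(P, H, Rm)
        eta = K @ nu
        R = rotations.orthonormalize(R @ exp_map(eta))
        IKH = np.eye(3) - K @ H
        P = IKH @ P @ IKH.T + K @ Rm @ K.T
        P = (P + P.T) / 2
        out[k] = R

    return OrientationSeries.from_matrices(t, out, "world", segment)
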