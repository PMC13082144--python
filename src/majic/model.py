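"""Model/Results interface over the orientation filters.

``RelativeOrientationKF`` is built from a pair of time-aligned IMU streams
and their joint-center mounts; ``fit()`` runs the selected filter and
returns a :class:`RelativeFilterResults` carrying the estimated relative
orientation series, the observability trace, covariance diagnostics and a
``summary()`` table.  ``GlobalOrientationEKF`` is the per-segment global
counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import evaluation, filters, rotations
from .filters import DEFAULT_THRESHOLD, FilterOutput, NoiseConfig
from .series import OrientationSeries
from .virtual_sensor import ImuStream, SensorMount

__all__ = [
    "RelativeOrientationKF",
    "GlobalOrientationEKF",
    "RelativeFilterResults",
    "GlobalFilterResults",
]


def _stream_from_frame(df: pd.DataFrame) -> ImuStream:
    from .io import IMU_COLUMNS

    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataframe missing column(s) {missing}")
    return ImuStream(
        time=df["time_s"].to_numpy(dtype=float),
        gyro=df[["gyro_x", "gyro_y", "gyro_z"]].to_numpy(dtype=float),
        accel=df[["accel_x", "accel_y", "accel_z"]].to_numpy(dtype=float),
        mag=df[["mag_x", "mag_y", "mag_z"]].to_numpy(dtype=float),
    )


class RelativeOrientationKF:
    """Relative-orientation error-state Kalman filter for one joint.

    Parameters
    ----------
    stream_J, stream_K : ImuStream
        Time-aligned streams from the proximal (J) and distal (K) segment.
    mount_J, mount_K : SensorMount
        Sensor-to-joint-center offsets for the shared joint.
    method : {"magoff", "magon", "majic"}
        When the joint-center magnetic field enters the update.
    threshold : float
        Observability gate in m^2/s^5 (``majic`` only); default 150.
    noise : NoiseConfig, optional
    smooth_cutoff : float or None
        Zero-phase low-pass cutoff (Hz) for gyro differentiation and the
        observability acceleration stream.
    hysteresis : float
        Width of an optional gating hysteresis band; 0 = plain threshold.
    """

    def __init__(
        self,
        stream_J: ImuStream,
        stream_K: ImuStream,
        mount_J: SensorMount,
        mount_K: SensorMount,
        method: str = "majic",
        threshold: float = DEFAULT_THRESHOLD,
        noise: NoiseConfig | None = None,
        smooth_cutoff: float | None = 10.0,
        hysteresis: float = 0.0,
    ):
        if mount_J.joint != mount_K.joint:
            raise ValueError(
                f"mounts refer to different joints: {mount_J.joint!r} vs {mount_K.joint!r}"
            )
        self.stream_J, self.stream_K = stream_J, stream_K
        self.mount_J, self.mount_K = mount_J, mount_K
        self.method = method
        self.threshold = threshold
        self.noise = noise or NoiseConfig()
        self.smooth_cutoff = smooth_cutoff
        self.hysteresis = hysteresis

    @classmethod
    def from_dataframes(
        cls,
        df_J: pd.DataFrame,
        df_K: pd.DataFrame,
        mount_J: SensorMount,
        mount_K: SensorMount,
        **kwargs,
    ) -> "RelativeOrientationKF":
        """Build from dataframes using the IMU CSV column schema."""
        return cls(
            _stream_from_frame(df_J), _stream_from_frame(df_K),
            mount_J, mount_K, **kwargs,
        )

    def fit(
        self,
        init: tuple[np.ndarray, np.ndarray] | None = None,
        alpha_J: np.ndarray | None = None,
        alpha_K: np.ndarray | None = None,
    ) -> "RelativeFilterResults":
        out = filters.run_relative_filter(
            self.stream_J, self.stream_K, self.mount_J, self.mount_K,
            noise=self.noise, method=self.method, threshold=self.threshold,
            smooth_cutoff=self.smooth_cutoff, hysteresis=self.hysteresis,
            init=init, alpha_J=alpha_J, alpha_K=alpha_K,
        )
        return RelativeFilterResults(self, out)


@dataclass
class RelativeFilterResults:
    """Estimates, uncertainties and diagnostics from one relative-filter fit."""

    model: RelativeOrientationKF
    _output: FilterOutput

    @property
    def orientations(self) -> OrientationSeries:
        """Estimated relative orientation R_JK per timestep."""
        return self._output.orientations

    @property
    def observability(self):
        return self._output.observability

    @property
    def P_trace(self) -> np.ndarray:
        """Trace of the 6x6 error covariance per timestep, rad^2."""
        return self._output.P_trace

    @property
    def orientation_std_deg(self) -> np.ndarray:
        """RMS one-sigma orientation uncertainty per timestep, degrees."""
        return np.degrees(np.sqrt(self._output.P_trace / 6.0))

    @property
    def mag_usage(self) -> float:
        """Fraction of timesteps in which the magnetometer entered the update."""
        return float(self._output.observability.mag_used.mean())

    def angle_axis_deg(self) -> np.ndarray:
        """(N, 3) relative joint angle-axis components, degrees."""
        return np.degrees(self.orientations.angle_axis())

    def rmse_vs(self, reference: OrientationSeries) -> float:
        """Total 3D angle RMSE against a reference series, degrees."""
        return evaluation.rmse_angle(self.orientations, reference)

    def pearson_vs(self, reference: OrientationSeries) -> tuple[float, float, float]:
        return evaluation.pearson_by_axis(self.orientations, reference)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-timestep results table."""
        aa = self.angle_axis_deg()
        obs = self.observability
        return pd.DataFrame(
            {
                "time_s": self.orientations.time,
                "angle_x_deg": aa[:, 0],
                "angle_y_deg": aa[:, 1],
                "angle_z_deg": aa[:, 2],
                "o_joint": obs.o_joint,
                "mag_used": obs.mag_used,
                "sigma_deg": self.orientation_std_deg,
            }
        )

    def summary(self) -> str:
        t = self.orientations.time
        obs = self.observability
        lines = [
            "Relative Orientation Kalman Filter Results",
            "=" * 46,
            f"joint:                 {self.model.mount_J.joint}",
            f"segments:              {self.model.mount_J.segment} -> {self.model.mount_K.segment}",
            f"method:                {self.model.method}",
            f"threshold [m^2/s^5]:   {self.model.threshold:g}",
            f"samples:               {len(t)}",
            f"duration [s]:          {t[-1] - t[0]:.2f}",
            f"magnetometer usage:    {100 * self.mag_usage:.1f}% of updates",
            f"median o_joint:        {np.median(obs.o_joint):.1f} m^2/s^5",
            f"final sigma [deg]:     {self.orientation_std_deg[-1]:.3f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot(self, reference: OrientationSeries | None = None, ax=None):
        """Joint angle-axis components (and observability) over time."""
        import matplotlib.pyplot as plt

        if ax is None:
            fig, (ax, ax2) = plt.subplots(
                2, 1, sharex=True, figsize=(9, 6),
                gridspec_kw={"height_ratios": [2, 1]},
            )
        else:
            fig, ax2 = ax.figure, None
        t = self.orientations.time
        aa = self.angle_axis_deg()
        for i, lbl in enumerate("xyz"):
            ax.plot(t, aa[:, i], label=f"est {lbl}")
        if reference is not None:
            ref = np.degrees(reference.angle_axis())
            for i, lbl in enumerate("xyz"):
                ax.plot(t, ref[:, i], "--", label=f"ref {lbl}")
        ax.set_ylabel("angle-axis [deg]")
        ax.legend(ncol=3, fontsize=8)
        if ax2 is not None:
            obs = self.observability
            ax2.semilogy(t, np.maximum(obs.o_joint, 1e-3), label="o_joint")
            ax2.axhline(self.model.threshold, color="r", ls=":", label="threshold")
            ax2.set_xlabel("time [s]")
            ax2.set_ylabel("observability")
            ax2.legend(fontsize=8)
        return fig


class GlobalOrientationEKF:
    """Traditional per-segment global orientation EKF (gravity + world field)."""

    def __init__(
        self,
        stream: ImuStream,
        segment: str = "segment",
        noise: NoiseConfig | None = None,
        mag_ref: np.ndarray | None = None,
        static_window: float = 2.0,
    ):
        self.stream = stream
        self.segment = segment
        self.noise = noise or NoiseConfig()
        self.mag_ref = mag_ref
        self.static_window = static_window

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "GlobalOrientationEKF":
        return cls(_stream_from_frame(df), **kwargs)

    def fit(self) -> "GlobalFilterResults":
        series = filters.run_global_ekf(
            self.stream, noise=self.noise, segment=self.segment,
            mag_ref=self.mag_ref, static_window=self.static_window,
        )
        return GlobalFilterResults(self, series)


@dataclass
class GlobalFilterResults:
    model: GlobalOrientationEKF
    orientations: OrientationSeries

    def relative_to(self, other: "GlobalFilterResults") -> OrientationSeries:
        """Relative series between this (proximal) and another (distal) fit."""
        RJ = self.orientations.as_matrices()
        RK = other.orientations.as_matrices()
        rel = np.einsum("nij,nik->njk", RJ, RK)
        return OrientationSeries.from_matrices(
            self.orientations.time, rel,
            self.orientations.frame_to, other.orientations.frame_to,
        )

    def summary(self) -> str:
        t = self.orientations.time
        return "\n".join(
            [
                "Global Orientation EKF Results",
                "=" * 40,
                f"segment:      {self.model.segment}",
                f"samples:      {len(t)}",
                f"duration [s]: {t[-1] - t[0]:.2f}",
                "=" * 40,
            ]
        )
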