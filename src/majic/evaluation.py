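"""Accuracy metrics for estimated vs. reference relative-orientation series.

The error of a sample is the magnitude of the angle-axis vector of
``R_ref^T R_est`` — a total 3D orientation error rather than separate
anatomical-plane angles.  Agreement of waveform shape is summarized by the
Pearson correlation between estimated and reference angle-axis components,
per component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import rotations
from .series import OrientationSeries

__all__ = [
    "MetricReport",
    "angle_errors",
    "rmse_angle",
    "pearson_by_axis",
    "report",
    "summarize",
    "align_heading",
]


@dataclass
class MetricReport:
    """Per (joint, method) accuracy summary."""

    joint: str
    method: str
    rmse_deg: float
    r_axis: tuple[float, float, float]
    n_samples: int

    def as_row(self) -> dict:
        return {
            "joint": self.joint,
            "method": self.method,
            "rmse_deg": self.rmse_deg,
            "r_axis1": self.r_axis[0],
            "r_axis2": self.r_axis[1],
            "r_axis3": self.r_axis[2],
            "n_samples": self.n_samples,
        }


def _check_pair(est: OrientationSeries, ref: OrientationSeries) -> None:
    if len(est) != len(ref):
        raise ValueError(f"series lengths differ: {len(est)} vs {len(ref)}")
    if len(est) == 0:
        raise ValueError("cannot score empty series")
    if (est.frame_from, est.frame_to) != (ref.frame_from, ref.frame_to):
        raise ValueError(
            f"frame mismatch: ({est.frame_from}->{est.frame_to}) vs "
            f"({ref.frame_from}->{ref.frame_to})"
        )
    if not np.allclose(est.time, ref.time, atol=1e-9):
        raise ValueError("series timestamps do not match")


def angle_errors(est: OrientationSeries, ref: OrientationSeries) -> np.ndarray:
    """Per-sample total 3D angle error, radians."""
    _check_pair(est, ref)
    E, R = est.as_matrices(), ref.as_matrices()
    return np.array(
        [np.linalg.norm(rotations.angle_axis(rotations.relative(r, e)))
         for e, r in zip(E, R)]
    )


def rmse_angle(est: OrientationSeries, ref: OrientationSeries) -> float:
    """Root-mean-square of the per-sample angle error, degrees."""
    theta = angle_errors(est, ref)
    return float(np.degrees(np.sqrt(np.mean(theta**2))))


def pearson_by_axis(
    est: OrientationSeries, ref: OrientationSeries
) -> tuple[float, float, float]:
    """Pearson r between est and ref angle-axis components, per component."""
    _check_pair(est, ref)
    a_est, a_ref = est.angle_axis(), ref.angle_axis()
    out = []
    for i, label in enumerate("xyz"):
        x, y = a_est[:, i], a_ref[:, i]
        if np.std(x) < 1e-15 or np.std(y) < 1e-15:
            raise ValueError(
                f"correlation undefined for angle-axis column {label!r}: "
                "zero variance"
            )
        out.append(float(stats.pearsonr(x, y).statistic))
    return tuple(out)


def align_heading(
    est: OrientationSeries, ref: OrientationSeries, window: float = 2.0
) -> OrientationSeries:
    """Left-apply the constant rotation minimizing the mean error over the
    first ``window`` seconds (optional pre-alignment; OFF by default in all
    reporting paths)."""
    _check_pair(est, ref)
    sel = est.time <= est.time[0] + window
    E, R = est.as_matrices()[sel], ref.as_matrices()[sel]
    # orthogonal Procrustes on stacked rotations: argmin_L sum ||L E_i - R_i||
    M = sum(r @ e.T for e, r in zip(E, R))
    L = rotations.orthonormalize(M)
    aligned = np.einsum("ij,njk->nik", L, est.as_matrices())
    return OrientationSeries.from_matrices(
        est.time, aligned, est.frame_from, est.frame_to
    )


def report(
    joint: str, method: str, est: OrientationSeries, ref: OrientationSeries
) -> MetricReport:
    """Score one estimated series against its reference."""
    return MetricReport(
        joint=joint,
        method=method,
        rmse_deg=rmse_angle(est, ref),
        r_axis=pearson_by_axis(est, ref),
        n_samples=len(est),
    )


def summarize(reports: list[MetricReport]) -> pd.DataFrame:
    """Median RMSE per method and per (method, joint) as a tidy table.

    Rows with ``joint == "(all)"`` pool every report for the method.
    """
    if not reports:
        raise ValueError("summarize needs at least one report")
    df = pd.DataFrame([r.as_row() for r in reports])
    rows = []
    for method, grp in df.groupby("method", sort=True):
        rows.append(
            {"method": method, "joint": "(all)",
             "median_rmse_deg": float(grp["rmse_deg"].median())}
        )
        for joint, jgrp in grp.groupby("joint", sort=True):
            rows.append(
                {"method": method, "joint": joint,
                 "median_rmse_deg": float(jgrp["rmse_deg"].median())}
            )
    return pd.DataFrame(rows)
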