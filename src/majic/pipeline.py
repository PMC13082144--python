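"""End-to-end helpers: simulated scenario -> filters -> metrics.

These glue functions resolve which sensors flank each joint, run any of the
four methods, rotate sensor-frame estimates into segment frames using the
known sensor mounting rotations (sensor-to-segment alignment is taken as
known, as when it comes from calibration), and score them against the
simulator's ground truth.
"""

from __future__ import annotations

import numpy as np

from . import evaluation
from .evaluation import MetricReport
from .filters import DEFAULT_THRESHOLD, NoiseConfig
from .model import GlobalOrientationEKF, RelativeOrientationKF, RelativeFilterResults
from .series import OrientationSeries
from .synthetic import SimulationResult

__all__ = ["joint_sensor_pair", "fit_joint", "score_scenario", "METHODS"]

METHODS = ("ekf", "magoff", "magon", "majic")


def joint_sensor_pair(sim: SimulationResult, joint: str) -> tuple[str, str]:
    """Names of the (proximal, distal) sensors flanking a joint."""
    rel = sim.truth_relative[joint]
    parent, child = rel.frame_from, rel.frame_to
    by_segment = {}
    for name, seg in sim.sensor_segment.items():
        by_segment.setdefault(seg, name)
    try:
        return by_segment[parent], by_segment[child]
    except KeyError as exc:
        raise ValueError(f"no sensor on segment {exc.args[0]!r} for joint {joint!r}")


def _to_segment_frames(
    series: OrientationSeries, C_J: np.ndarray, C_K: np.ndarray,
    parent: str, child: str,
) -> OrientationSeries:
    """Rotate a sensor-frame relative series into segment frames:
    ``R_seg = C_J R_sensor C_K^T``."""
    R = series.as_matrices()
    R_seg = np.einsum("ij,njk,lk->nil", C_J, R, C_K)
    return OrientationSeries.from_matrices(series.time, R_seg, parent, child)


def fit_joint(
    sim: SimulationResult,
    joint: str,
    method: str,
    noise: NoiseConfig | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    smooth_cutoff: float | None = 10.0,
    hysteresis: float = 0.0,
    init_truth: bool = False,
    true_alpha: bool = False,
) -> tuple[OrientationSeries, RelativeFilterResults | None]:
    """Estimate one joint's relative orientation with one method.

    Returns the estimated series in segment frames (comparable with
    ``sim.truth_relative[joint]``) and, for the relative methods, the full
    :class:`RelativeFilterResults`.

    ``init_truth`` initializes nominal orientations from the simulator's
    ground truth; ``true_alpha`` substitutes the exact angular
    accelerations for the differentiated ones (both for oracle studies).
    """
    name_J, name_K = joint_sensor_pair(sim, joint)
    rel_truth = sim.truth_relative[joint]
    parent, child = rel_truth.frame_from, rel_truth.frame_to
    C_J, C_K = sim.sensor_rotation[name_J], sim.sensor_rotation[name_K]

    if method == "ekf":
        fits = []
        for name, seg in ((name_J, parent), (name_K, child)):
            fits.append(
                GlobalOrientationEKF(
                    sim.streams[name], segment=name, noise=noise
                ).fit()
            )
        rel_sensor = fits[0].relative_to(fits[1])
        return _to_segment_frames(rel_sensor, C_J, C_K, parent, child), None

    model = RelativeOrientationKF(
        sim.streams[name_J], sim.streams[name_K],
        sim.mounts[name_J][joint], sim.mounts[name_K][joint],
        method=method, threshold=threshold, noise=noise,
        smooth_cutoff=smooth_cutoff, hysteresis=hysteresis,
    )
    init = None
    if init_truth:
        R_WJ0 = sim.truth_global[parent].as_matrices()[0] @ C_J
        R_WK0 = sim.truth_global[child].as_matrices()[0] @ C_K
        init = (R_WJ0, R_WK0)
    alphas = {}
    if true_alpha:
        alphas = {
            "alpha_J": sim.sensor_alpha(name_J),
            "alpha_K": sim.sensor_alpha(name_K),
        }
    results = model.fit(init=init, **alphas)
    est = _to_segment_frames(results.orientations, C_J, C_K, parent, child)
    return est, results


def score_scenario(
    sim: SimulationResult,
    methods=METHODS,
    noise: NoiseConfig | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    **fit_kwargs,
) -> tuple[list[MetricReport], dict[tuple[str, str], OrientationSeries]]:
    """Run the requested methods on every joint and score them.

    Returns the metric reports and the estimated series keyed by
    ``(joint, method)``.
    """
    reports: list[MetricReport] = []
    series: dict[tuple[str, str], OrientationSeries] = {}
    for joint, truth in sim.truth_relative.items():
        for method in methods:
            est, _ = fit_joint(
                sim, joint, method, noise=noise, threshold=threshold, **fit_kwargs
            )
            series[(joint, method)] = est
            reports.append(evaluation.report(joint, method, est, truth))
    return reports, series
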