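"""Timestamped orientation sequences with frame labels."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import rotations

__all__ = ["OrientationSeries"]


@dataclass
class OrientationSeries:
    """A sequence of rotations ``R`` mapping ``frame_to`` vectors into
    ``frame_from`` coordinates (``v_from = R v_to``), stored as scalar-first
    unit quaternions.

    For a relative joint series ``frame_from`` is the proximal segment and
    ``frame_to`` the distal one; for a global series ``frame_from`` is
    ``"world"``.
    """

    time: np.ndarray          # (N,) seconds
    quat: np.ndarray          # (N, 4) scalar-first [w, x, y, z]
    frame_from: str
    frame_to: str

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.quat = np.asarray(self.quat, dtype=float)
        if self.quat.shape != (len(self.time), 4):
            raise ValueError(
                f"quat must have shape ({len(self.time)}, 4), got {self.quat.shape}"
            )
        norms = np.linalg.norm(self.quat, axis=1)
        if len(norms) and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("quaternions must have unit norm")

    def __len__(self) -> int:
        return len(self.time)

    @classmethod
    def from_matrices(
        cls, time: np.ndarray, matrices: np.ndarray, frame_from: str, frame_to: str
    ) -> "OrientationSeries":
        quat = np.array([rotations.quat_from_matrix(R) for R in matrices])
        if len(quat) == 0:
            quat = np.zeros((0, 4))
        return cls(np.asarray(time, dtype=float), quat, frame_from, frame_to)

    def as_matrices(self) -> np.ndarray:
        """(N, 3, 3) rotation matrices."""
        return np.array([rotations.matrix_from_quat(q) for q in self.quat]).reshape(
            len(self), 3, 3
        )

    def angle_axis(self) -> np.ndarray:
        """(N, 3) angle-axis vectors, radians."""
        return np.array([rotations.angle_axis(R) for R in self.as_matrices()]).reshape(
            len(self), 3
        )
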