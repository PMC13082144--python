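"""Minimal 3D rotation algebra shared by every other module.

Rotations are represented as 3x3 orthonormal matrices (numpy arrays); helper
functions convert to/from scalar-first unit quaternions and angle-axis
vectors via :class:`scipy.spatial.transform.Rotation`.

Conventions
-----------
* Quaternions are scalar-first ``[w, x, y, z]`` with ``w >= 0``.
* ``angle_axis`` returns ``theta * n`` with ``theta in [0, pi]``; at the
  half-turn ambiguity ``theta == pi`` the axis sign is fixed so that its
  first nonzero component is positive.
* Small-angle errors are injected with the exact exponential map (Rodrigues),
  which agrees with the first-order ``I + [eta x]`` injection to
  ``O(||eta||^2)`` but never leaves the manifold.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation as _ScipyRotation

__all__ = [
    "skew",
    "exp_map",
    "log_map",
    "relative",
    "angle_axis",
    "quat_from_matrix",
    "matrix_from_quat",
    "random_rotation",
    "orthonormalize",
    "is_rotation",
]

_IDENTITY = np.eye(3)


def _check_vector(v: np.ndarray, name: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} must be finite, got {v}")
    return v


def skew(v: np.ndarray) -> np.ndarray:
    """Cross-product matrix ``[v x]`` with ``skew(v) @ u == cross(v, u)``."""
    v = _check_vector(v)
    return np.array(
        [
            [0.0, -v[2], v[1]],
            [v[2], 0.0, -v[0]],
            [-v[1], v[0], 0.0],
        ]
    )


def exp_map(eta: np.ndarray) -> np.ndarray:
    """Rodrigues rotation matrix for the rotation vector ``eta``."""
    eta = _check_vector(eta, "eta")
    return _ScipyRotation.from_rotvec(eta).as_matrix()


def log_map(R: np.ndarray) -> np.ndarray:
    """Inverse of :func:`exp_map`; alias of :func:`angle_axis`."""
    return angle_axis(R)


def relative(R_WJ: np.ndarray, R_WK: np.ndarray) -> np.ndarray:
    """Relative orientation ``R_JK = R_WJ^T R_WK`` of frame K seen from J."""
    return np.asarray(R_WJ).T @ np.asarray(R_WK)


def angle_axis(R: np.ndarray) -> np.ndarray:
    """Angle-axis vector ``theta * n`` with ``theta in [0, pi]``.

    At ``theta == pi`` the axis sign is chosen so its first nonzero
    component is positive (the two signs describe the same rotation).
    """
    rv = _ScipyRotation.from_matrix(np.asarray(R, dtype=float)).as_rotvec()
    theta = np.linalg.norm(rv)
    if theta > np.pi - 1e-9:
        for c in rv:
            if abs(c) > 1e-12:
                if c < 0:
                    rv = -rv
                break
    return rv


def quat_from_matrix(R: np.ndarray) -> np.ndarray:
    """Scalar-first unit quaternion ``[w, x, y, z]`` with ``w >= 0``."""
    q = _ScipyRotation.from_matrix(np.asarray(R, dtype=float)).as_quat()  # x,y,z,w
    q = np.array([q[3], q[0], q[1], q[2]])
    if q[0] < 0:
        q = -q
    return q


def matrix_from_quat(q: np.ndarray) -> np.ndarray:
    """Rotation matrix from a scalar-first quaternion (normalized on input)."""
    q = np.asarray(q, dtype=float)
    if q.shape != (4,):
        raise ValueError(f"quaternion must have 4 components, got shape {q.shape}")
    n = np.linalg.norm(q)
    if not np.isfinite(n) or n == 0:
        raise ValueError("quaternion must be finite and nonzero")
    q = q / n
    return _ScipyRotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (for tests and property checks)."""
    return _ScipyRotation.random(rng=rng).as_matrix()


def orthonormalize(R: np.ndarray) -> np.ndarray:
    """Project a near-rotation matrix back onto SO(3) (nearest by SVD)."""
    U, _, Vt = np.linalg.svd(np.asarray(R, dtype=float))
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


def is_rotation(R: np.ndarray, tol: float = 1e-9) -> bool:
    """True if ``R`` is orthonormal with determinant +1 within ``tol``."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or not np.all(np.isfinite(R)):
        return False
    return (
        np.allclose(R.T @ R, _IDENTITY, atol=tol)
        and abs(np.linalg.det(R) - 1.0) < tol
    )
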