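"""Discrete-curvature geometry of point trajectories.

A trajectory is an ordered sequence of T+1 points.  Its local curvature at an
interior point is the unsigned angle between the two unit displacement
vectors that meet there, and its global curvature is the mean of the local
angles.  The module also converts between point coordinates and intrinsic
coordinates (step lengths, turning angles, and unit acceleration directions),
and recovers the turning angle at a vertex from three pairwise distances via
the law of cosines.

Angles are degrees at the interface and radians internally.  All operations
are invariant to rigid motions and to uniform positive scaling of the points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _ad as ad

__all__ = [
    "DegenerateTrajectoryError", "GeometryError", "IntrinsicTrajectory",
    "local_curvatures", "global_curvature", "angle_from_distances",
    "reconstruct", "extract_intrinsic",
]


class DegenerateTrajectoryError(ValueError):
    """Raised when consecutive trajectory points coincide."""


class GeometryError(ValueError):
    """Raised when distances cannot come from a planar triangle."""


@dataclass
class IntrinsicTrajectory:
    """Intrinsic coordinates of a point trajectory.

    Attributes
    ----------
    distances : (T,) positive step lengths d_t between successive points.
    curvatures_deg : (T-1,) local turning angles c_t in degrees, in [0, 180].
    accel_dirs : (T-1, n) unit vectors a_t, each orthogonal to the previous
        displacement direction; the new direction is
        ``v_t = cos(c_t) v_{t-1} + sin(c_t) a_t``.
    start_point : (n,) coordinates of the first point.
    start_direction : (n,) unit direction of the first displacement.
    """

    distances: np.ndarray
    curvatures_deg: np.ndarray
    accel_dirs: np.ndarray
    start_point: np.ndarray
    start_direction: np.ndarray

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        self.curvatures_deg = np.asarray(self.curvatures_deg, dtype=float)
        self.accel_dirs = np.atleast_2d(np.asarray(self.accel_dirs, dtype=float))
        self.start_point = np.asarray(self.start_point, dtype=float)
        self.start_direction = np.asarray(self.start_direction, dtype=float)
        if np.any(self.distances <= 0):
            raise ValueError("all step lengths must be positive")
        if len(self.curvatures_deg) != len(self.distances) - 1:
            raise ValueError("need one turning angle per interior point")
        if self.accel_dirs.shape[0] != len(self.curvatures_deg):
            raise ValueError("need one acceleration direction per turning angle")


def _validate_points(points) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    if points.shape[0] < 3:
        raise ValueError("curvature needs at least 3 points")
    return points


def local_curvatures(points) -> np.ndarray:
    """Turning angles (degrees) at the T-1 interior points of a trajectory."""
    points = _validate_points(points)
    disp = np.diff(points, axis=0)
    norms = np.linalg.norm(disp, axis=1)
    if np.any(norms == 0):
        raise DegenerateTrajectoryError("consecutive points coincide")
    v = disp / norms[:, None]
    # atan2 form of the arccos angle: exact at 0 and 180 degrees, where the
    # derivative of arccos of the (clipped) dot product blows up
    diff = np.linalg.norm(v[1:] - v[:-1], axis=1)
    summ = np.linalg.norm(v[1:] + v[:-1], axis=1)
    return np.degrees(2.0 * np.arctan2(diff, summ))


def global_curvature(points) -> float:
    """Mean of the local turning angles, in degrees."""
    return float(np.mean(local_curvatures(points)))


def angle_from_distances(d12: float, d23: float, d13: float,
                         tol: float = 1e-9) -> float:
    """Turning angle (degrees) at the middle of three points from distances.

    Uses the law of cosines: with gamma the interior angle at the middle
    point, the turning angle is ``180 - gamma`` degrees.  Distances violating
    the triangle inequality by more than ``tol`` (relative) raise
    :class:`GeometryError`; smaller violations are clipped.
    """
    if d12 <= 0 or d23 <= 0:
        raise ValueError("the two adjacent distances must be positive")
    cos_gamma = (d12 ** 2 + d23 ** 2 - d13 ** 2) / (2.0 * d12 * d23)
    if abs(cos_gamma) > 1.0 + tol * max(1.0, abs(cos_gamma)):
        raise GeometryError(
            f"distances ({d12}, {d23}, {d13}) violate the triangle inequality")
    return float(180.0 - np.degrees(np.arccos(np.clip(cos_gamma, -1.0, 1.0))))


def reconstruct_core(d, c_rad, a, x0, v1):
    """Differentiable trajectory reconstruction from intrinsic coordinates.

    All arguments may be numpy arrays or autodiff tensors and may carry
    arbitrary leading batch axes: ``d`` (..., T), ``c_rad`` (..., T-1),
    ``a`` (..., T-1, n), ``x0`` and ``v1`` (..., n).  Returns the (..., T+1, n)
    stacked points.  No validation is performed here.
    """
    T = ad.value(d).shape[-1]
    points = [x0]
    v = v1
    x = x0
    for t in range(T):
        if t > 0:
            ct = c_rad[..., t - 1:t]
            at = a[..., t - 1, :]
            v = ad.cos(ct) * v + ad.sin(ct) * at
        x = x + d[..., t:t + 1] * v
        points.append(x)
    return ad.stack(points, axis=-2)


def reconstruct(intr: IntrinsicTrajectory, atol: float = 1e-8) -> np.ndarray:
    """Points (T+1, n) of the trajectory with the given intrinsic coordinates.

    Raises ``ValueError`` if any acceleration direction is not unit length or
    not orthogonal to the direction it turns away from.
    """
    norms = np.linalg.norm(intr.accel_dirs, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("acceleration directions must be unit vectors")
    if abs(np.linalg.norm(intr.start_direction) - 1.0) > 1e-6:
        raise ValueError("start_direction must be a unit vector")
    # orthogonality must hold against the evolving direction sequence
    c = np.radians(intr.curvatures_deg)
    v = intr.start_direction
    for t in range(len(c)):
        if abs(float(np.dot(intr.accel_dirs[t], v))) > 1e-6:
            raise ValueError(
                f"accel_dirs[{t}] is not orthogonal to the previous direction")
        v = np.cos(c[t]) * v + np.sin(c[t]) * intr.accel_dirs[t]
    return np.asarray(reconstruct_core(
        intr.distances, c, intr.accel_dirs, intr.start_point,
        intr.start_direction))


def extract_intrinsic(points) -> IntrinsicTrajectory:
    """Intrinsic coordinates of a point trajectory (inverse of reconstruct).

    At numerically collinear vertices the acceleration direction is
    underdetermined; an arbitrary unit vector orthogonal to the previous
    direction is chosen there.
    """
    points = _validate_points(points)
    disp = np.diff(points, axis=0)
    d = np.linalg.norm(disp, axis=1)
    if np.any(d == 0):
        raise DegenerateTrajectoryError("consecutive points coincide")
    v = disp / d[:, None]
    cosang = np.clip(np.einsum("ij,ij->i", v[:-1], v[1:]), -1.0, 1.0)
    c = np.arccos(cosang)
    n = points.shape[1]
    a = np.zeros((len(c), n))
    for t in range(len(c)):
        resid = v[t + 1] - cosang[t] * v[t]
        nr = np.linalg.norm(resid)
        if nr > 1e-12:
            a[t] = resid / nr
        else:
            # collinear: any unit vector orthogonal to v_t
            basis = np.eye(n)[np.argmin(np.abs(v[t]))]
            resid = basis - np.dot(basis, v[t]) * v[t]
            a[t] = resid / np.linalg.norm(resid)
    return IntrinsicTrajectory(distances=d, curvatures_deg=np.degrees(c),
                               accel_dirs=a, start_point=points[0],
                               start_direction=v[0])
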