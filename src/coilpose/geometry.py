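"""Centerline geometry: tangent-angle <-> skeleton conversions, angular
metrics, head-tail flips and eigenworm projections.

A worm pose is parameterized by the vector of tangent angles
``theta = (theta_1, ..., theta_N)`` of N equal-length centerline segments,
ordered head to tail (N = 100 by convention, giving 101 skeleton points).
Angles follow the image convention x = column, y = row (y grows downward)
and are measured with ``atan2(dy, dx)``.

All angular arithmetic goes through :func:`wrap_angle` /
:func:`wrap_angle_diff`, which map onto the interval (-pi, pi].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Skeleton",
    "EigenBasis",
    "wrap_angle",
    "wrap_angle_diff",
    "angles_to_skeleton",
    "skeleton_to_angles",
    "resample_skeleton",
    "skeleton_length",
    "unwrap_body",
    "rmse_angle_distance",
    "mean_abs_angle_distance",
    "flip_centerline",
    "compute_eigenbasis",
    "project_modes",
    "reconstruct_from_modes",
]

#: default number of tangent angles describing a pose
N_ANGLES = 100


def wrap_angle(theta: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) to the interval (-pi, pi]."""
    wrapped = np.mod(np.asarray(theta, dtype=float) + np.pi, 2.0 * np.pi) - np.pi
    # np.mod gives [-pi, pi); move the open edge so that -pi maps to +pi
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    if np.isscalar(theta):
        return float(wrapped)
    return wrapped


def wrap_angle_diff(alpha, beta):
    """Signed angular difference ``alpha - beta`` wrapped to (-pi, pi].

    Computed as ``atan2(sin(a - b), cos(a - b))``, which is antisymmetric:
    ``wrap_angle_diff(a, b) == -wrap_angle_diff(b, a)`` up to the +/-pi edge.
    """
    delta = np.asarray(alpha, dtype=float) - np.asarray(beta, dtype=float)
    out = np.arctan2(np.sin(delta), np.cos(delta))
    if np.isscalar(alpha) and np.isscalar(beta):
        return float(out)
    return out


@dataclass
class Skeleton:
    """Ordered (x, y) pixel coordinates of equidistant centerline points.

    Points run head to tail; ``ds`` is the segment length in pixels.
    """

    points: np.ndarray  # (n_points, 2) float, columns (x, y)
    ds: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (x, y)")
        if self.points.shape[0] < 3:
            raise ValueError("a skeleton needs at least 3 points")
        if self.ds <= 0:
            raise ValueError("segment length ds must be positive")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    @property
    def length(self) -> float:
        """Total arc length along the polyline, in pixels."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


def angles_to_skeleton(
    angles: np.ndarray, ds: float, origin: tuple[float, float] = (0.0, 0.0)
) -> Skeleton:
    """Integrate tangent angles into skeleton coordinates.

    Point 1 sits at ``origin`` and each subsequent point advances by
    ``ds * (cos theta_i, sin theta_i)``, so N angles yield N + 1 points.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.ndim != 1 or angles.size < 2:
        raise ValueError("need a 1-D vector of at least 2 angles")
    if ds <= 0:
        raise ValueError("segment length ds must be positive")
    steps = ds * np.column_stack([np.cos(angles), np.sin(angles)])
    points = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    points += np.asarray(origin, dtype=float)
    return Skeleton(points=points, ds=float(ds))


def skeleton_to_angles(skeleton: Skeleton | np.ndarray) -> np.ndarray:
    """Tangent angle of each skeleton segment: ``atan2(dy_i, dx_i)``.

    The inverse of :func:`angles_to_skeleton`; N_S points yield N_S - 1
    angles. Raises on duplicate consecutive points (undefined direction).
    """
    points = skeleton.points if isinstance(skeleton, Skeleton) else np.asarray(skeleton, float)
    if points.shape[0] < 3:
        raise ValueError("need at least 3 skeleton points")
    diffs = np.diff(points, axis=0)
    if np.any(np.all(diffs == 0.0, axis=1)):
        raise ValueError("duplicate consecutive skeleton points")
    return np.arctan2(diffs[:, 1], diffs[:, 0])


def skeleton_length(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(np.asarray(points, float), axis=0), axis=1).sum())


def resample_skeleton(points: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a polyline to ``n_points`` equidistant points by arc-length
    linear interpolation. Used whenever a reference and target differ in N_S."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    target = np.linspace(0.0, s[-1], n_points)
    x = np.interp(target, s, points[:, 0])
    y = np.interp(target, s, points[:, 1])
    return np.column_stack([x, y])


def unwrap_body(angles: np.ndarray) -> np.ndarray:
    """Unwrap a tangent-angle vector along the body.

    Wrapped angles of deeply coiled postures jump by 2*pi where the true
    (smooth) tangent direction crosses +/-pi; unwrapping restores the
    smooth curve so that linear operations (eigenworm projections) are
    meaningful. Accepts ``(N,)`` or ``(T, N)``.
    """
    return np.unwrap(np.asarray(angles, dtype=float), axis=-1)


def rmse_angle_distance(theta1: np.ndarray, theta2: np.ndarray) -> float:
    """Root-mean-square wrapped angle difference between two centerlines:
    ``d(t1, t2) = sqrt(mean_i eps(t1_i, t2_i)^2)``. Symmetric, >= 0."""
    theta1 = np.asarray(theta1, dtype=float)
    theta2 = np.asarray(theta2, dtype=float)
    if theta1.shape != theta2.shape:
        raise ValueError("centerline length mismatch")
    eps = wrap_angle_diff(theta1, theta2)
    return float(np.sqrt(np.mean(np.square(eps))))


def mean_abs_angle_distance(theta1: np.ndarray, theta2: np.ndarray) -> float:
    """Mean absolute wrapped angle difference; the adjacent-frame distance
    used when resolving head-tail orientation over time."""
    theta1 = np.asarray(theta1, dtype=float)
    theta2 = np.asarray(theta2, dtype=float)
    if theta1.shape != theta2.shape:
        raise ValueError("centerline length mismatch")
    return float(np.mean(np.abs(wrap_angle_diff(theta1, theta2))))


def flip_centerline(angles: np.ndarray) -> np.ndarray:
    """Head-tail flipped version of a pose: reverse the angle order and add
    pi, rewrapped. The flipped skeleton traces the same curve tail to head,
    and the operation is an involution."""
    angles = np.asarray(angles, dtype=float)
    return wrap_angle(angles[::-1] + np.pi)


@dataclass
class EigenBasis:
    """Eigenworm basis: principal components of a tangent-angle ensemble.

    ``components[i]`` is the i-th eigenworm (orthonormal, decreasing
    explained variance). By convention the first two capture the traveling
    body wave and the third, a_3, the turning amplitude.
    """

    mean_angles: np.ndarray  # (N,)
    components: np.ndarray  # (d, N) orthonormal rows
    explained_variance_ratio: np.ndarray
    source: str = "unspecified"

    def __post_init__(self) -> None:
        self.mean_angles = np.asarray(self.mean_angles, dtype=float)
        self.components = np.asarray(self.components, dtype=float)
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(self.components.shape[0]), atol=1e-8):
            raise ValueError("eigenbasis components must be orthonormal")

    @property
    def n_modes(self) -> int:
        return self.components.shape[0]


def compute_eigenbasis(
    shapes: np.ndarray, n_modes: int = 5, source: str = "unspecified"
) -> EigenBasis:
    """Mean-subtracted PCA of a shape ensemble -> eigenworm basis.

    Parameters
    ----------
    shapes : (n_shapes, N) array of tangent-angle vectors. Shapes should be
        supplied in a common body frame (global rotation removed) if
        rotation-invariant mode coefficients are wanted.
    n_modes : number of leading components to keep (d = 5 conventionally).
    """
    shapes = np.asarray(shapes, dtype=float)
    if shapes.ndim != 2:
        raise ValueError("shapes must be a 2-D (n_shapes, N) array")
    if shapes.shape[0] < n_modes:
        raise ValueError("need at least n_modes shapes")
    mean = shapes.mean(axis=0)
    centered = shapes - mean
    # SVD is deterministic and exact; sklearn.PCA adds nothing here
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int(np.sum(svals > svals[0] * 1e-12)) if svals.size else 0
    if n_modes > rank:
        raise ValueError(f"requested {n_modes} modes but data rank is {rank}")
    var = svals**2
    total = var.sum()
    evr = var[:n_modes] / total if total > 0 else np.zeros(n_modes)
    # fix sign deterministically: largest-magnitude entry positive
    comps = vt[:n_modes].copy()
    for row in comps:
        imax = np.argmax(np.abs(row))
        if row[imax] < 0:
            row *= -1.0
    return EigenBasis(
        mean_angles=mean,
        components=comps,
        explained_variance_ratio=evr,
        source=source,
    )


def project_modes(angles: np.ndarray, basis: EigenBasis) -> np.ndarray:
    """Eigenworm coefficients ``a_i = (theta - mean) . component_i``.

    Accepts a single centerline ``(N,)`` or a stack ``(T, N)``.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.shape[-1] != basis.mean_angles.shape[0]:
        raise ValueError("centerline length does not match basis")
    return (angles - basis.mean_angles) @ basis.components.T


def reconstruct_from_modes(modes: np.ndarray, basis: EigenBasis) -> np.ndarray:
    """Map mode coefficients back to tangent angles:
    ``mean + sum_i a_i component_i`` (the L2-optimal reconstruction within
    the span of the basis)."""
    modes = np.asarray(modes, dtype=float)
    return basis.mean_angles + modes @ basis.components
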