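"""Rigid superimposition of one sinus model onto another by iterative
closest point (ICP).

The moving (PM) mesh is aligned onto the reference (AM) mesh by alternating
(a) exact point-to-surface correspondences — each moving vertex is paired
with its nearest point on the reference surface — and (b) the closed-form
Kabsch solution of the resulting paired least-squares problem.  Rotations
are proper (determinant +1): left and right sinuses are never
cross-compared, so reflections are forbidden.

The ICP objective (RMS of the moving vertices' distances to the reference
surface) is non-increasing by construction: the new correspondences cannot
be farther than the old paired points, and the Kabsch step cannot increase
the paired sum of squares.  The recorded trace asserts this on every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .distance import SurfaceDistanceQuery
from .errors import DegenerateGeometryError, EmptyInputError, InvalidConfigError

__all__ = [
    "RigidTransform",
    "IcpConfig",
    "IcpTrace",
    "kabsch_align",
    "initialize_pose",
    "icp_register",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> rotation @ x + translation`` in mm."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        object.__setattr__(self, "rotation", rotation)
        object.__setattr__(self, "translation", translation)
        if not np.allclose(rotation.T @ rotation, np.eye(3), atol=1e-8):
            raise InvalidConfigError("rotation matrix is not orthogonal")
        if np.linalg.det(rotation) < 0:
            raise InvalidConfigError("reflections are not rigid motions here")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def to_matrix(self) -> np.ndarray:
        matrix = np.eye(4)
        matrix[:3, :3] = self.rotation
        matrix[:3, 3] = self.translation
        return matrix


@dataclass(frozen=True)
class IcpConfig:
    """ICP iteration-control parameters.

    ``rel_tolerance`` stops iteration when the relative drop of the
    objective RMS falls below it; ``init_mode`` selects the starting pose.
    """

    max_iterations: int = 100
    rel_tolerance: float = 1e-6
    init_mode: str = "centroid+pca"
    correspondence: str = "surface"

    def __post_init__(self):
        if self.max_iterations < 1:
            raise InvalidConfigError("max_iterations must be >= 1")
        if self.rel_tolerance <= 0:
            raise InvalidConfigError("rel_tolerance must be positive")
        if self.init_mode not in {"identity", "centroid", "centroid+pca"}:
            raise InvalidConfigError(f"unknown init_mode {self.init_mode!r}")
        if self.correspondence not in {"surface", "vertex"}:
            raise InvalidConfigError(f"unknown correspondence {self.correspondence!r}")


@dataclass
class IcpTrace:
    """Objective history of one ICP run (RMS in mm per iteration)."""

    objective: list = field(default_factory=list)
    converged: bool = False
    iterations_used: int = 0


def kabsch_align(source_points: np.ndarray,
                 target_points: np.ndarray) -> RigidTransform:
    """Least-squares rigid alignment of paired point sets (Kabsch, SVD).

    Returns the proper rotation and translation minimizing
    ``sum_i || R s_i + t - t_i ||^2``; the determinant of ``R`` is corrected
    to +1 so a reflection can never be returned.
    """
    source = np.asarray(source_points, dtype=np.float64)
    target = np.asarray(target_points, dtype=np.float64)
    if source.shape != target.shape or source.ndim != 2 or source.shape[1] != 3:
        raise DegenerateGeometryError("point sets must be matching (n, 3) arrays")
    if len(source) < 3:
        raise DegenerateGeometryError("rigid alignment needs at least 3 points")
    source_centroid = source.mean(axis=0)
    target_centroid = target.mean(axis=0)
    cross = (target - target_centroid).T @ (source - source_centroid)
    # rank < 2 means the points are collinear (or coincident): rotation
    # about the common line is unconstrained
    if np.linalg.matrix_rank(cross, tol=1e-12 * max(1.0, abs(cross).max())) < 2:
        if np.allclose(source - source_centroid, 0) and np.allclose(target - target_centroid, 0):
            raise DegenerateGeometryError("all points coincide")
        raise DegenerateGeometryError("point configuration is collinear")
    u, _, vt = np.linalg.svd(cross)
    sign = np.sign(np.linalg.det(u @ vt))
    rotation = u @ np.diag([1.0, 1.0, sign]) @ vt
    translation = target_centroid - rotation @ source_centroid
    return RigidTransform(rotation, translation)


def _principal_axes(points: np.ndarray) -> np.ndarray:
    """Right-handed principal axes (columns, descending variance)."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axes = vt.T
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    return axes


def _surface_rms(query: SurfaceDistanceQuery, points: np.ndarray) -> float:
    _, dist = query.query(points)
    return float(np.sqrt(np.mean(np.square(dist))))


def initialize_pose(moving: trimesh.Trimesh, reference: trimesh.Trimesh,
                    mode: str = "centroid+pca",
                    query: SurfaceDistanceQuery | None = None) -> RigidTransform:
    """Starting pose for ICP.

    ``identity`` leaves the moving mesh in place; ``centroid`` translates its
    centroid onto the reference's; ``centroid+pca`` additionally rotates its
    principal axes onto the reference's, trying the four proper sign
    combinations and keeping the one with the smallest surface RMS on a
    vertex subsample.
    """
    if len(moving.vertices) == 0 or len(reference.vertices) == 0:
        raise EmptyInputError("initialize_pose requires nonempty meshes")
    if mode == "identity":
        return RigidTransform.identity()
    moving_centroid = moving.vertices.mean(axis=0)
    reference_centroid = reference.vertices.mean(axis=0)
    if mode == "centroid":
        return RigidTransform(np.eye(3), reference_centroid - moving_centroid)
    if mode != "centroid+pca":
        raise InvalidConfigError(f"unknown init mode {mode!r}")
    moving_axes = _principal_axes(np.asarray(moving.vertices))
    reference_axes = _principal_axes(np.asarray(reference.vertices))
    if query is None:
        query = SurfaceDistanceQuery(reference)
    sample = np.asarray(moving.vertices)
    if len(sample) > 200:
        sample = sample[np.linspace(0, len(sample) - 1, 200).astype(int)]
    best: RigidTransform | None = None
    best_rms = np.inf
    # the four proper rotations flipping pairs of principal axes
    for signs in ([1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]):
        rotation = reference_axes @ np.diag(signs) @ moving_axes.T
        translation = reference_centroid - rotation @ moving_centroid
        candidate = RigidTransform(rotation, translation)
        candidate_rms = _surface_rms(query, candidate.apply(sample))
        if candidate_rms < best_rms:
            best_rms = candidate_rms
            best = candidate
    assert best is not None
    return best


def icp_register(moving: trimesh.Trimesh, reference: trimesh.Trimesh,
                 config: IcpConfig | None = None
                 ) -> tuple[RigidTransform, IcpTrace]:
    """Rigidly register ``moving`` (PM) onto ``reference`` (AM).

    Returns the cumulative transform mapping original moving coordinates
    into the reference frame, plus the iteration trace.  The objective is
    the RMS distance of the transformed moving vertices to the reference
    surface; iteration stops when its relative change falls below
    ``config.rel_tolerance`` or ``config.max_iterations`` is reached.
    """
    if config is None:
        config = IcpConfig()
    if len(moving.vertices) == 0 or len(reference.vertices) == 0:
        raise EmptyInputError("icp_register requires nonempty meshes")
    query = SurfaceDistanceQuery(reference)
    reference_vertex_tree = None
    if config.correspondence == "vertex":
        from scipy.spatial import cKDTree
        reference_vertex_tree = cKDTree(np.asarray(reference.vertices))

    transform = initialize_pose(moving, reference, config.init_mode, query=query)
    points = transform.apply(moving.vertices)
    trace = IcpTrace()
    previous = np.inf
    for iteration in range(1, config.max_iterations + 1):
        if config.correspondence == "surface":
            targets, dist = query.query(points)
        else:
            dist, idx = reference_vertex_tree.query(points)
            targets = np.asarray(reference.vertices)[idx]
        objective = float(np.sqrt(np.mean(np.square(dist))))
        trace.objective.append(objective)
        trace.iterations_used = iteration
        if objective < 1e-12:
            trace.converged = True
            break
        if np.isfinite(previous) and (previous - objective) / previous < config.rel_tolerance:
            trace.converged = True
            break
        previous = objective
        step = kabsch_align(points, targets)
        transform = step.compose(transform)
        points = step.apply(points)
    return transform, trace
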