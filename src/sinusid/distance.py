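"""Point-to-surface distance fields, the RMS identity statistic, and the
three-band chromatic classification of superimposed sinus models.

The headline statistic of the whole pipeline is the RMS point-to-point
distance: the square root of the mean squared distance from each vertex of
the reference (AM) model to the nearest point on the registered moving (PM)
surface.  Distances are true point-to-triangle distances, not
vertex-to-vertex ones, so the statistic does not depend on how finely the
moving surface happens to be sampled.

Nearest-point queries are exact: a k-d tree over triangle centroids prunes
candidates using a provable radius bound (nearest-vertex distance plus the
largest centroid-to-vertex radius in the mesh), and the exact closest point
on each surviving triangle is then computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from trimesh.triangles import closest_point as _triangle_closest_point

from .errors import EmptyInputError, InvalidConfigError

__all__ = [
    "SurfaceDistanceQuery",
    "DistanceField",
    "SuperimpositionResult",
    "point_to_surface_field",
    "rms",
    "color_classify",
]


class SurfaceDistanceQuery:
    """Exact nearest-point-on-surface queries against a fixed triangle mesh.

    Parameters
    ----------
    mesh:
        Triangle mesh in mm coordinates.  Vertices and faces are copied once;
        the query object is immutable afterwards.

    Notes
    -----
    For each query point ``p`` the distance to the nearest mesh *vertex* is an
    upper bound ``u`` on the distance to the surface.  Any triangle containing
    a closer point must have its centroid within ``u + R`` of ``p``, where
    ``R`` is the largest centroid-to-vertex distance over all triangles, so a
    ball query over centroids with that radius yields a candidate set that is
    guaranteed to contain the true nearest triangle.  The exact closest point
    on every candidate is then evaluated.
    """

    def __init__(self, mesh: trimesh.Trimesh):
        if len(mesh.vertices) == 0 or len(mesh.faces) == 0:
            raise EmptyInputError("cannot build a distance query on an empty mesh")
        self.triangles = np.asarray(mesh.triangles, dtype=np.float64)
        self._centroids = self.triangles.mean(axis=1)
        # per-triangle circumscribing radius about the centroid
        tri_radius = np.linalg.norm(
            self.triangles - self._centroids[:, None, :], axis=2
        ).max(axis=1)
        self._max_tri_radius = float(tri_radius.max())
        self._vertex_tree = cKDTree(np.asarray(mesh.vertices, dtype=np.float64))
        self._centroid_tree = cKDTree(self._centroids)

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(closest_points, distances)`` for an (n, 3) array."""
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        upper, _ = self._vertex_tree.query(points)
        radii = upper + self._max_tri_radius + 1e-9
        candidate_lists = self._centroid_tree.query_ball_point(points, radii)
        counts = np.fromiter((len(c) for c in candidate_lists), dtype=np.intp,
                             count=len(points))
        tri_idx = np.concatenate([np.asarray(c, dtype=np.intp)
                                  for c in candidate_lists])
        pt_idx = np.repeat(np.arange(len(points)), counts)
        cand_closest = _triangle_closest_point(self.triangles[tri_idx],
                                               points[pt_idx])
        cand_dist = np.linalg.norm(cand_closest - points[pt_idx], axis=1)
        # per-point argmin: sort candidates by distance, keep the first
        # occurrence of each point index (every point has >= 1 candidate)
        order = np.argsort(cand_dist, kind="stable")
        _, first = np.unique(pt_idx[order], return_index=True)
        best = order[first]
        return cand_closest[best], cand_dist[best]


@dataclass
class DistanceField:
    """Per-reference-vertex distances to the registered moving surface.

    ``signed`` is positive where the moving surface lies outside the
    reference along the reference outward normal, negative where it lies
    inside; ``unsigned`` is its absolute value.
    """

    unsigned: np.ndarray
    signed: np.ndarray

    def __post_init__(self):
        self.unsigned = np.asarray(self.unsigned, dtype=np.float64)
        self.signed = np.asarray(self.signed, dtype=np.float64)
        if self.unsigned.shape != self.signed.shape:
            raise ValueError("unsigned and signed fields must share a shape")
        if not np.allclose(self.unsigned, np.abs(self.signed)):
            raise ValueError("unsigned field must equal |signed|")

    def __len__(self) -> int:
        return len(self.unsigned)


@dataclass
class SuperimpositionResult:
    """One superimposition: transform, distance field and the RMS statistic."""

    rms: float
    field: DistanceField
    transform: "np.ndarray | None" = None
    trace: "object | None" = None
    metadata: dict = field(default_factory=dict)


def point_to_surface_field(reference: trimesh.Trimesh,
                           registered_moving: trimesh.Trimesh) -> DistanceField:
    """Distance from every reference (AM) vertex to the moving (PM) surface.

    Both meshes must already be superimposed and expressed in mm.  The sign
    of each distance is the sign of the displacement from the reference
    vertex to its nearest moving-surface point, projected on the reference
    outward vertex normal: positive means the moving surface sits outside
    the reference at that vertex.
    """
    if len(reference.vertices) == 0 or len(registered_moving.vertices) == 0:
        raise EmptyInputError("point_to_surface_field requires nonempty meshes")
    query = SurfaceDistanceQuery(registered_moving)
    closest, dist = query.query(reference.vertices)
    normals = np.asarray(reference.vertex_normals, dtype=np.float64)
    direction = np.einsum("ij,ij->i", closest - reference.vertices, normals)
    signed = np.where(direction >= 0.0, dist, -dist)
    return DistanceField(unsigned=dist, signed=signed)


def rms(field: DistanceField | np.ndarray) -> float:
    """Root mean square of the unsigned distances, in mm."""
    values = field.unsigned if isinstance(field, DistanceField) else np.asarray(field, dtype=float)
    if values.size == 0:
        raise EmptyInputError("rms of an empty distance field is undefined")
    return float(np.sqrt(np.mean(np.square(values))))


def color_classify(field: DistanceField, band: float = 0.5) -> np.ndarray:
    """Three-band chromatic map of the signed distance field.

    ``green`` where ``|signed| <= band`` (surfaces locally coincide),
    ``red`` where ``signed > band`` (moving surface outside the reference),
    ``blue`` where ``signed < -band``.  The band boundary is inclusive, so a
    signed distance of exactly ``+band`` is green.
    """
    if band <= 0:
        raise InvalidConfigError("color band must be positive")
    classes = np.full(len(field), "green", dtype=object)
    classes[field.signed > band] = "red"
    classes[field.signed < -band] = "blue"
    return classes
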