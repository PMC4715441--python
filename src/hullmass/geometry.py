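"""Per-segment convex hulls and volumes for articulated skeletons.

A skeleton is supplied as named point sets ("functional units": skull, neck
sub-units, trunk, limb elements, feet), each of which is wrapped in its
minimum convex hull. Whole-body hull volume is the sum of the per-segment
hull volumes; because foot hulls are very sensitive to digit posture, totals
are reported both with and without the segments flagged as feet.

Coordinates are millimetres and volumes cubic millimetres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .errors import DegenerateGeometry, InvalidPlane, OpenSurface

#: planarity tolerance, as a fraction of the hull's bounding-box diagonal
PLANAR_TOL_SCALE = 1e-8
#: relative tolerance on volume comparisons
VOLUME_RTOL = 1e-9


@dataclass(frozen=True)
class PointSet:
    """A labelled cloud of 3D points (mm) belonging to one functional unit."""

    label: str
    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must have shape (n, 3), got {pts.shape}")
        if pts.shape[0] < 1:
            raise ValueError("a point set needs at least one point")
        if not np.all(np.isfinite(pts)):
            raise ValueError(f"non-finite coordinates in segment {self.label!r}")
        if not self.label:
            raise ValueError("segment label must be non-empty")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class SkeletonSegments:
    """An articulated skeleton partitioned into named functional units.

    ``segments`` preserves insertion order; ``feet_labels`` flags the subset
    of segments whose hulls are excluded from the minus-feet total.
    """

    specimen_id: str
    segments: dict[str, PointSet]
    feet_labels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        self.feet_labels = frozenset(self.feet_labels)
        unknown = self.feet_labels - set(self.segments)
        if unknown:
            raise ValueError(f"feet labels not among segments: {sorted(unknown)}")
        for name, seg in self.segments.items():
            if seg.label != name:
                raise ValueError(f"segment key {name!r} != point-set label {seg.label!r}")


@dataclass(frozen=True)
class ConvexPolytope:
    """A closed triangulated convex surface: vertices plus oriented facets.

    Facets are index triples wound so that the geometric normal points away
    from the interior.
    """

    vertices: np.ndarray
    facets: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.facets, dtype=np.intp)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must have shape (m, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("facets must have shape (k, 3)")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "facets", f)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_facets(self) -> int:
        return self.facets.shape[0]

    @property
    def n_edges(self) -> int:
        edges = {frozenset(e) for tri in self.facets for e in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0]))}
        return len(edges)

    def planar_tolerance(self) -> float:
        """Absolute planarity tolerance scaled to the bounding-box diagonal."""
        diag = float(np.linalg.norm(self.vertices.max(axis=0) - self.vertices.min(axis=0)))
        return PLANAR_TOL_SCALE * max(diag, 1.0)

    def facet_normals(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit outward normals and plane offsets (n·x = d) per facet."""
        tris = self.vertices[self.facets]
        n = np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0])
        norms = np.linalg.norm(n, axis=1, keepdims=True)
        n = n / norms
        d = np.einsum("ij,ij->i", n, tris[:, 0])
        return n, d

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Max signed distance of each point to the facet planes (<=0 inside)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n, d = self.facet_normals()
        return (pts @ n.T - d).max(axis=1)

    def contains(self, points: np.ndarray, tol: float | None = None) -> np.ndarray:
        if tol is None:
            tol = self.planar_tolerance()
        return self.signed_distance(points) <= tol

    def validate(self) -> None:
        """Check closure, the Euler relation and outward facet orientation."""
        _check_closed(self.facets, self.n_vertices)
        euler = self.n_vertices - self.n_edges + self.n_facets
        if euler != 2:
            raise OpenSurface(f"Euler characteristic {euler} != 2")
        centroid = self.vertices.mean(axis=0)
        n, d = self.facet_normals()
        if np.any(n @ centroid - d >= 0):
            raise OpenSurface("some facet normals do not point away from the centroid")
        # every vertex on or inside every plane
        tol = self.planar_tolerance()
        if self.signed_distance(self.vertices).max() > tol:
            raise OpenSurface("a vertex lies outside a facet plane beyond tolerance")


def _check_closed(facets: np.ndarray, n_vertices: int) -> None:
    """Every undirected edge must be used exactly twice, once per direction."""
    directed: set[tuple[int, int]] = set()
    for tri in facets:
        for e in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            e = (int(e[0]), int(e[1]))
            if e[0] == e[1] or e in directed:
                raise OpenSurface(f"degenerate or repeated directed edge {e}")
            directed.add(e)
    for a, b in directed:
        if (b, a) not in directed:
            raise OpenSurface(f"boundary edge ({a}, {b}): surface is not closed")


def compute_convex_hull(points: PointSet | np.ndarray) -> ConvexPolytope:
    """Minimum convex hull of a point set.

    Duplicate points are removed first; the remaining set must contain at
    least four points of full affine rank (a genuinely 3D cloud), otherwise
    :class:`~hullmass.errors.DegenerateGeometry` is raised — a flat or sparse
    segment would silently contribute zero volume to a skeleton total.
    """
    label = points.label if isinstance(points, PointSet) else None
    pts = points.points if isinstance(points, PointSet) else np.asarray(points, dtype=float)
    pts = np.unique(pts, axis=0)
    if pts.shape[0] < 4:
        raise DegenerateGeometry(
            f"segment {label or '<anonymous>'}: need >= 4 distinct points, got {pts.shape[0]}",
            label=label,
        )
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[0] == 0 or s[2] / s[0] < 1e-10:
        raise DegenerateGeometry(
            f"segment {label or '<anonymous>'}: points are coplanar or collinear",
            label=label,
        )
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:  # pragma: no cover - rank check catches most
        raise DegenerateGeometry(
            f"segment {label or '<anonymous>'}: hull construction failed: {exc}",
            label=label,
        ) from exc

    used = hull.vertices  # indices of extreme points
    remap = np.full(pts.shape[0], -1, dtype=np.intp)
    remap[used] = np.arange(used.size)
    facets = remap[hull.simplices]

    # orient each triangle so its geometric normal matches qhull's outward plane
    verts = pts[used]
    tris = verts[facets]
    geo = np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0])
    flip = np.einsum("ij,ij->i", geo, hull.equations[:, :3]) < 0
    facets[flip] = facets[flip][:, [0, 2, 1]]

    return ConvexPolytope(vertices=verts, facets=facets)


def polytope_volume(hull: ConvexPolytope) -> float:
    """Volume enclosed by a closed oriented triangulated surface.

    Sum of signed tetrahedron volumes spanned by each facet and the origin
    (divergence theorem); with outward-oriented facets the result is
    origin-independent and positive.
    """
    _check_closed(hull.facets, hull.n_vertices)
    tris = hull.vertices[hull.facets]
    vol = float(np.einsum("ij,ij->", tris[:, 0], np.cross(tris[:, 1], tris[:, 2]))) / 6.0
    if vol <= 0:
        raise OpenSurface(f"non-positive volume {vol}: facets are not consistently oriented")
    return vol


@dataclass
class HullVolumeTable:
    """Per-segment hull volumes (mm³) for one specimen, plus totals."""

    specimen_id: str
    volumes: dict[str, float]
    feet_labels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        self.feet_labels = frozenset(self.feet_labels)
        unknown = self.feet_labels - set(self.volumes)
        if unknown:
            raise ValueError(f"feet labels not among segments: {sorted(unknown)}")
        for name, v in self.volumes.items():
            if not v > 0:
                raise ValueError(f"segment {name!r} has non-positive volume {v}")

    @property
    def total_with_feet(self) -> float:
        return float(sum(self.volumes.values()))

    @property
    def total_minus_feet(self) -> float:
        feet = sum(self.volumes[k] for k in self.feet_labels)
        return float(self.total_with_feet - feet)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"specimen": self.specimen_id, "segment": seg, "volume_mm3": vol}
            for seg, vol in self.volumes.items()
        ]
        rows.append({"specimen": self.specimen_id, "segment": "TOTAL", "volume_mm3": self.total_with_feet})
        rows.append(
            {"specimen": self.specimen_id, "segment": "TOTAL_MINUS_FEET", "volume_mm3": self.total_minus_feet}
        )
        return pd.DataFrame(rows)


def segment_hull_volumes(skeleton: SkeletonSegments) -> HullVolumeTable:
    """Hull every segment of a skeleton and tabulate volumes and totals.

    Raises :class:`DegenerateGeometry` carrying the label of the first
    segment that cannot be hulled.
    """
    volumes: dict[str, float] = {}
    for name, seg in skeleton.segments.items():
        try:
            hull = compute_convex_hull(seg)
        except DegenerateGeometry as exc:
            raise DegenerateGeometry(str(exc), label=name) from exc
        volumes[name] = polytope_volume(hull)
    return HullVolumeTable(
        specimen_id=skeleton.specimen_id, volumes=volumes, feet_labels=skeleton.feet_labels
    )


def mirror_segment(
    points: PointSet, plane_point: np.ndarray, plane_normal: np.ndarray
) -> PointSet:
    """Reflect a segment across a plane given by a point and a normal.

    Used to restore bilateral symmetry when one side of a mounted skeleton
    is incomplete (e.g. a ribcage missing the ribs of one side). Reflection
    is an involution and preserves hull volume.
    """
    p0 = np.asarray(plane_point, dtype=float).reshape(3)
    n = np.asarray(plane_normal, dtype=float).reshape(3)
    norm = np.linalg.norm(n)
    if norm == 0 or not np.isfinite(norm):
        raise InvalidPlane("mirror plane normal must be non-zero and finite")
    n = n / norm
    d = (points.points - p0) @ n
    reflected = points.points - 2.0 * d[:, None] * n
    return PointSet(label=points.label, points=reflected)
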