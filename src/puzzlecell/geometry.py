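"""Planar computational geometry for cell contours.

The shape statistics and the tissue simulator both operate on closed
polygonal outlines ("contours") of single cells, measured in micrometres.
This module provides the shared primitives: orientation normalization,
areas and perimeters, convex hulls, outward node normals, signed turning
angles, contour resampling, the Delaunay-based largest empty circle (LEC)
and PCA projection of 3D contours onto their best-fit plane.

Conventions
-----------
* Contours are stored counter-clockwise (signed area > 0) after
  :func:`normalize_contour`; the closing edge (last -> first point) is
  implicit.
* Indices are 0-based; ``node_normal(c, i)`` refers to the i-th stored
  point.
* All coordinates are continuous 2D positions in µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import ConvexHull, Delaunay, QhullError
from shapely.geometry import Polygon


__all__ = [
    "Contour",
    "Contour3D",
    "LECResult",
    "normalize_contour",
    "polygon_area",
    "polygon_perimeter",
    "convex_hull",
    "node_normal",
    "node_normals",
    "turning_angle",
    "turning_angles",
    "smoothed_turning_angles",
    "largest_empty_circle",
    "resample_contour",
    "pca_project",
]


@dataclass(frozen=True)
class Contour:
    """Closed 2D polyline outlining one cell (closing edge implicit)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"contour points must be (n, 2), got {pts.shape}")
        if len(pts) < 3:
            raise ValueError("a contour needs at least 3 points")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return len(self.points)

    def polygon(self) -> Polygon:
        """Shapely polygon view of the contour."""
        return Polygon(self.points)

    def bbox_diagonal(self) -> float:
        lo = self.points.min(axis=0)
        hi = self.points.max(axis=0)
        return float(np.hypot(*(hi - lo)))


@dataclass(frozen=True)
class Contour3D:
    """Closed 3D polyline, e.g. a cell outline on a curved organ surface."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"3D contour points must be (n, 3), got {pts.shape}")
        if len(pts) < 3:
            raise ValueError("a contour needs at least 3 points")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class LECResult:
    """Largest empty circle inside a contour: radius and center (µm)."""

    radius: float
    center: np.ndarray = field(repr=True)

    @property
    def area(self) -> float:
        return float(np.pi * self.radius**2)


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area; positive for counter-clockwise loops."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _dedupe(points: np.ndarray, tol: float) -> np.ndarray:
    d = np.linalg.norm(points - np.roll(points, 1, axis=0), axis=1)
    return points[d > tol]


def normalize_contour(c: Contour) -> Contour:
    """Canonical form: CCW orientation, consecutive duplicates removed.

    Raises ``ValueError`` for self-intersecting or degenerate input: every
    downstream metric assumes a simple polygon.
    """
    pts = c.points
    diag = Contour(pts).bbox_diagonal() if len(pts) >= 3 else 0.0
    pts = _dedupe(pts, 1e-12 * max(diag, 1.0))
    if len(pts) < 3:
        raise ValueError("degenerate contour: fewer than 3 distinct points")
    poly = Polygon(pts)
    if not poly.is_valid or poly.area == 0.0:
        raise ValueError("contour is self-intersecting or has zero area")
    if signed_area(pts) < 0:
        pts = pts[::-1].copy()
    return Contour(pts)


def polygon_area(c: Contour) -> float:
    """Enclosed area (µm²); contour must be normalized (CCW)."""
    return signed_area(c.points)


def polygon_perimeter(c: Contour) -> float:
    """Total boundary length including the closing edge (µm)."""
    d = np.linalg.norm(np.roll(c.points, -1, axis=0) - c.points, axis=1)
    return float(d.sum())


def convex_hull(c: Contour) -> Contour:
    """Convex hull as a CCW contour; vertices are a subset of the input."""
    try:
        hull = ConvexHull(c.points)
    except QhullError as exc:  # collinear input
        raise ValueError("convex hull undefined: input is collinear") from exc
    return Contour(c.points[hull.vertices])


def _edge_normals(points: np.ndarray) -> np.ndarray:
    """Outward unit normal of each edge (i -> i+1) of a CCW polygon."""
    e = np.roll(points, -1, axis=0) - points
    lens = np.linalg.norm(e, axis=1)
    if np.any(lens == 0):
        raise ValueError("zero-length segment in contour")
    n = np.column_stack([e[:, 1], -e[:, 0]]) / lens[:, None]
    return n


def node_normals(c: Contour) -> np.ndarray:
    """Outward unit normal at every node.

    Defined as the normalized bisector of the outward normals of the two
    incident wall segments.  At a (pathological) 180-degree spike the
    bisector vanishes; the trailing edge normal is used as a fallback.
    """
    en = _edge_normals(c.points)
    s = en + np.roll(en, 1, axis=0)  # edge (i-1,i) + edge (i,i+1)
    lens = np.linalg.norm(s, axis=1)
    bad = lens < 1e-12
    s[bad] = np.roll(en, 1, axis=0)[bad]
    lens = np.linalg.norm(s, axis=1)
    return s / lens[:, None]


def node_normal(c: Contour, i: int) -> np.ndarray:
    """Outward unit normal at node ``i`` (bisector rule)."""
    return node_normals(c)[i]


def turning_angles(c: Contour) -> np.ndarray:
    """Signed exterior angle at every node of a CCW contour.

    Positive where the boundary turns left (locally convex), negative in
    indentations.  The angles of a simple CCW polygon sum to 2*pi.
    """
    e = np.roll(c.points, -1, axis=0) - c.points
    e_prev = np.roll(e, 1, axis=0)
    cross = e_prev[:, 0] * e[:, 1] - e_prev[:, 1] * e[:, 0]
    dot = np.einsum("ij,ij->i", e_prev, e)
    return np.arctan2(cross, dot)


def turning_angle(c: Contour, i: int) -> float:
    return float(turning_angles(c)[i])


def smoothed_turning_angles(c: Contour, window: int = 2) -> np.ndarray:
    """Circular moving average of turning angles over ``i - w .. i + w``.

    Discretization breaks a smooth bend into many small kinks; averaging
    over a window recovers a stable local convexity signal.
    """
    t = turning_angles(c)
    if window <= 0:
        return t
    acc = t.copy()
    for k in range(1, window + 1):
        acc += np.roll(t, k) + np.roll(t, -k)
    return acc / (2 * window + 1)


def resample_contour(c: Contour, spacing: float) -> Contour:
    """Subdivide edges so no segment exceeds ``spacing``; vertices kept."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    pts = c.points
    nxt = np.roll(pts, -1, axis=0)
    out: list[np.ndarray] = []
    for a, b in zip(pts, nxt):
        length = float(np.hypot(*(b - a)))
        k = max(1, int(np.ceil(length / spacing)))
        frac = np.arange(k, dtype=float)[:, None] / k
        out.append(a + frac * (b - a))
    return Contour(np.vstack(out))


def _circumcircles(p: np.ndarray, tri: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Circumcenters and radii for an array of triangles (vertex indices)."""
    a, b, c = p[tri[:, 0]], p[tri[:, 1]], p[tri[:, 2]]
    ab, ac = b - a, c - a
    d = 2.0 * (ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0])
    # degenerate (collinear) triangles get an infinite radius; masked later
    with np.errstate(divide="ignore", invalid="ignore"):
        ab2 = np.einsum("ij,ij->i", ab, ab)
        ac2 = np.einsum("ij,ij->i", ac, ac)
        ux = (ac[:, 1] * ab2 - ab[:, 1] * ac2) / d
        uy = (ab[:, 0] * ac2 - ac[:, 0] * ab2) / d
    centers = a + np.column_stack([ux, uy])
    radii = np.linalg.norm(centers - a, axis=1)
    radii[~np.isfinite(radii)] = np.inf
    return centers, radii


def largest_empty_circle(c: Contour, spacing: float | None = None) -> LECResult:
    """Largest circle that fits inside the contour, via Delaunay triangulation.

    The boundary is resampled to at most ``spacing`` (default: 1/100 of the
    bounding-box diagonal), the Delaunay triangulation of the boundary
    samples is computed, and the largest circumscribed circle whose center
    lies strictly inside the polygon is returned.  Candidates whose best
    empty point sits on the boundary are thereby ignored, which is the
    appropriate reading for densely sampled cell outlines.
    """
    if spacing is None:
        spacing = c.bbox_diagonal() / 100.0
    dense = resample_contour(c, spacing)
    pts = dense.points
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise ValueError("degenerate polygon: Delaunay triangulation failed") from exc
    centers, radii = _circumcircles(pts, tri.simplices)
    finite = np.isfinite(radii)
    inside = np.zeros(len(radii), dtype=bool)
    poly = c.polygon()
    inside[finite] = shapely.contains_xy(poly, centers[finite, 0], centers[finite, 1])
    if not inside.any():
        raise ValueError("no circumcenter falls inside the polygon "
                         "(degenerate or needle-shaped contour)")
    masked = np.where(inside, radii, -np.inf)
    best = int(np.argmax(masked))
    return LECResult(radius=float(radii[best]), center=centers[best].copy())


def pca_project(c: Contour3D) -> Contour:
    """Project a 3D contour onto its best-fit plane.

    The plane is orthogonal to the direction of minimal variance (third
    principal component) and passes through the contour mean; the returned
    2D coordinates are expressed in the first two principal directions and
    oriented counter-clockwise.
    """
    pts = c.points
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise ValueError("contour points are collinear: projection plane undefined")
    coords = centered @ vt[:2].T
    if signed_area(coords) < 0:
        coords = coords * np.array([1.0, -1.0])
    return Contour(coords)
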