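"""Synthetic tissues and test contours.

The simulator starts from a meristematic-like template: small, convex,
roughly isodiametric polygonal cells tiling a rectangle with shared
walls.  :func:`generate_tissue` builds one as the Voronoi tessellation of
a jittered lattice of seed points, made exact on the rectangle by
mirroring the seeds across all four sides (so every interior cell is
finite and boundary cells are clipped exactly to the rectangle), with
optional Lloyd relaxation for a more even, natural look.

Also provides parametric single-cell contours for the metrics pipeline:
a disc with radial lobes (:func:`generate_lobed_disc`) and a set of named
fixture shapes contrasting lobeyness with hull solidity.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Voronoi

from .geometry import Contour, signed_area
from .model import Tissue, subdivide_walls

__all__ = ["generate_tissue", "generate_lobed_disc", "fixture_shapes"]


def _mirror(points: np.ndarray, width: float, height: float) -> np.ndarray:
    left = points * [-1, 1]
    right = points * [-1, 1] + [2 * width, 0]
    bottom = points * [1, -1]
    top = points * [1, -1] + [0, 2 * height]
    return np.vstack([points, left, right, bottom, top])


def _voronoi_cells(points: np.ndarray, width: float, height: float) -> tuple[np.ndarray, list[list[int]]]:
    """Voronoi polygons of ``points`` clipped exactly to the rectangle.

    Returns a shared vertex array and one CCW vertex-index loop per seed
    point; vertices are deduplicated so adjacent cells share node ids.
    """
    vor = Voronoi(_mirror(points, width, height))
    scale = max(width, height)
    key_of: dict[tuple[int, int], int] = {}
    verts: list[np.ndarray] = []

    def vid(v: np.ndarray) -> int:
        key = (int(round(v[0] / scale * 1e8)), int(round(v[1] / scale * 1e8)))
        if key not in key_of:
            key_of[key] = len(verts)
            verts.append(v)
        return key_of[key]

    loops: list[list[int]] = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise ValueError("unbounded Voronoi region; mirroring failed")
        poly = vor.vertices[region]
        if signed_area(poly) < 0:
            poly = poly[::-1]
        loops.append([vid(v) for v in poly])
    return np.asarray(verts), loops


def _lattice(seed: int, n_cells: int, width: float, height: float, jitter: float) -> np.ndarray:
    rng = np.random.default_rng(seed)
    aspect = width / height
    ny = max(2, int(round(np.sqrt(n_cells / aspect))))
    nx = max(2, int(round(n_cells / ny)))
    dx, dy = width / nx, height / ny
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dy
    pts = np.stack(np.meshgrid(xs, ys), axis=-1).reshape(-1, 2)
    pts = pts + rng.uniform(-jitter, jitter, size=pts.shape) * [dx, dy]
    return np.clip(pts, [0.05 * dx, 0.05 * dy], [width - 0.05 * dx, height - 0.05 * dy])


def generate_tissue(
    seed: int = 0,
    n_cells: int = 30,
    width: float = 100.0,
    height: float = 100.0,
    jitter: float = 0.25,
    lloyd_iters: int = 2,
    spacing: float = 2.0,
) -> Tissue:
    """Meristematic-like starting tissue: convex cells tiling a rectangle.

    A jittered ``~n_cells`` lattice is Voronoi-tessellated (mirrored seeds
    clip the tessellation exactly to the rectangle), relaxed by
    ``lloyd_iters`` Lloyd iterations (seeds moved to cell centroids), and
    the walls are resampled so no segment exceeds ``spacing`` µm.  A pure
    function of its arguments.
    """
    if n_cells < 4:
        raise ValueError("need at least 4 cells")
    pts = _lattice(seed, n_cells, width, height, jitter)
    for _ in range(max(0, lloyd_iters)):
        verts, loops = _voronoi_cells(pts, width, height)
        pts = np.asarray([verts[loop].mean(axis=0) for loop in loops])
    verts, loops = _voronoi_cells(pts, width, height)

    eps = 1e-9 * max(width, height)
    boundary = {
        i for i, (x, y) in enumerate(verts)
        if x < eps or y < eps or x > width - eps or y > height - eps
    }
    rest = {}
    for loop in loops:
        for a, b in zip(loop, loop[1:] + loop[:1]):
            key = (a, b) if a < b else (b, a)
            rest[key] = float(np.hypot(*(verts[b] - verts[a])))
    if min(rest.values()) <= eps:
        raise ValueError("degenerate template: zero-length wall; change seed/jitter")

    t = Tissue(
        nodes=verts, cells=loops, rest_lengths=rest, boundary_nodes=boundary,
    )
    # hinge rest angles: every template vertex keeps its initial interior
    # angle — per owning cell at junctions (so walls meeting at a junction
    # resist scissoring), once per node elsewhere
    count = t.node_cell_count()
    for ci, loop in enumerate(t.cells):
        n = len(loop)
        for k, node in enumerate(loop):
            u = verts[loop[k - 1]] - verts[node]
            v = verts[loop[(k + 1) % n]] - verts[node]
            ang = np.arctan2(v[0] * u[1] - v[1] * u[0], u @ v)
            ang = float(ang if ang >= 0 else ang + 2 * np.pi)
            if count[node] >= 3:
                t.junction_hinge_rest[(ci, node)] = ang
            elif node not in t.hinge_rest:
                t.hinge_rest[node] = ang
    subdivide_walls(t, spacing)
    return t


def generate_lobed_disc(
    radius: float = 10.0,
    n_lobes: int = 0,
    lobe_length: float = 4.0,
    lobe_width: float = 3.0,
    n_points: int = 400,
) -> Contour:
    """Disc of given radius with ``n_lobes`` evenly spaced radial lobes.

    Lobes are smooth Gaussian bumps of the polar radius; ``n_lobes = 0``
    gives a plain circle.  The central disc is untouched by lobe length,
    so its largest empty circle stays at ~``radius`` however long the
    lobes grow.
    """
    if n_lobes < 0:
        raise ValueError("n_lobes must be >= 0")
    if n_lobes > 0 and n_lobes * lobe_width * 2 > 2 * np.pi * radius:
        raise ValueError("lobes overlap: reduce n_lobes or lobe_width")
    phi = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    r = np.full(n_points, float(radius))
    if n_lobes > 0:
        sigma = lobe_width / (2.0 * radius)  # angular half-width
        centers = np.linspace(0, 2 * np.pi, n_lobes, endpoint=False)
        for c in centers:
            d = np.angle(np.exp(1j * (phi - c)))
            r += lobe_length * np.exp(-0.5 * (d / sigma) ** 2)
    return Contour(np.column_stack([r * np.cos(phi), r * np.sin(phi)]))


def fixture_shapes() -> dict[str, Contour]:
    """Named reference contours used across the test-suite and docs.

    ``plus`` is the 3x3-grid cross (lobeyness 12 / (4 + 4*sqrt(2)),
    hull solidity 1.4); ``boomerang`` and ``worm`` are thin bent bands —
    nearly convex by lobeyness yet far from their hulls, the classic
    failure mode of hull solidity as a lobation measure.
    """
    square = Contour(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
    rect = Contour(np.array([[0, 0], [5, 0], [5, 1], [0, 1]], float))
    plus = Contour(np.array([
        [1, 0], [2, 0], [2, 1], [3, 1], [3, 2], [2, 2],
        [2, 3], [1, 3], [1, 2], [0, 2], [0, 1], [1, 1],
    ], float))

    def band(center_angles: np.ndarray, radius: float, half_width: float) -> Contour:
        spine = np.column_stack([radius * np.cos(center_angles),
                                 radius * np.sin(center_angles)])
        tangent = np.gradient(spine, axis=0)
        tangent /= np.linalg.norm(tangent, axis=1)[:, None]
        normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])
        top = spine + half_width * normal
        bot = spine - half_width * normal
        return Contour(np.vstack([top, bot[::-1]]))

    from .geometry import normalize_contour

    boomerang = normalize_contour(
        band(np.linspace(-0.85 * np.pi, -0.15 * np.pi, 48), 10.0, 0.6))
    worm = normalize_contour(
        band(np.linspace(-0.95 * np.pi, 0.45 * np.pi, 80), 6.0, 0.5))
    return {
        "square": square,
        "rect5x1": rect,
        "plus": plus,
        "boomerang": boomerang,
        "worm": worm,
    }
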