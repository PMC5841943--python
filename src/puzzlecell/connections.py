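"""Placement and retirement of transversal springs.

The growth-restricting connections stand in for cortical-microtubule
guided cellulose deposition responding to wall stress.  At every
reassignment the springs of each cell are rebuilt from its current
shape:

* each wall node connects to the *closest* node across the same cell
  whose chord direction lies within a cone of half-angle ``theta_micro``
  around the outward normals of *both* endpoints;
* candidate pairs closer than ``s_min`` positions along the contour are
  excluded (a chord must cross the cell, not hug the wall);
* the chord must lie inside the cell polygon;
* nodes on locally convex wall (smoothed turning angle above
  ``kappa_convex``) neither initiate nor accept connections — lobe tips
  shed their restrictions, which is what lets lobes keep growing.  The
  *spk1* variant switches this inhibition off, so connections invade the
  lobes and simple, worm-like interdigitation results instead.

A new spring's reference length is ``max(current chord length,
min_micro)``: it only starts to pull once the span it guards exceeds the
target largest-empty-circle size, and growth never updates it.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import Polygon

from .geometry import Contour, node_normals, smoothed_turning_angles
from .model import SimulationParams, Tissue, TransversalSpring

__all__ = ["place_connections", "spring_force"]


def spring_force(s: TransversalSpring, current_length: float, k_m: float) -> float:
    """Tension-only spring law: ``k * (l - l_ref)`` when stretched, else 0."""
    ext = current_length - s.ref_length
    if ext <= 0:
        return 0.0
    return k_m * s.stiffness * ext


def _cell_springs(
    ci: int, loop: list[int], pts: np.ndarray, p: SimulationParams
) -> list[TransversalSpring]:
    n = len(pts)
    if n < 2 * p.s_min:
        return []
    contour = Contour(pts)
    normals = node_normals(contour)
    kappa = smoothed_turning_angles(contour, p.convex_window)
    eligible = np.ones(n, dtype=bool)
    if not p.spk1_mode:
        eligible = kappa <= p.kappa_convex

    # pairwise geometry
    diff = pts[None, :, :] - pts[:, None, :]          # a -> b
    dist = np.linalg.norm(diff, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = diff / dist[:, :, None]

    cos_theta = np.cos(p.theta_micro)
    # a chord runs across the cell: direction a->b must lie within the cone
    # around a's inward normal, and b->a within the cone around b's inward
    # normal
    dot_a = np.einsum("abk,ak->ab", -unit, normals)
    dot_b = np.einsum("abk,bk->ab", unit, normals)
    ok = (dot_a >= cos_theta) & (dot_b >= cos_theta)

    idx = np.arange(n)
    sep = np.abs(idx[None, :] - idx[:, None])
    sep = np.minimum(sep, n - sep)
    ok &= sep >= p.s_min
    ok &= eligible[:, None] & eligible[None, :]

    poly = Polygon(pts)
    shapely.prepare(poly)
    springs: list[TransversalSpring] = []
    chord_ok_cache: dict[tuple[int, int], bool] = {}
    for a in range(n):
        cand = np.flatnonzero(ok[a])
        if len(cand) == 0:
            continue
        # closest admissible partner; ties broken by lowest node index
        order = cand[np.lexsort((cand, dist[a, cand]))]
        for b in order:
            key = (min(a, b), max(a, b))
            inside = chord_ok_cache.get(key)
            if inside is None:
                chord = shapely.LineString([pts[a], pts[b]])
                inside = bool(poly.covers(chord))
                chord_ok_cache[key] = inside
            if inside:
                springs.append(
                    TransversalSpring(
                        cell_id=ci,
                        node_a=int(loop[a]),
                        node_b=int(loop[int(b)]),
                        ref_length=float(max(dist[a, b], p.min_micro)),
                    )
                )
                break
    # one physical connection per unordered pair
    seen: set[tuple[int, int]] = set()
    unique: list[TransversalSpring] = []
    for s in springs:
        key = (min(s.node_a, s.node_b), max(s.node_a, s.node_b))
        if key not in seen:
            seen.add(key)
            unique.append(s)
    return unique


def place_connections(t: Tissue, p: SimulationParams) -> Tissue:
    """Rebuild the transversal springs of every cell from its current shape.

    All previous springs are discarded; the procedure is a deterministic
    function of the tissue state and parameters.  Nodes with no admissible
    partner simply receive no spring.  Modifies ``t`` in place and returns
    it.
    """
    springs: list[TransversalSpring] = []
    for ci, loop in enumerate(t.cells):
        pts = t.nodes[loop]
        springs.extend(_cell_springs(ci, loop, pts, p))
    t.springs = springs
    return t
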