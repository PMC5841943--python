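"""State containers for the simulated tissue and the model parameters.

A :class:`Tissue` is a shared-node polygonal cell complex: wall nodes are
point masses, wall segments between consecutive nodes act as linear
springs, non-junction nodes carry a bending hinge, and tension-only
:class:`TransversalSpring` elements span cell interiors (the
microtubule-guided cellulose proxy).  Topology (cell count and adjacency)
is fixed for the lifetime of a simulation; only node positions, wall
subdivision, rest lengths and the transversal springs change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from shapely.geometry import Polygon

from .geometry import Contour, signed_area

__all__ = [
    "Tissue",
    "TransversalSpring",
    "SimulationParams",
    "validate",
    "subdivide_walls",
    "tissue_to_json",
    "tissue_from_json",
]

GrowthFactor = "float | Callable[[np.ndarray], np.ndarray]"

SCHEMA = "puzzlecell-tissue/1"


@dataclass
class TransversalSpring:
    """One-sided (tension-only) connection across a cell interior.

    Represents a bundle of microtubule-guided cellulose reinforcement:
    it resists stretching beyond its reference length but exerts no force
    when shorter.  ``ref_length`` is fixed at placement and is unaffected
    by growth until the spring is replaced.
    """

    cell_id: int
    node_a: int
    node_b: int
    ref_length: float
    stiffness: float = 1.0  # multiplier on the global k_m

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise ValueError("transversal spring endpoints must differ")
        if self.ref_length <= 0:
            raise ValueError("ref_length must be positive")


@dataclass
class SimulationParams:
    """All model constants.

    Stiffnesses are in force units per unit strain (walls) or per unit
    extension (transversal springs and hinges); lengths in µm; angles in
    radians.  The defaults are calibrated to the puzzle-cell regime under
    isotropic growth, see docs/methods.md for the rationale per value.
    """

    k_s: float = 1.0            # wall stretching stiffness (per unit strain)
    k_b: float = 0.2            # bending stiffness at wall hinges
    k_m: float = 0.3            # transversal (cellulose) spring stiffness
    min_micro: float = 20.0     # target LEC span (µm, ~diameter): chords activate beyond it
    theta_micro: float = 0.35   # half-angle of the normal cone for pairing (rad)
    kappa_convex: float = 0.05  # smoothed turning angle above which a node counts convex
    convex_window: int = 2      # +-window (nodes) for turning-angle smoothing
    s_min: int = 5              # minimum contour separation (nodes) for a chord
    reset_period: int = 1       # steps between connection reassignment
    g_x: float | Callable = 1.04  # per-step growth factor in x (may be f(template_x))
    g_y: float | Callable = 1.04  # per-step growth factor in y (may be f(template_x))
    max_segment: float = 2.0    # wall subdivision length (µm)
    solver_tol: float = 1e-3    # max residual force per free node at equilibrium
    max_iter: int = 3000        # equilibration iteration budget
    n_steps: int = 30           # growth steps per run
    seed: int = 0               # template generation seed (the loop is deterministic)
    spk1_mode: bool = False     # disable the convexity inhibition of connections
    strain_normalized: bool = True  # wall energy per unit rest length (subdivision-safe)
    solver: str = "lbfgs"       # "lbfgs" (quasi-Newton) or "descent" (monotone)

    def __post_init__(self) -> None:
        for name in ("k_s", "k_b", "k_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.theta_micro < np.pi / 2:
            raise ValueError("theta_micro must be in (0, pi/2)")
        if self.reset_period < 1:
            raise ValueError("reset_period must be >= 1")
        for name in ("g_x", "g_y"):
            g = getattr(self, name)
            if not callable(g) and g < 1:
                raise ValueError("growth factors must be >= 1")
        if self.max_segment <= 0 or self.min_micro <= 0:
            raise ValueError("lengths must be positive")

    def updated(self, **kwargs) -> "SimulationParams":
        return replace(self, **kwargs)


def _edge_key(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


@dataclass
class Tissue:
    """Shared-node polygonal cell complex (the simulator state).

    Attributes
    ----------
    nodes : (N, 2) float array of positions (µm).
    cells : list of CCW node-index loops, one per cell (closing edge implicit).
    rest_lengths : per-wall-segment rest length, keyed by sorted node pair.
    springs : active transversal springs.
    boundary_nodes : node indices on the tissue outline (pinned during
        equilibration; they follow the imposed tissue growth).
    template_x : per-node material x-coordinate, frozen at template
        creation; growth-gradient laws are functions of this so the
        displacement map stays continuous as nodes move.
    hinge_rest : rest angle of the bending hinge at each non-junction
        node.
    junction_hinge_rest : per-cell rest angles at junction nodes (shared
        by >= 3 cells), keyed ``(cell_index, node)``; these corner hinges
        keep the walls meeting at a junction from scissoring through each
        other.
    """

    nodes: np.ndarray
    cells: list[list[int]]
    rest_lengths: dict[tuple[int, int], float]
    springs: list[TransversalSpring] = field(default_factory=list)
    boundary_nodes: set[int] = field(default_factory=set)
    template_x: np.ndarray | None = None
    hinge_rest: dict[int, float] = field(default_factory=dict)
    junction_hinge_rest: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.template_x is None:
            self.template_x = self.nodes[:, 0].copy()

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def copy(self) -> "Tissue":
        return Tissue(
            nodes=self.nodes.copy(),
            cells=[list(loop) for loop in self.cells],
            rest_lengths=dict(self.rest_lengths),
            springs=[replace(s) for s in self.springs],
            boundary_nodes=set(self.boundary_nodes),
            template_x=self.template_x.copy(),
            hinge_rest=dict(self.hinge_rest),
            junction_hinge_rest=dict(self.junction_hinge_rest),
        )

    # -- derived structure ------------------------------------------------

    def edges(self) -> dict[tuple[int, int], list[int]]:
        """Undirected wall segments -> owning cell indices."""
        owners: dict[tuple[int, int], list[int]] = {}
        for ci, loop in enumerate(self.cells):
            for a, b in zip(loop, loop[1:] + loop[:1]):
                owners.setdefault(_edge_key(a, b), []).append(ci)
        return owners

    def node_cell_count(self) -> np.ndarray:
        count = np.zeros(self.n_nodes, dtype=int)
        for loop in self.cells:
            count[loop] += 1
        return count

    def cell_contour(self, ci: int) -> Contour:
        return Contour(self.nodes[self.cells[ci]])

    def cell_is_interior(self, ci: int) -> bool:
        return not any(n in self.boundary_nodes for n in self.cells[ci])

    def hinges(self) -> tuple[np.ndarray, np.ndarray]:
        """Bending hinge triples ``(prev, node, next)`` and rest angles.

        Each hinged wall node contributes exactly one triple, taken from
        the first cell loop that contains it (for a two-cell wall node
        the interior angles on the two sides sum to 2*pi, so the choice
        does not affect the energy for the straight rest state).
        Junction nodes contribute one triple per owning cell, with the
        per-cell rest angle from ``junction_hinge_rest``.
        """
        triples: list[tuple[int, int, int]] = []
        rests: list[float] = []
        seen: set[int] = set()
        for ci, loop in enumerate(self.cells):
            n = len(loop)
            for k, node in enumerate(loop):
                if (ci, node) in self.junction_hinge_rest:
                    triples.append((loop[k - 1], node, loop[(k + 1) % n]))
                    rests.append(self.junction_hinge_rest[(ci, node)])
                    continue
                if node in seen or node not in self.hinge_rest:
                    continue
                seen.add(node)
                triples.append((loop[k - 1], node, loop[(k + 1) % n]))
                rests.append(self.hinge_rest[node])
        if not triples:
            return np.empty((0, 3), dtype=int), np.empty(0)
        return np.asarray(triples, dtype=int), np.asarray(rests)


def validate(t: Tissue) -> list[str]:
    """Diagnostic invariant check; returns a list of violations (empty if OK)."""
    report: list[str] = []
    if not np.all(np.isfinite(t.nodes)):
        report.append("non-finite node positions")
    for ci, loop in enumerate(t.cells):
        if len(loop) < 3:
            report.append(f"cell {ci}: fewer than 3 nodes")
            continue
        if len(set(loop)) != len(loop):
            report.append(f"cell {ci}: repeated node in loop")
            continue
        pts = t.nodes[loop]
        if signed_area(pts) <= 0:
            report.append(f"cell {ci}: loop not counter-clockwise")
        if not Polygon(pts).is_valid:
            report.append(f"cell {ci}: loop is not a simple polygon")
    owners = t.edges()
    for edge, cells in owners.items():
        if len(cells) > 2:
            report.append(f"wall {edge}: owned by {len(cells)} cells")
        if edge not in t.rest_lengths:
            report.append(f"wall {edge}: missing rest length")
        elif t.rest_lengths[edge] <= 0:
            report.append(f"wall {edge}: non-positive rest length")
    cell_sets = [set(loop) for loop in t.cells]
    for s in t.springs:
        if not (0 <= s.cell_id < t.n_cells):
            report.append(f"spring {s.node_a}-{s.node_b}: unknown cell {s.cell_id}")
        elif s.node_a not in cell_sets[s.cell_id] or s.node_b not in cell_sets[s.cell_id]:
            report.append(
                f"spring {s.node_a}-{s.node_b}: endpoint not on cell {s.cell_id}"
            )
    return report


def subdivide_walls(t: Tissue, max_segment: float) -> None:
    """Split every wall segment longer than ``max_segment`` in place.

    New nodes are spaced evenly along the old segment, inherit an
    interpolated material coordinate, lie on the boundary iff the wall
    does, and get a straight (pi) bending rest angle — exact at creation
    since they are collinear with their neighbours.
    """
    owners = t.edges()
    insertions: dict[tuple[int, int], list[int]] = {}
    new_nodes: list[np.ndarray] = []
    new_tx: list[float] = []
    next_id = t.n_nodes
    for (a, b), own in owners.items():
        pa, pb = t.nodes[a], t.nodes[b]
        length = float(np.hypot(*(pb - pa)))
        pieces = int(np.ceil(length / max_segment))
        if pieces <= 1:
            continue
        ids = list(range(next_id, next_id + pieces - 1))
        next_id += pieces - 1
        frac = np.arange(1, pieces) / pieces
        for f, nid in zip(frac, ids):
            new_nodes.append(pa + f * (pb - pa))
            new_tx.append(float(t.template_x[a] + f * (t.template_x[b] - t.template_x[a])))
            t.hinge_rest[nid] = np.pi
            if len(own) == 1 and a in t.boundary_nodes and b in t.boundary_nodes:
                t.boundary_nodes.add(nid)
        insertions[(a, b)] = ids
        old_rest = t.rest_lengths.pop(_edge_key(a, b))
        chain = [a] + ids + [b]
        for u, v in zip(chain, chain[1:]):
            t.rest_lengths[_edge_key(u, v)] = old_rest / pieces
    if not new_nodes:
        return
    t.nodes = np.vstack([t.nodes, np.asarray(new_nodes)])
    t.template_x = np.concatenate([t.template_x, np.asarray(new_tx)])
    for ci, loop in enumerate(t.cells):
        out: list[int] = []
        n = len(loop)
        for k in range(n):
            a, b = loop[k], loop[(k + 1) % n]
            out.append(a)
            if (a, b) in insertions:
                out.extend(insertions[(a, b)])
            elif (b, a) in insertions:
                out.extend(reversed(insertions[(b, a)]))
        t.cells[ci] = out


# -- serialization --------------------------------------------------------


def tissue_to_json(t: Tissue) -> str:
    doc = {
        "schema": SCHEMA,
        "nodes": t.nodes.tolist(),
        "cells": [list(map(int, loop)) for loop in t.cells],
        "boundary": sorted(int(i) for i in t.boundary_nodes),
        "template_x": t.template_x.tolist(),
        "rest_lengths": [[int(i), int(j), l] for (i, j), l in sorted(t.rest_lengths.items())],
        "hinge_rest": [[int(i), r] for i, r in sorted(t.hinge_rest.items())],
        "junction_hinge_rest": [
            [int(ci), int(i), r] for (ci, i), r in sorted(t.junction_hinge_rest.items())
        ],
        "springs": [
            {
                "cell_id": int(s.cell_id),
                "node_a": int(s.node_a),
                "node_b": int(s.node_b),
                "ref_length": s.ref_length,
                "stiffness": s.stiffness,
            }
            for s in t.springs
        ],
    }
    return json.dumps(doc)


def tissue_from_json(text: str) -> Tissue:
    doc = json.loads(text)
    if doc.get("schema") != SCHEMA:
        raise ValueError(f"unsupported tissue schema: {doc.get('schema')!r}")
    return Tissue(
        nodes=np.asarray(doc["nodes"], dtype=float),
        cells=[list(loop) for loop in doc["cells"]],
        rest_lengths={_edge_key(i, j): l for i, j, l in doc["rest_lengths"]},
        springs=[TransversalSpring(**s) for s in doc["springs"]],
        boundary_nodes=set(doc["boundary"]),
        template_x=np.asarray(doc["template_x"], dtype=float),
        hinge_rest={int(i): r for i, r in doc["hinge_rest"]},
        junction_hinge_rest={
            (int(ci), int(i)): r for ci, i, r in doc.get("junction_hinge_rest", [])
        },
    )
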