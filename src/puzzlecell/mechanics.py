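"""Mechanical equilibrium of the wall/hinge/spring network.

Forces on a wall node come from three element types:

* stretching of the two incident wall segments, with energy
  ``1/2 * k_s * (l - l0)^2 / l0`` per segment (strain-normalized, so
  subdividing a wall leaves its stiffness unchanged; an extension-based
  variant without the ``1/l0`` is switchable via
  ``SimulationParams.strain_normalized``),
* bending at the node's hinge, ``1/2 * k_b * (theta - theta0)^2`` with
  ``theta`` the interior angle between the incident segments — this
  penalizes sharp kinks in the wall,
* tension-only transversal springs, ``1/2 * k_m * max(0, l - l_ref)^2``:
  slack springs contribute exactly zero energy and force.

A short-range self-contact penalty between each node and the
non-adjacent wall segments of the same cell (``1/2 * k_c * (r_c - d)^2``
for node-to-segment distance ``d < r_c``) gives the wall an effective
thickness: opposing flanks of a narrowing neck rest on each other
instead of passing through.  Contact candidates are re-detected between
solver rounds.

Equilibration moves the free (interior) nodes to a force balance while
the tissue-outline nodes stay pinned at their post-growth positions: the
tissue-scale growth is imposed, and unopposed contracting springs would
otherwise shrink the whole domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from shapely.geometry import Polygon

from .model import SimulationParams, Tissue

__all__ = ["total_energy", "forces", "equilibrate", "EquilibriumInfo", "ConvergenceWarning"]


class ConvergenceWarning(UserWarning):
    """Equilibration stopped at the iteration budget with residual > tol."""


@dataclass
class EquilibriumInfo:
    residual: float
    iterations: int
    energy: float
    converged: bool


class _Network:
    """Flat element arrays extracted from a Tissue, for vectorized evaluation."""

    def __init__(self, t: Tissue, p: SimulationParams):
        edges = sorted(t.edges().keys())
        self.edge_idx = np.asarray(edges, dtype=int).reshape(-1, 2)
        self.edge_rest = np.asarray([t.rest_lengths[e] for e in edges])
        self.hinge_idx, self.hinge_rest = t.hinges()
        if t.springs:
            self.spring_idx = np.asarray([[s.node_a, s.node_b] for s in t.springs], dtype=int)
            self.spring_ref = np.asarray([s.ref_length for s in t.springs])
            self.spring_k = p.k_m * np.asarray([s.stiffness for s in t.springs])
        else:
            self.spring_idx = np.empty((0, 2), dtype=int)
            self.spring_ref = np.empty(0)
            self.spring_k = np.empty(0)
        self.p = p
        self.n_nodes = t.n_nodes
        if p.strain_normalized:
            self._edge_coeff = p.k_s / self.edge_rest
        else:
            self._edge_coeff = np.full_like(self.edge_rest, p.k_s)
        self.contact_cutoff = 0.8 * p.max_segment
        self.contact_k = 20.0 * p.k_s
        self.contact_idx = self._detect_contacts(t)

    def _detect_contacts(self, t: Tissue) -> np.ndarray:
        """Node-vs-wall-segment contact candidates within one cell.

        Rows are ``(node, seg_start, seg_end)`` triples where the node lies
        close in space to a wall segment of the same cell at least 2
        positions away along the contour.  The search margin of 2x the
        cutoff leaves room for nodes to move during the equilibration the
        list is frozen for.
        """
        triples: set[tuple[int, int, int]] = set()
        for loop in t.cells:
            n = len(loop)
            if n < 10:
                continue
            pts = t.nodes[loop]
            seg_vec = np.roll(pts, -1, axis=0) - pts
            mids = pts + 0.5 * seg_vec
            # search radius covers the longest half-segment in this cell
            reach = 2.0 * self.contact_cutoff + 0.5 * float(
                np.linalg.norm(seg_vec, axis=1).max()
            )
            tree = cKDTree(pts)
            for m, near in enumerate(tree.query_ball_point(mids, reach)):
                for k in near:
                    sep = min(
                        abs(k - m), n - abs(k - m),
                        abs(k - (m + 1) % n), n - abs(k - (m + 1) % n),
                    )
                    if sep < 2:
                        continue
                    triples.add((loop[k], loop[m], loop[(m + 1) % n]))
        if not triples:
            return np.empty((0, 3), dtype=int)
        return np.asarray(sorted(triples), dtype=int)

    # -- energy and gradient ------------------------------------------------

    def energy_grad(self, pos: np.ndarray) -> tuple[float, np.ndarray]:
        p = self.p
        energy = 0.0
        idx_parts: list[np.ndarray] = []
        val_parts: list[np.ndarray] = []

        # wall stretching
        i, j = self.edge_idx[:, 0], self.edge_idx[:, 1]
        d = pos[j] - pos[i]
        l = np.sqrt(np.einsum("ij,ij->i", d, d))
        rest = self.edge_rest
        coeff = self._edge_coeff
        dl = l - rest
        energy += 0.5 * float(np.sum(coeff * dl**2))
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = d / l[:, None]
        unit[~np.isfinite(unit)] = 0.0
        f = (coeff * dl)[:, None] * unit  # dE/d(pos_j)
        idx_parts += [j, i]
        val_parts += [f, -f]

        # transversal springs (tension-only)
        if len(self.spring_idx):
            a, b = self.spring_idx[:, 0], self.spring_idx[:, 1]
            d = pos[b] - pos[a]
            l = np.sqrt(np.einsum("ij,ij->i", d, d))
            ext = np.maximum(0.0, l - self.spring_ref)
            energy += 0.5 * float(np.sum(self.spring_k * ext**2))
            with np.errstate(invalid="ignore", divide="ignore"):
                unit = d / l[:, None]
            unit[~np.isfinite(unit)] = 0.0
            f = (self.spring_k * ext)[:, None] * unit
            idx_parts += [b, a]
            val_parts += [f, -f]

        # self-contact repulsion: node vs wall segment, one-sided, short
        # range.  The closest-point parameter tt minimizes the distance, so
        # by the envelope theorem the gradient can treat tt as constant.
        if len(self.contact_idx):
            ni, sa, sb = self.contact_idx.T
            pn, pa, pb = pos[ni], pos[sa], pos[sb]
            e = pb - pa
            ee = np.einsum("ij,ij->i", e, e)
            with np.errstate(invalid="ignore", divide="ignore"):
                tt = (np.einsum("ij,ij->i", pn - pa, e) / ee)
            tt[~np.isfinite(tt)] = 0.0
            np.clip(tt, 0.0, 1.0, out=tt)
            d = pn - pa - tt[:, None] * e
            l = np.sqrt(np.einsum("ij,ij->i", d, d))
            overlap = np.maximum(0.0, self.contact_cutoff - l)
            if np.any(overlap > 0):
                energy += 0.5 * self.contact_k * float(np.sum(overlap**2))
                with np.errstate(invalid="ignore", divide="ignore"):
                    unit = d / l[:, None]
                unit[~np.isfinite(unit)] = 0.0
                f = (self.contact_k * overlap)[:, None] * unit  # -dE/d(pn)
                idx_parts += [ni, sa, sb]
                val_parts += [-f, (1.0 - tt)[:, None] * f, tt[:, None] * f]

        # bending hinges
        if len(self.hinge_idx):
            hi, hj, hk = self.hinge_idx.T
            u = pos[hi] - pos[hj]
            v = pos[hk] - pos[hj]
            # interior angle of a CCW loop, measured from the outgoing edge
            # (towards next) to the incoming edge (towards prev); in (0, 2*pi)
            cross = v[:, 0] * u[:, 1] - v[:, 1] * u[:, 0]
            dot = np.einsum("ij,ij->i", u, v)
            theta = np.arctan2(cross, dot)
            theta = np.where(theta < 0, theta + 2 * np.pi, theta)
            dtheta = theta - self.hinge_rest
            energy += 0.5 * p.k_b * float(np.sum(dtheta**2))
            denom = cross**2 + dot**2
            with np.errstate(invalid="ignore", divide="ignore"):
                dth_du = np.column_stack([
                    (-dot * v[:, 1] - cross * v[:, 0]) / denom,
                    (dot * v[:, 0] - cross * v[:, 1]) / denom,
                ])
                dth_dv = np.column_stack([
                    (dot * u[:, 1] - cross * u[:, 0]) / denom,
                    (-dot * u[:, 0] - cross * u[:, 1]) / denom,
                ])
            dth_du[~np.isfinite(dth_du)] = 0.0
            dth_dv[~np.isfinite(dth_dv)] = 0.0
            w = (p.k_b * dtheta)[:, None]
            idx_parts += [hi, hk, hj]
            val_parts += [w * dth_du, w * dth_dv, -w * (dth_du + dth_dv)]

        idx = np.concatenate(idx_parts)
        vals = np.concatenate(val_parts)
        grad = np.column_stack([
            np.bincount(idx, weights=vals[:, 0], minlength=self.n_nodes),
            np.bincount(idx, weights=vals[:, 1], minlength=self.n_nodes),
        ])
        return energy, grad


def total_energy(t: Tissue, p: SimulationParams) -> float:
    """Total elastic energy of the tissue in its current configuration."""
    if not np.all(np.isfinite(t.nodes)):
        raise ValueError("non-finite node positions")
    e, _ = _Network(t, p).energy_grad(t.nodes)
    return e


def forces(t: Tissue, p: SimulationParams) -> np.ndarray:
    """Analytic force on every node (negative energy gradient), (N, 2)."""
    _, g = _Network(t, p).energy_grad(t.nodes)
    return -g


def _invalid_cells(t: Tissue, pos: np.ndarray) -> set[int]:
    return {
        ci for ci, loop in enumerate(t.cells)
        if not Polygon(pos[loop]).is_valid
    }


def _residual(grad: np.ndarray, free: np.ndarray) -> float:
    if not free.any():
        return 0.0
    return float(np.linalg.norm(grad[free], axis=1).max())


def equilibrate(t: Tissue, p: SimulationParams) -> Tissue:
    """Relax the free nodes to mechanical equilibrium (in place).

    Boundary (outline) nodes are pinned; interior nodes move until the
    largest per-node force falls below ``p.solver_tol`` or the iteration
    budget runs out, in which case a :class:`ConvergenceWarning` reporting
    the residual is emitted.  ``p.solver`` selects between a quasi-Newton
    minimizer (``"lbfgs"``, default) and a damped first-order descent with
    adaptive step (``"descent"``) whose accepted steps are strictly
    energy-decreasing.

    Returns the tissue (same object) with ``t.equilibrium`` set to an
    :class:`EquilibriumInfo`.
    """
    free = np.ones(t.n_nodes, dtype=bool)
    free[list(t.boundary_nodes)] = False
    pos = t.nodes.copy()

    net = _Network(t, p)
    e0, g0 = net.energy_grad(pos)
    res = _residual(g0, free)
    if res < p.solver_tol or not free.any():
        t.equilibrium = EquilibriumInfo(res, 0, e0, True)
        return t

    total_iters = 0
    info = EquilibriumInfo(res, 0, e0, False)
    # outer rounds: the contact pair list is frozen per solve, so re-detect
    # contacts from the moved configuration and re-solve until stable
    for _ in range(4):
        if p.solver == "lbfgs":
            pos, info = _solve_lbfgs(net, pos, free, p)
            # L-BFGS terminates on its own projected-gradient test; polish
            # with monotone descent if the per-node residual is still high
            if not info.converged or info.residual >= p.solver_tol:
                pos, info2 = _solve_fire(
                    net, pos, free, p, max_iter=p.max_iter,
                    dmax=0.25 * net.contact_cutoff,
                )
                info = EquilibriumInfo(
                    info2.residual, info.iterations + info2.iterations,
                    info2.energy, info2.converged,
                )
        elif p.solver == "descent":
            pos, info = _solve_descent(net, pos, free, p, max_iter=p.max_iter)
        else:
            raise ValueError(f"unknown solver {p.solver!r}")
        total_iters += info.iterations
        t_moved = t.copy()
        t_moved.nodes = pos
        new_contacts = net._detect_contacts(t_moved)
        if np.array_equal(new_contacts, net.contact_idx):
            break  # same problem again would not improve a stalled solve
        net.contact_idx = new_contacts
        e, g = net.energy_grad(pos)
        info = EquilibriumInfo(_residual(g, free), total_iters, e,
                               _residual(g, free) < p.solver_tol)
        if info.converged:
            break
    info = EquilibriumInfo(info.residual, total_iters, info.energy, info.converged)

    # anti-tunnelling guard: a quasi-Newton line search can step clean
    # across the thin contact barrier and settle in a self-intersecting
    # minimum.  If the solve created a newly invalid cell outline, redo it
    # with displacement-capped monotone descent, which has to climb the
    # barrier and therefore cannot cross it.
    if p.solver != "descent":
        invalid_before = _invalid_cells(t, t.nodes)
        if _invalid_cells(t, pos) - invalid_before:
            net.contact_idx = net._detect_contacts(t)
            dmax = 0.25 * net.contact_cutoff
            pos2 = t.nodes.copy()
            iters2 = 0
            for _ in range(3):
                pos2, info2 = _solve_fire(
                    net, pos2, free, p, max_iter=p.max_iter, dmax=dmax
                )
                iters2 += info2.iterations
                t_moved = t.copy()
                t_moved.nodes = pos2
                new_contacts = net._detect_contacts(t_moved)
                if np.array_equal(new_contacts, net.contact_idx) and info2.converged:
                    break
                net.contact_idx = new_contacts
            if not (_invalid_cells(t, pos2) - invalid_before):
                pos = pos2
                info = EquilibriumInfo(
                    info2.residual, total_iters + iters2, info2.energy,
                    info2.converged,
                )

    if not info.converged:
        warnings.warn(
            f"equilibrate: residual {info.residual:.3g} > tol {p.solver_tol:.3g} "
            f"after {info.iterations} iterations",
            ConvergenceWarning,
            stacklevel=2,
        )
    t.nodes = pos
    t.equilibrium = info
    return t


def _solve_lbfgs(net, pos, free, p) -> tuple[np.ndarray, EquilibriumInfo]:
    fixed = pos[~free]
    x0 = pos[free].ravel()

    def fun(x):
        full = np.empty_like(pos)
        full[free] = x.reshape(-1, 2)
        full[~free] = fixed
        e, g = net.energy_grad(full)
        return e, g[free].ravel()

    out = minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": p.max_iter, "gtol": p.solver_tol / 4, "ftol": 1e-16},
    )
    full = np.empty_like(pos)
    full[free] = out.x.reshape(-1, 2)
    full[~free] = fixed
    e, g = net.energy_grad(full)
    res = _residual(g, free)
    return full, EquilibriumInfo(res, int(out.nit), e, res < p.solver_tol)


def _solve_fire(
    net, pos, free, p, max_iter: int, dmax: float
) -> tuple[np.ndarray, EquilibriumInfo]:
    """FIRE (fast inertial relaxation engine) with a displacement cap.

    Inertial descent that accelerates while moving downhill and restarts
    on uphill power; the per-node displacement cap keeps it from stepping
    across the self-contact barrier.
    """
    pos = pos.copy()
    v = np.zeros_like(pos)
    e, g = net.energy_grad(pos)
    res = _residual(g, free)
    k_scale = max(
        p.k_s / max(p.max_segment, 1e-9), p.k_m, p.k_b, net.contact_k, 1e-12
    )
    dt = 0.1 / np.sqrt(k_scale)
    dt_max = 10.0 * dt
    alpha0, alpha, n_pos = 0.1, 0.1, 0
    it = 0
    best_res, best_it = res, 0
    while res >= p.solver_tol and it < max_iter:
        it += 1
        # frustrated contact clusters can pin the residual above tol; stop
        # burning budget once progress has stalled
        if res < 0.99 * best_res:
            best_res, best_it = res, it
        elif it - best_it > 300:
            break
        f = -g
        power = float(np.sum(f[free] * v[free]))
        if power > 0:
            n_pos += 1
            fnorm = float(np.linalg.norm(f[free]))
            vnorm = float(np.linalg.norm(v[free]))
            if fnorm > 0:
                v[free] = (1 - alpha) * v[free] + alpha * (vnorm / fnorm) * f[free]
            if n_pos > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
        else:
            v[:] = 0.0
            dt *= 0.5
            alpha, n_pos = alpha0, 0
        v[free] += dt * f[free]
        move = dt * v[free]
        norms = np.linalg.norm(move, axis=1)
        over = norms > dmax
        if over.any():
            move[over] *= (dmax / norms[over])[:, None]
        pos[free] += move
        e, g = net.energy_grad(pos)
        res = _residual(g, free)
    return pos, EquilibriumInfo(res, it, e, res < p.solver_tol)


def _solve_descent(
    net, pos, free, p, max_iter: int, dmax: float | None = None
) -> tuple[np.ndarray, EquilibriumInfo]:
    """Damped gradient descent; only energy-decreasing steps are accepted.

    With ``dmax`` set, no node moves further than ``dmax`` in a single
    step, so the iteration cannot jump across the thin self-contact
    barrier into an interpenetrating minimum.
    """
    pos = pos.copy()
    e, g = net.energy_grad(pos)
    res = _residual(g, free)
    # initial step from the dominant stiffness scale
    k_scale = max(p.k_s / max(p.max_segment, 1e-9), p.k_m, p.k_b, net.contact_k, 1e-12)
    step = 0.1 / k_scale
    it = 0
    best_res, best_it = res, 0
    while res >= p.solver_tol and it < max_iter:
        it += 1
        if res < 0.99 * best_res:
            best_res, best_it = res, it
        elif it - best_it > 500:
            break  # stalled
        move = step * g[free]
        if dmax is not None:
            norms = np.linalg.norm(move, axis=1)
            over = norms > dmax
            if over.any():
                move[over] *= (dmax / norms[over])[:, None]
        trial = pos.copy()
        trial[free] -= move
        e_t, g_t = net.energy_grad(trial)
        if e_t < e:
            pos, e, g = trial, e_t, g_t
            res = _residual(g, free)
            step *= 1.25
        else:
            step *= 0.5
            if step * res < 1e-15:
                break  # stalled at numerical precision
    return pos, EquilibriumInfo(res, it, e, res < p.solver_tol)
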