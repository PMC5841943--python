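"""The three-phase growth loop and the scenario suite.

One simulation step is:

1. **connect** — every ``reset_period`` steps the transversal springs are
   reassigned from the current cell shapes (:mod:`.connections`);
2. **grow** — all node positions are scaled by the per-step growth
   factors, wall-segment rest lengths are relaxed to their new actual
   lengths (the wall yields to growth), over-long segments are
   subdivided; transversal reference lengths are *not* touched, so
   growth stretches active springs further;
3. **equilibrate** — interior nodes relax to force balance with the
   outline pinned at its post-growth position (:mod:`.mechanics`).

Scenarios preset the growth field and parameter variants: ``isotropic``
(puzzle cells), ``anisotropic`` (elongated cells), ``gradient`` (a
left-to-right gradient of isotropy and hence of lobeyness), ``spk1``
(convexity inhibition off, stiffer springs and walls, slower resets —
worm-like interdigitation) and ``no_restriction`` (k_m = 0 control:
growth alone makes no lobes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .connections import place_connections
from .mechanics import equilibrate
from .metrics import METRIC_COLUMNS, measure_contour
from .model import SimulationParams, Tissue, subdivide_walls
from .synthetic import generate_tissue

__all__ = ["grow", "step", "measure_tissue", "run_scenario", "sweep", "ScenarioRun", "SCENARIOS"]


def _factors(g, template_x: np.ndarray) -> np.ndarray:
    if callable(g):
        return np.asarray(g(template_x), dtype=float)
    return np.full(len(template_x), float(g))


def grow(t: Tissue, p: SimulationParams) -> Tissue:
    """Apply one increment of imposed tissue growth (in place).

    Positions map ``(x, y) -> (g_x * x, g_y * y)``; position-dependent
    factors are evaluated on the frozen material coordinate
    ``template_x`` so the displacement field stays continuous.  *Stretched*
    wall segments are then relaxed: their rest lengths are raised to the
    post-growth actual lengths.  Compressed (buckled) segments keep their
    rest length and continue to push back toward straight — one-sided
    relaxation, so transient wrinkles are not ratcheted into the wall.
    Walls longer than ``max_segment`` are subdivided; spring reference
    lengths are left untouched.
    """
    gx = _factors(p.g_x, t.template_x)
    gy = _factors(p.g_y, t.template_x)
    if np.any(gx < 1) or np.any(gy < 1):
        raise ValueError("growth factors must be >= 1")
    t.nodes = t.nodes * np.column_stack([gx, gy])
    for (i, j) in t.edges():
        key = (i, j) if i < j else (j, i)
        current = float(np.hypot(*(t.nodes[j] - t.nodes[i])))
        if current > t.rest_lengths[key]:
            t.rest_lengths[key] = current
    subdivide_walls(t, p.max_segment)
    return t


def measure_tissue(t: Tissue, step_index: int = 0, *, pressure: float | None = None) -> pd.DataFrame:
    """Per-cell shape metrics for the current state, one row per cell.

    Cells whose outline has gone non-simple (a numerical pathology, not
    an expected state) get NaN metrics rather than aborting the run.
    """
    taut = np.zeros(t.n_cells, dtype=int)
    for s in t.springs:
        length = float(np.hypot(*(t.nodes[s.node_b] - t.nodes[s.node_a])))
        if length > s.ref_length:
            taut[s.cell_id] += 1
    rows = []
    for ci in range(t.n_cells):
        contour = t.cell_contour(ci)
        base = {
            "step": step_index,
            "cell_id": ci,
            "interior": t.cell_is_interior(ci),
            "active_springs": int(taut[ci]),
        }
        try:
            rec = measure_contour(
                contour, cell_id=ci, step=step_index, pressure=pressure
            ).as_dict()
            rec.update(base)
        except ValueError:
            rec = dict.fromkeys(METRIC_COLUMNS, float("nan"))
            rec.update(base)
        rows.append(rec)
    return pd.DataFrame(rows, columns=METRIC_COLUMNS + ["interior", "active_springs"])


def step(t: Tissue, p: SimulationParams, step_index: int) -> tuple[Tissue, pd.DataFrame]:
    """One full simulation step: connect (periodically), grow, equilibrate.

    Wall segments that stretch far beyond ``max_segment`` while the
    network relaxes are subdivided and the tissue re-equilibrated, so the
    discretization (and with it the self-contact barrier) tracks the
    deformation.
    """
    if step_index % p.reset_period == 0:
        place_connections(t, p)
    grow(t, p)
    equilibrate(t, p)
    for _ in range(3):
        too_long = any(
            np.hypot(*(t.nodes[j] - t.nodes[i])) > 1.34 * p.max_segment
            for (i, j) in t.edges()
        )
        if not too_long:
            break
        subdivide_walls(t, p.max_segment)
        equilibrate(t, p)
    return t, measure_tissue(t, step_index + 1)


@dataclass
class ScenarioRun:
    """Artifacts of one scenario run."""

    scenario: str
    params: SimulationParams
    tissue: Tissue                      # final state
    metrics: pd.DataFrame               # per-cell per-step records
    initial_centroids: np.ndarray       # (n_cells, 2) template cell centroids
    snapshots: dict[int, Tissue] = field(default_factory=dict)

    def interior_metrics(self) -> pd.DataFrame:
        return self.metrics[self.metrics["interior"]]

    def save(self, out_dir: str | Path) -> None:
        from .model import tissue_to_json
        from .render import tissue_svg

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(out / "metrics.csv", index=False)
        (out / "final_tissue.json").write_text(tissue_to_json(self.tissue))
        (out / "final_tissue.svg").write_text(tissue_svg(self.tissue))
        for si, snap in self.snapshots.items():
            (out / f"tissue_step{si:04d}.json").write_text(tissue_to_json(snap))
            (out / f"tissue_step{si:04d}.svg").write_text(tissue_svg(snap))
        log = {
            "scenario": self.scenario,
            "version": _version,
            "params": {
                k: (repr(v) if callable(v) else v)
                for k, v in vars(self.params).items()
            },
            "n_cells": self.tissue.n_cells,
            "n_nodes": self.tissue.n_nodes,
            "final_residual": getattr(self.tissue, "equilibrium", None)
            and self.tissue.equilibrium.residual,
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2))


def _gradient_gy(base_gx: float, width: float):
    """y-growth interpolating from 1 (left edge) to g_x (right edge)."""

    def g_y(template_x: np.ndarray) -> np.ndarray:
        frac = np.clip(template_x / width, 0.0, 1.0)
        return 1.0 + frac * (base_gx - 1.0)

    return g_y


SCENARIOS = ("isotropic", "anisotropic", "gradient", "spk1", "no_restriction")


def scenario_params(
    name: str, base: SimulationParams | None = None, *, width: float = 100.0
) -> SimulationParams:
    """Parameter preset for a named scenario, derived from ``base``."""
    p = base if base is not None else SimulationParams()
    if name == "isotropic":
        return p
    if name == "anisotropic":
        return p.updated(g_x=max(_scalar(p.g_x), _scalar(p.g_y)), g_y=1.0)
    if name == "gradient":
        gx = max(_scalar(p.g_x), _scalar(p.g_y))
        return p.updated(g_x=gx, g_y=_gradient_gy(gx, width))
    if name == "spk1":
        # lobe-tip placement allowed; stiffer connections and cell wall
        # (stretching and, dominantly, bending — the smoothness of the
        # worm-like mutant cells); less frequent connection resets
        return p.updated(
            spk1_mode=True,
            k_m=2.0 * p.k_m,
            k_s=4.0 * p.k_s,
            k_b=50.0 * p.k_b,
            reset_period=2 * p.reset_period,
        )
    if name == "no_restriction":
        return p.updated(k_m=0.0)
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")


def _scalar(g) -> float:
    if callable(g):
        raise ValueError("scenario presets need scalar base growth factors")
    return float(g)


def run_scenario(
    name: str,
    params: SimulationParams | None = None,
    *,
    template: Tissue | None = None,
    n_cells: int = 30,
    width: float = 100.0,
    height: float = 100.0,
    out_dir: str | Path | None = None,
    snapshot_every: int = 0,
) -> ScenarioRun:
    """Run a named scenario end to end and collect metrics.

    The initial tissue is generated from ``params.seed`` unless an
    explicit ``template`` is supplied.  Deterministic: the same seed and
    configuration give identical metrics.
    """
    p = scenario_params(name, params, width=width)
    if template is None:
        template = generate_tissue(
            seed=p.seed, n_cells=n_cells, width=width, height=height,
            spacing=p.max_segment,
        )
    t = template.copy()
    centroids = np.asarray(
        [t.nodes[loop].mean(axis=0) for loop in t.cells]
    )
    frames = [measure_tissue(t, 0)]
    snapshots: dict[int, Tissue] = {}
    for si in range(p.n_steps):
        t, df = step(t, p, si)
        frames.append(df)
        if snapshot_every and (si + 1) % snapshot_every == 0:
            snapshots[si + 1] = t.copy()
    metrics = pd.concat(frames, ignore_index=True)
    run = ScenarioRun(
        scenario=name, params=p, tissue=t, metrics=metrics,
        initial_centroids=centroids, snapshots=snapshots,
    )
    if out_dir is not None:
        run.save(out_dir)
    return run


SWEEPABLE = ("isotropy", "k_b", "k_m", "k_s", "min_micro", "theta_micro")


def sweep(
    parameter: str,
    values: list[float],
    base: SimulationParams | None = None,
    **scenario_kwargs,
) -> pd.DataFrame:
    """One isotropic-template run per parameter value; final-state summary.

    ``isotropy`` values are fractions in [0, 1] mapping to
    ``g_y = 1 + v * (g_x - 1)``; the other names are absolute parameter
    values.  The emergence of lobes has no sharp threshold along any of
    these axes — the summary table shows the continuous transition.
    """
    if parameter not in SWEEPABLE:
        raise ValueError(f"unknown sweep parameter {parameter!r}; choose from {SWEEPABLE}")
    base = base if base is not None else SimulationParams()
    rows = []
    for v in values:
        if parameter == "isotropy":
            gx = _scalar(base.g_x)
            p = base.updated(g_y=1.0 + float(v) * (gx - 1.0))
        else:
            p = base.updated(**{parameter: float(v)})
        run = run_scenario("isotropic", p, **scenario_kwargs)
        final = run.interior_metrics()
        final = final[final["step"] == final["step"].max()]
        rows.append({
            "parameter": parameter,
            "value": v,
            "mean_lobeyness": final["lobeyness"].mean(),
            "lec_radius_p50": final["lec_radius"].quantile(0.5),
            "lec_radius_p90": final["lec_radius"].quantile(0.9),
            "mean_aspect_ratio": final["aspect_ratio"].mean(),
        })
    return pd.DataFrame(rows)
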