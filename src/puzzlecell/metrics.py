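"""Pavement-cell shape and growth statistics.

Implements the scalar shape descriptors used throughout the package:

* **lobeyness** — cell perimeter / convex-hull perimeter; 1 for convex
  cells, growing with lobe complexity; translation/rotation/scale
  invariant.
* **circularity** — perimeter / sqrt(area); minimal (2*sqrt(pi)) for a
  disc but inflated by elongation, which is why lobeyness is preferred
  for lobation readouts.
* **hull solidity** — convex-hull area / cell area; sensitive to bent
  (boomerang/worm) shapes that lobeyness scores as nearly convex.
* **largest empty circle (LEC)** — geometric proxy for the turgor-induced
  wall stress a cell must withstand; see :func:`stress_proxy`.
* **growth anisotropy** — ratio of maximal to minimal expansion rate of a
  cell between two time points, from a least-squares affine fit to
  corresponded contour points.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .geometry import (
    Contour,
    convex_hull,
    largest_empty_circle,
    normalize_contour,
    polygon_area,
    polygon_perimeter,
)

__all__ = [
    "MetricsRecord",
    "lobeyness",
    "circularity",
    "hull_solidity",
    "aspect_ratio",
    "growth_anisotropy",
    "stress_proxy",
    "measure_contour",
    "lec_vs_area_summary",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = [
    "step", "cell_id", "area", "perimeter", "lobeyness", "circularity",
    "hull_solidity", "lec_radius", "lec_area", "aspect_ratio", "stress_proxy",
]


@dataclass
class MetricsRecord:
    """One row of per-cell, per-step measurements."""

    cell_id: int
    step: int
    area: float
    perimeter: float
    lobeyness: float
    circularity: float
    hull_solidity: float
    lec_radius: float
    lec_area: float
    aspect_ratio: float
    stress_proxy: float = float("nan")

    def as_dict(self) -> dict:
        return asdict(self)


def lobeyness(c: Contour) -> float:
    """Perimeter of the cell divided by the perimeter of its convex hull.

    Equals 1 for convex shapes and increases with contour complexity.
    """
    return polygon_perimeter(c) / polygon_perimeter(convex_hull(c))


def circularity(c: Contour) -> float:
    """Perimeter divided by the square root of area.

    2*sqrt(pi) (~3.545) for a disc; note that mere elongation inflates
    this measure even without any lobes.
    """
    area = polygon_area(c)
    if area <= 0:
        raise ValueError("circularity undefined for zero-area contour")
    return polygon_perimeter(c) / float(np.sqrt(area))


def hull_solidity(c: Contour) -> float:
    """Convex-hull area divided by cell area (>= 1)."""
    area = polygon_area(c)
    if area <= 0:
        raise ValueError("hull solidity undefined for zero-area contour")
    return polygon_area(convex_hull(c)) / area


def aspect_ratio(c: Contour, n_samples: int = 256) -> float:
    """Elongation: sqrt of the ratio of contour-point covariance eigenvalues.

    The contour is resampled to ``n_samples`` points at exactly uniform
    arc length first, so that vertex density does not bias the covariance.
    """
    pts = c.points
    seg = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    closed = np.vstack([pts, pts[:1]])
    s = np.linspace(0.0, cum[-1], n_samples, endpoint=False)
    xs = np.interp(s, cum, closed[:, 0])
    ys = np.interp(s, cum, closed[:, 1])
    cov = np.cov(np.column_stack([xs, ys]).T)
    ev = np.linalg.eigvalsh(cov)
    if ev[0] <= 0:
        raise ValueError("degenerate contour: zero covariance eigenvalue")
    return float(np.sqrt(ev[1] / ev[0]))


def growth_anisotropy(
    c0: Contour, c1: Contour, correspondences: np.ndarray | None = None
) -> float:
    """Max/min expansion-rate ratio between two corresponded outlines.

    A linear map ``A`` is fitted by least squares from centered time-0
    points to centered time-1 points; the returned value is the ratio of
    the singular values of ``A`` (>= 1).  Equals 1 for isotropic
    deformations and the imposed axis ratio for pure stretches.

    Parameters
    ----------
    correspondences
        Optional ``(m, 2)`` integer array of (index in c0, index in c1)
        pairs; by default points are matched by position in the sequence
        (requires equally long contours).
    """
    if correspondences is None:
        if c0.n != c1.n:
            raise ValueError("contours differ in length; pass explicit correspondences")
        p0, p1 = c0.points, c1.points
    else:
        corr = np.asarray(correspondences, dtype=int)
        p0, p1 = c0.points[corr[:, 0]], c1.points[corr[:, 1]]
    if len(p0) < 3:
        raise ValueError("need at least 3 corresponded points")
    x0 = p0 - p0.mean(axis=0)
    x1 = p1 - p1.mean(axis=0)
    at, *_ = np.linalg.lstsq(x0, x1, rcond=None)
    s = np.linalg.svd(at.T, compute_uv=False)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise ValueError("rank-deficient correspondence set")
    return float(s[0] / s[1])


def stress_proxy(lec_radius: float, pressure: float = 0.5, thickness: float = 1.0) -> float:
    """Thin-wall hoop-stress proxy ``P * r / t`` (MPa).

    Uses the LEC radius as the effective cylinder radius: the largest
    unsupported span of wall sets the stress scale under turgor.  Defaults
    correspond to 5 bar turgor and a 1 µm wall.  This is a documented
    closed-form proxy, not a finite-element result.
    """
    return pressure * lec_radius / thickness


def measure_contour(
    c: Contour,
    *,
    cell_id: int = 0,
    step: int = 0,
    lec_spacing: float | None = None,
    pressure: float | None = None,
    thickness: float = 1.0,
    normalized: bool = False,
) -> MetricsRecord:
    """All shape metrics for one contour, as a :class:`MetricsRecord`."""
    if not normalized:
        c = normalize_contour(c)
    lec = largest_empty_circle(c, spacing=lec_spacing)
    sp = stress_proxy(lec.radius, pressure, thickness) if pressure is not None else float("nan")
    return MetricsRecord(
        cell_id=cell_id,
        step=step,
        area=polygon_area(c),
        perimeter=polygon_perimeter(c),
        lobeyness=lobeyness(c),
        circularity=circularity(c),
        hull_solidity=hull_solidity(c),
        lec_radius=lec.radius,
        lec_area=lec.area,
        aspect_ratio=aspect_ratio(c),
        stress_proxy=sp,
    )


def lec_vs_area_summary(
    records: pd.DataFrame, top_fraction: float = 0.20, group_col: str = "step"
) -> pd.DataFrame:
    """Mean cell area vs. mean LEC area over the largest cells per group.

    For each time group, only the largest ``top_fraction`` of cells by
    area are kept (default 20%, which excludes the small cells of the
    stomatal lineage in real tissue).  The ``circular_reference`` column
    restates the mean area: a perfectly circular cell would have LEC area
    equal to cell area, so points below that line indicate LEC regulation.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    rows = []
    for key, grp in records.groupby(group_col, sort=True):
        if len(grp) == 0:
            raise ValueError(f"empty group {key!r}")
        k = max(1, int(np.ceil(top_fraction * len(grp))))
        top = grp.nlargest(k, "area")
        rows.append({
            group_col: key,
            "n_cells": k,
            "mean_area": top["area"].mean(),
            "mean_lec_area": top["lec_area"].mean(),
            "circular_reference": top["area"].mean(),
        })
    return pd.DataFrame(rows)
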