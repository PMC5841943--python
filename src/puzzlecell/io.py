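"""Reading and writing cell-contour files.

Two plain-text formats are supported for user-supplied outlines:

* CSV with columns ``cell_id,x,y[,z]`` — one row per contour point,
  points of one cell contiguous and in boundary order;
* JSON ``{"cells": [{"id": ..., "points": [[x, y(, z)], ...]}, ...]}``.

3D contours are projected onto their PCA best-fit plane before any 2D
metric is computed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import Contour, Contour3D

__all__ = ["read_contours", "read_contours_csv", "read_contours_json", "write_contours_csv"]


def _make(points: np.ndarray) -> Contour | Contour3D:
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] not in (2, 3):
        raise ValueError(f"contour points must be (n, 2) or (n, 3), got {points.shape}")
    if points.shape[1] == 3:
        if np.allclose(points[:, 2], points[0, 2]):
            return Contour(points[:, :2])
        return Contour3D(points)
    return Contour(points)


def read_contours_csv(path: str | Path) -> dict[str, Contour | Contour3D]:
    df = pd.read_csv(path)
    cols = [c for c in ("x", "y", "z") if c in df.columns]
    if "cell_id" not in df.columns or len(cols) < 2:
        raise ValueError("contour CSV needs columns cell_id,x,y[,z]")
    return {
        str(cid): _make(grp[cols].to_numpy())
        for cid, grp in df.groupby("cell_id", sort=False)
    }


def read_contours_json(path: str | Path) -> dict[str, Contour | Contour3D]:
    import json

    doc = json.loads(Path(path).read_text())
    return {str(c["id"]): _make(np.asarray(c["points"])) for c in doc["cells"]}


def read_contours(path: str | Path) -> dict[str, Contour | Contour3D]:
    """Dispatch on file extension (.csv or .json)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return read_contours_json(path)
    return read_contours_csv(path)


def write_contours_csv(contours: dict[str, Contour | Contour3D], path: str | Path) -> None:
    rows = []
    for cid, c in contours.items():
        for p in c.points:
            row = {"cell_id": cid, "x": p[0], "y": p[1]}
            if len(p) == 3:
                row["z"] = p[2]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
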