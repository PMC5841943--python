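"""Minimal SVG rendering of tissues.

Frames mirror the conventional presentation of this model family: cell
outlines in black on white, active transversal springs as red chords.
Because late-stage cells carry many springs, only a random 50% subsample
is drawn by default (a fixed-seed choice that affects rendering only,
never the simulation).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .model import Tissue

__all__ = ["tissue_svg", "write_svg"]


def tissue_svg(
    t: Tissue,
    *,
    springs: bool = True,
    spring_fraction: float = 0.5,
    seed: int = 0,
    pad: float = 2.0,
    scale: float = 4.0,
) -> str:
    """Render a tissue as an SVG document string."""
    lo = t.nodes.min(axis=0) - pad
    hi = t.nodes.max(axis=0) + pad
    w, h = (hi - lo) * scale

    def xy(p: np.ndarray) -> tuple[float, float]:
        # flip y so the tissue is drawn with y up
        return ((p[0] - lo[0]) * scale, (hi[1] - p[1]) * scale)

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w:.0f}" height="{h:.0f}" '
        f'viewBox="0 0 {w:.2f} {h:.2f}">',
        f'<rect width="{w:.2f}" height="{h:.2f}" fill="white"/>',
    ]
    for loop in t.cells:
        pts = " ".join(f"{x:.2f},{y:.2f}" for x, y in (xy(p) for p in t.nodes[loop]))
        parts.append(
            f'<polygon points="{pts}" fill="none" stroke="black" stroke-width="1"/>'
        )
    if springs and t.springs:
        rng = np.random.default_rng(seed)
        keep = rng.random(len(t.springs)) < spring_fraction
        for s, k in zip(t.springs, keep):
            if not k:
                continue
            length = float(np.hypot(*(t.nodes[s.node_b] - t.nodes[s.node_a])))
            if length <= s.ref_length:
                continue  # slack springs are invisible, like unloaded fibrils
            xa, ya = xy(t.nodes[s.node_a])
            xb, yb = xy(t.nodes[s.node_b])
            parts.append(
                f'<line x1="{xa:.2f}" y1="{ya:.2f}" x2="{xb:.2f}" y2="{yb:.2f}" '
                f'stroke="red" stroke-width="0.7"/>'
            )
    parts.append("</svg>")
    return "\n".join(parts)


def write_svg(t: Tissue, path: str | Path, **kwargs) -> None:
    Path(path).write_text(tissue_svg(t, **kwargs))
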