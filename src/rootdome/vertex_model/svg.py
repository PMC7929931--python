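"""Minimal SVG rendering of tissue snapshots (plain-text output)."""

from __future__ import annotations

from pathlib import Path

from .core import Tissue

_ROLE_FILL = {
    "central": "#2c4f9e",
    "flanking": "#9db8e8",
    "peripheral": "#f2f2f2",
    "provascular": "#c04fc0",
    "overlay": "#bbbbbb",
}


def render_tissue_svg(t: Tissue, path: str | Path, scale: float = 3.0,
                      margin: float = 10.0) -> Path:
    """Write the polygonal cells of a tissue as an SVG drawing."""
    pts = t.verts
    xmin, ymin = pts.min(axis=0) - margin
    xmax, ymax = pts.max(axis=0) + margin
    w = (xmax - xmin) * scale
    h = (ymax - ymin) * scale

    def sx(x):
        return (x - xmin) * scale

    def sy(y):
        return (ymax - y) * scale  # flip: SVG y points down

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w:.0f}" '
        f'height="{h:.0f}" viewBox="0 0 {w:.0f} {h:.0f}">'
    ]
    for cell in t.cells:
        coords = " ".join(f"{sx(pts[v, 0]):.2f},{sy(pts[v, 1]):.2f}"
                          for v in cell.cycle)
        fill = _ROLE_FILL.get(cell.role, "#ffffff")
        opacity = "0.5" if cell.role == "overlay" else "1.0"
        parts.append(f'<polygon points="{coords}" fill="{fill}" '
                     f'fill-opacity="{opacity}" stroke="#333" '
                     'stroke-width="0.6"/>')
    parts.append("</svg>")
    path = Path(path)
    path.write_text("\n".join(parts) + "\n")
    return path
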