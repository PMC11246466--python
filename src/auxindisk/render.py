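"""Cosmetic SVG rendering of a snapshot (auxin green, CUC blue, PIN red)."""

from __future__ import annotations

import numpy as np

from .mesh import TissueMesh, cell_vertex_loop


def render_svg(mesh: TissueMesh, path, color_by: str = "aux",
               size: int = 640) -> None:
    """Write an SVG of the tissue; cell fill encodes auxin (green) or CUC
    (blue), wall-side red marks encode PIN allocation."""
    if color_by not in ("aux", "cuc"):
        raise ValueError("color_by must be 'aux' or 'cuc'")
    pos = np.array([v.pos for v in mesh.vertices.values()])
    lo, hi = pos.min(axis=0), pos.max(axis=0)
    span = max(hi - lo) * 1.05 + 1e-9
    scale = size / span

    def xy(p):
        q = (p - lo) * scale + 0.025 * size
        return f"{q[0]:.2f},{size - q[1]:.2f}"

    vmax = max((getattr(c, color_by) for c in mesh.cells.values()),
               default=1.0) or 1.0
    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{size}" '
             f'height="{size}" viewBox="0 0 {size} {size}">',
             f'<rect width="{size}" height="{size}" fill="white"/>']
    for cell in mesh.cells.values():
        loop = cell_vertex_loop(mesh, cell)
        pts = " ".join(xy(mesh.vertices[v].pos) for v in loop)
        t = getattr(cell, color_by) / vmax
        rgb = (f"rgb({int(255 * (1 - t))},255,{int(255 * (1 - t))})"
               if color_by == "aux"
               else f"rgb({int(255 * (1 - t))},{int(255 * (1 - t))},255)")
        parts.append(f'<polygon points="{pts}" fill="{rgb}" '
                     'stroke="#444" stroke-width="0.6"/>')
    # PIN: red marks just inside each wall, thickness by allocation
    cents = {c.id: np.mean([mesh.vertices[v].pos
                            for v in cell_vertex_loop(mesh, c)], axis=0)
             for c in mesh.cells.values()}
    for w in mesh.walls.values():
        for cid, p in w.pin.items():
            if p <= 1e-4:
                continue
            a = mesh.vertices[w.v1].pos
            b = mesh.vertices[w.v2].pos
            off = 0.12 * (cents[cid] - 0.5 * (a + b))
            x1, y1 = xy(a + off).split(",")
            x2, y2 = xy(b + off).split(",")
            parts.append(
                f'<line x1="{x1}" y1="{y1}" x2="{x2}" y2="{y2}" '
                f'stroke="red" stroke-width="{min(3.0, 0.5 + 6 * p):.2f}" '
                'stroke-opacity="0.7"/>')
    parts.append("</svg>")
    with open(path, "w") as fh:
        fh.write("\n".join(parts))
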