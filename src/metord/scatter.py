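"""Self-contained interactive HTML export of an ordination.

Renders the first up-to-three ordination axes as a drag-to-rotate 3-D
scatter (plain canvas, no external assets, so the file can be shared as a
single download). Samples are colored by one metadata column, optionally
shaped by a second, and every color group can be toggled on/off from the
legend. Axis labels carry the proportion of variation explained.

The sample coordinates are embedded verbatim in a ``<script
type="application/json" id="metord-data">`` block, which doubles as a
machine-readable record of the plotted points.
"""

from __future__ import annotations

import json
from pathlib import Path

from .ordination import OrdinationResult
from .tables import SampleMetadata

__all__ = ["render_scatter"]

_PALETTE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
]
_SHAPES = ["circle", "square", "triangle", "diamond", "cross"]


def _axis_label(axis: int, proportion: float) -> str:
    return f"PCo{axis + 1} ({100 * proportion:.1f}%)"


def render_scatter(
    result: OrdinationResult,
    metadata: SampleMetadata,
    color_by: str,
    shape_by: str | None = None,
    path=None,
) -> str:
    """Write (or return) the standalone HTML scatter; returns the HTML text."""
    colors = metadata.column(color_by)           # raises listing columns
    shapes = metadata.column(shape_by) if shape_by else None

    k = min(3, result.num_axes)
    coords = result.coordinates[:, :k]
    color_groups = sorted(set(colors.reindex(result.ids)))
    shape_groups = sorted(set(shapes.reindex(result.ids))) if shapes is not None else ["all"]

    points = []
    for i, sid in enumerate(result.ids):
        xyz = list(coords[i]) + [0.0] * (3 - k)
        points.append(
            {
                "id": sid,
                "x": xyz[0],
                "y": xyz[1],
                "z": xyz[2],
                "color_group": str(colors.loc[sid]),
                "shape_group": str(shapes.loc[sid]) if shapes is not None else "all",
            }
        )
    data = {
        "n_axes": k,
        "axis_labels": [
            _axis_label(a, result.proportion_explained[a]) for a in range(k)
        ],
        "points": points,
        "color_groups": color_groups,
        "colors": {g: _PALETTE[i % len(_PALETTE)] for i, g in enumerate(color_groups)},
        "shape_groups": shape_groups,
        "shapes": {g: _SHAPES[i % len(_SHAPES)] for i, g in enumerate(shape_groups)},
    }
    html = _TEMPLATE.replace("__DATA__", json.dumps(data, sort_keys=True))
    if path is not None:
        Path(path).write_text(html)
    return html


_TEMPLATE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>PCoA ordination</title>
<style>
 body { font-family: sans-serif; margin: 1em; }
 #wrap { display: flex; gap: 1em; }
 #legend { min-width: 12em; }
 #legend label { display: block; margin: 0.2em 0; cursor: pointer; }
 .swatch { display: inline-block; width: 0.8em; height: 0.8em;
           margin-right: 0.4em; border-radius: 50%; }
 canvas { border: 1px solid #ccc; }
 #hint { color: #666; font-size: 0.85em; }
</style>
</head>
<body>
<h3>Ordination scatter</h3>
<div id="wrap">
  <canvas id="plot" width="640" height="520"></canvas>
  <div id="legend"><strong>Groups</strong></div>
</div>
<p id="hint">Drag to rotate; tick boxes to select or deselect groups.</p>
<script type="application/json" id="metord-data">__DATA__</script>
<script>
const DATA = JSON.parse(document.getElementById("metord-data").textContent);
const canvas = document.getElementById("plot");
const ctx = canvas.getContext("2d");
const visible = {};
DATA.color_groups.forEach(g => visible[g] = true);

// normalize coordinates to [-1, 1] per axis for display
const axes = ["x", "y", "z"];
const span = {};
axes.forEach(a => {
  const vals = DATA.points.map(p => p[a]);
  const lo = Math.min(...vals), hi = Math.max(...vals);
  span[a] = { lo: lo, range: (hi - lo) || 1 };
});
function norm(p, a) { return 2 * (p[a] - span[a].lo) / span[a].range - 1; }

let yaw = 0.5, pitch = 0.35;
function project(p) {
  const x = norm(p, "x"), y = norm(p, "y"), z = DATA.n_axes > 2 ? norm(p, "z") : 0;
  const cy = Math.cos(yaw), sy = Math.sin(yaw);
  const cp = Math.cos(pitch), sp = Math.sin(pitch);
  const x1 = cy * x + sy * z, z1 = -sy * x + cy * z;
  const y1 = cp * y - sp * z1, z2 = sp * y + cp * z1;
  const s = 200;
  return { sx: canvas.width / 2 + s * x1,
           sy: canvas.height / 2 - s * y1, depth: z2 };
}
function drawMarker(x, y, shape, color) {
  ctx.fillStyle = color; ctx.strokeStyle = color; ctx.lineWidth = 2;
  ctx.beginPath();
  const r = 5;
  if (shape === "square") ctx.rect(x - r, y - r, 2 * r, 2 * r);
  else if (shape === "triangle") {
    ctx.moveTo(x, y - r); ctx.lineTo(x - r, y + r); ctx.lineTo(x + r, y + r);
    ctx.closePath();
  } else if (shape === "diamond") {
    ctx.moveTo(x, y - r); ctx.lineTo(x - r, y); ctx.lineTo(x, y + r);
    ctx.lineTo(x + r, y); ctx.closePath();
  } else if (shape === "cross") {
    ctx.moveTo(x - r, y - r); ctx.lineTo(x + r, y + r);
    ctx.moveTo(x - r, y + r); ctx.lineTo(x + r, y - r);
    ctx.stroke(); return;
  } else ctx.arc(x, y, r, 0, 2 * Math.PI);
  ctx.fill();
}
function drawAxes() {
  ctx.fillStyle = "#333"; ctx.font = "12px sans-serif";
  DATA.axis_labels.forEach((lab, i) => {
    ctx.fillText(lab, 10, 16 + 14 * i);
  });
}
function draw() {
  ctx.clearRect(0, 0, canvas.width, canvas.height);
  drawAxes();
  const pts = DATA.points
    .filter(p => visible[p.color_group])
    .map(p => Object.assign({ proj: project(p) }, p))
    .sort((a, b) => a.proj.depth - b.proj.depth);
  pts.forEach(p => drawMarker(p.proj.sx, p.proj.sy,
    DATA.shapes[p.shape_group], DATA.colors[p.color_group]));
}
let dragging = false, lastX = 0, lastY = 0;
canvas.addEventListener("mousedown", e => {
  dragging = true; lastX = e.clientX; lastY = e.clientY;
});
window.addEventListener("mouseup", () => dragging = false);
window.addEventListener("mousemove", e => {
  if (!dragging) return;
  yaw += (e.clientX - lastX) * 0.01;
  pitch += (e.clientY - lastY) * 0.01;
  lastX = e.clientX; lastY = e.clientY;
  draw();
});
const legend = document.getElementById("legend");
DATA.color_groups.forEach(g => {
  const label = document.createElement("label");
  const box = document.createElement("input");
  box.type = "checkbox"; box.checked = true;
  box.addEventListener("change", () => { visible[g] = box.checked; draw(); });
  const swatch = document.createElement("span");
  swatch.className = "swatch";
  swatch.style.background = DATA.colors[g];
  label.appendChild(box); label.appendChild(swatch);
  label.appendChild(document.createTextNode(g));
  legend.appendChild(label);
});
draw();
</script>
</body>
</html>
"""
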