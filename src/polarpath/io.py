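"""Edge-list manifests, solution files and PNG rendering.

A manifest is a CSV of one row per edge (x1, y1, x2, y2, r, g, b, label)
preceded by a single JSON header line carrying the canvas size, condition
and generation parameters.  Coordinates are 0-based canvas pixels with y
pointing down.  Externally supplied edge lists may omit the color columns
(treated as all-white; color coefficients must then be zero) and the
label column (edges become "unknown"; the start edge must be supplied by
the caller).
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
from PIL import Image, ImageDraw

from .optimize import BoundaryPath
from .stimulus import CANVAS_H, CANVAS_W, EdgeSegment, EggParams, StimulusCanvas

logger = logging.getLogger(__name__)

MANIFEST_MAGIC = "#POLARPATH-MANIFEST"
MANIFEST_VERSION = 1


def write_manifest(stimulus: StimulusCanvas, path: Union[str, Path]) -> None:
    header = {
        "version": MANIFEST_VERSION,
        "width": stimulus.width,
        "height": stimulus.height,
        "condition": stimulus.condition,
        "fixation": list(stimulus.fixation),
        "seed": stimulus.seed,
    }
    if stimulus.egg is not None:
        header.update(
            k=stimulus.egg.k, jitter_deg=stimulus.egg.jitter_deg,
            pointing=stimulus.egg.pointing,
            egg_center=list(stimulus.egg.center) if stimulus.egg.center else None)
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"{MANIFEST_MAGIC} {json.dumps(header)}\n")
        w = csv.writer(fh)
        w.writerow(["x1", "y1", "x2", "y2", "r", "g", "b", "label"])
        for e in stimulus.edges:
            w.writerow([f"{e.p1[0]:.6f}", f"{e.p1[1]:.6f}",
                        f"{e.p2[0]:.6f}", f"{e.p2[1]:.6f}",
                        int(e.rgb[0]), int(e.rgb[1]), int(e.rgb[2]), e.label])


def read_manifest(path: Union[str, Path]) -> StimulusCanvas:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().rstrip("\n")
        header: dict = {}
        if first.startswith(MANIFEST_MAGIC):
            header = json.loads(first[len(MANIFEST_MAGIC):])
            if header.get("version") != MANIFEST_VERSION:
                raise ValueError(f"unknown manifest version {header.get('version')!r}")
            col_line = fh.readline()
        else:
            col_line = first
        cols = [c.strip() for c in col_line.split(",")]
        if cols[:4] != ["x1", "y1", "x2", "y2"]:
            raise ValueError("manifest must start with columns x1,y1,x2,y2")
        has_color = len(cols) >= 7
        has_label = "label" in cols
        if not has_color:
            logger.warning("manifest %s has no color columns; edges set to white "
                           "(run the model with a3 = a4 = 0)", path.name)
        width = int(header.get("width", CANVAS_W))
        height = int(header.get("height", CANVAS_H))
        edges = []
        for lineno, row in enumerate(csv.reader(fh), start=3 if header else 2):
            if not row:
                continue
            try:
                x1, y1, x2, y2 = (float(v) for v in row[:4])
                rgb = tuple(int(v) for v in row[4:7]) if has_color else (255, 255, 255)
                label = row[7] if has_label and len(row) > 7 else "unknown"
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path.name}:{lineno}: malformed row ({exc})") from None
            for x, y in ((x1, y1), (x2, y2)):
                if not (0 <= x <= width - 1 and 0 <= y <= height - 1):
                    raise ValueError(f"{path.name}:{lineno}: endpoint ({x}, {y}) outside canvas")
            edges.append(EdgeSegment(p1=(x1, y1), p2=(x2, y2), rgb=rgb, label=label))

    egg = None
    if "k" in header:
        egg = EggParams(k=header["k"], pointing=header.get("pointing", "right"),
                        jitter_deg=header.get("jitter_deg", 0.0),
                        center=tuple(header["egg_center"]) if header.get("egg_center") else None)
    fixation = tuple(header.get("fixation", (width / 2.0, height / 2.0)))
    return StimulusCanvas(edges=edges, egg=egg, condition=header.get("condition", "no_color"),
                          fixation=fixation, width=width, height=height,
                          seed=header.get("seed"))


# -- rendering --------------------------------------------------------------

def render_stimulus(stimulus: StimulusCanvas, path: Union[str, Path]) -> None:
    """1-px colored edges on black, written as PNG."""
    img = Image.new("RGB", (stimulus.width, stimulus.height), (0, 0, 0))
    draw = ImageDraw.Draw(img)
    for e in stimulus.edges:
        draw.line([tuple(e.p1), tuple(e.p2)], fill=tuple(int(c) for c in e.rgb), width=1)
    img.save(path)


def render_solution(stimulus: StimulusCanvas, path_or_polygon, out_path: Union[str, Path],
                    start_edge: Optional[int] = None) -> None:
    """Stimulus with the solved closed boundary overlaid in red, the
    fixation point marked with a cross and the start edge in yellow."""
    polygon = path_or_polygon.polygon if isinstance(path_or_polygon, BoundaryPath) else path_or_polygon
    if start_edge is None and isinstance(path_or_polygon, BoundaryPath):
        start_edge = path_or_polygon.start_edge
    img = Image.new("RGB", (stimulus.width, stimulus.height), (0, 0, 0))
    draw = ImageDraw.Draw(img)
    for e in stimulus.edges:
        draw.line([tuple(e.p1), tuple(e.p2)], fill=tuple(int(c) for c in e.rgb), width=1)
    pts = [tuple(p) for p in np.asarray(polygon)]
    draw.line(pts, fill=(255, 0, 0), width=1)
    fx, fy = stimulus.fixation
    draw.line([(fx - 6, fy), (fx + 6, fy)], fill=(0, 255, 0), width=1)
    draw.line([(fx, fy - 6), (fx, fy + 6)], fill=(0, 255, 0), width=1)
    if start_edge is not None:
        e = stimulus.edges[start_edge]
        draw.line([tuple(e.p1), tuple(e.p2)], fill=(255, 255, 0), width=2)
    img.save(out_path)


def render_logpolar(stimulus: StimulusCanvas, frame, path: Union[str, Path]) -> None:
    """Debug view: edges mapped into the (u, v) plane (out_size square)."""
    from .logpolar import to_logpolar

    img = Image.new("RGB", (frame.out_size, frame.out_size), (0, 0, 0))
    draw = ImageDraw.Draw(img)
    for e in stimulus.edges:
        uv = to_logpolar(np.array([e.p1, e.p2]), frame)
        draw.line([(uv[0, 0], uv[0, 1]), (uv[1, 0], uv[1, 1])],
                  fill=tuple(int(c) for c in e.rgb), width=1)
    img.save(path)


def write_graph_dump(graph, coeffs, path: Union[str, Path]) -> None:
    """Connection list as text ("from_id to_id cost D TA CS CC") for
    offline inspection of the cost structure."""
    costs = graph.costs(coeffs)
    cc = graph.nodes.contrast
    c = graph.conns
    with Path(path).open("w") as fh:
        fh.write("# from_id to_id cost D TA CS CC\n")
        for k in range(len(c)):
            fh.write(f"{c.from_idx[k]} {c.to_idx[k]} {costs[k]:.6f} "
                     f"{c.D[k]:.3f} {c.TA[k]:.6f} {c.CS[k]:.3f} {cc[c.to_idx[k]]:.3f}\n")


def write_solution(path_obj: BoundaryPath, out: Union[str, Path]) -> None:
    """Solution JSON: node sequence, per-connection features, cost, polygon."""
    payload = {
        "version": MANIFEST_VERSION,
        "node_ids": [int(i) for i in path_obj.node_ids],
        "total_cost": path_obj.total_cost,
        "start_edge": path_obj.start_edge,
        "per_connection_features": [
            {"D": float(d), "TA": float(ta), "CS": float(cs), "CC": float(cc)}
            for d, ta, cs, cc in path_obj.per_connection_features],
        "polygon": np.asarray(path_obj.polygon).tolist(),
    }
    Path(out).write_text(json.dumps(payload))
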