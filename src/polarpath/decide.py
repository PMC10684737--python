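"""Area-split decision: convert a closed boundary into the 2AFC response.

The horizontal midpoint of the extracted boundary's x-range splits the
polygon by a vertical line; the pointy side of the egg is the side with
the smaller enclosed area.  Exact ties (symmetric toy shapes) force a
seeded random response, as a forced-choice observer would.  A
self-intersecting polygon falls back to areas measured on an even-odd
rasterized mask (logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw
from shapely.geometry import Polygon, box

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Decision:
    response: str          # "left" | "right"
    area_left: float       # px^2
    area_right: float
    x_mid: float           # px
    tie: bool = False


def _raster_areas(poly_xy: np.ndarray, x_mid: float) -> tuple[float, float]:
    """Even-odd rasterized areas left/right of x_mid for a self-crossing
    polygon, at 1 px resolution in the polygon's own bounding box."""
    xmin, ymin = poly_xy.min(axis=0)
    xmax, ymax = poly_xy.max(axis=0)
    w = max(2, int(np.ceil(xmax - xmin)) + 3)
    h = max(2, int(np.ceil(ymax - ymin)) + 3)
    img = Image.new("1", (w, h), 0)
    pts = [(float(x - xmin + 1), float(y - ymin + 1)) for x, y in poly_xy]
    ImageDraw.Draw(img).polygon(pts, fill=1)
    mask = np.asarray(img, dtype=bool)
    xs = np.arange(w) + xmin - 1 + 0.5          # pixel-center x in canvas coords
    col_counts = mask.sum(axis=0)
    left = float(col_counts[xs < x_mid].sum())
    right = float(col_counts[xs >= x_mid].sum())
    return left, right


def pointing_decision(polygon: np.ndarray, rng: np.random.Generator) -> Decision:
    """Respond 'left' or 'right' from a closed polygon (first row == last)."""
    poly_xy = np.asarray(polygon, dtype=float)
    xmin, xmax = poly_xy[:, 0].min(), poly_xy[:, 0].max()
    ymin, ymax = poly_xy[:, 1].min(), poly_xy[:, 1].max()
    x_mid = (xmin + xmax) / 2.0

    shp = Polygon(poly_xy)
    if shp.is_valid and shp.area > 0:
        pad = 10.0
        left_box = box(xmin - pad, ymin - pad, x_mid, ymax + pad)
        right_box = box(x_mid, ymin - pad, xmax + pad, ymax + pad)
        area_left = shp.intersection(left_box).area
        area_right = shp.intersection(right_box).area
    else:
        logger.info("pointing_decision: self-intersecting polygon, using raster fallback")
        area_left, area_right = _raster_areas(poly_xy, x_mid)

    if area_left == area_right:
        return Decision(response="left" if rng.random() < 0.5 else "right",
                        area_left=area_left, area_right=area_right,
                        x_mid=x_mid, tie=True)
    response = "left" if area_left < area_right else "right"
    return Decision(response=response, area_left=area_left,
                    area_right=area_right, x_mid=x_mid)
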