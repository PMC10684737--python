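"""Conformal complex-log mapping between the canvas and log-polar space.

The mapping is the complex logarithm about the fixation point: a point at
radius ``r`` and polar angle ``theta`` (radians, measured from a
per-trial reference angle) maps to

    u = (ln r - ln r_min) / (ln r_max - ln r_min) * out_size
    v = ((theta - theta_ref) mod 2*pi) / (2*pi) * out_size

Natural logarithm and radian angles make this a conformal map (local
angles are preserved), the standard approximation of the retina-to-V1
retinotopy.  Circles centered on fixation map to lines of constant u;
scaling about fixation is a pure translation in u; the angular coordinate
is 2*pi-periodic, which is what turns "find a closed boundary around
fixation" into a plain s-t shortest-path problem.

Screen coordinates have y pointing down; angles are measured
counterclockwise in the mathematical convention after negating y, so a
point directly above fixation on screen has theta = +pi/2.

Geometry is kept in continuous log-polar coordinates throughout; the
1920 x 1920 raster exists only for visualization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .stimulus import CANVAS_H, CANVAS_W, EdgeSegment

logger = logging.getLogger(__name__)

OUT_SIZE = 1920
R_MAX = math.hypot(CANVAS_W, CANVAS_H) / 2.0   # half canvas diagonal, ~1101 px
# For a square out_size x out_size image the map is conformal only when the
# radial and angular scales agree: out_size / ln(r_max / r_min) must equal
# out_size / (2*pi), hence r_min = r_max * e^(-2*pi)  (~2.06 px here).
R_MIN = R_MAX * math.exp(-2.0 * math.pi)
BAND_PX = 240                                   # seam-duplication width = window size


@dataclass(frozen=True)
class LogPolarFrame:
    """A per-trial log-polar coordinate frame."""

    fixation: tuple[float, float]
    theta_ref: float = 0.0
    r_min: float = R_MIN
    r_max: float = R_MAX
    out_size: int = OUT_SIZE
    band_px: int = BAND_PX

    def __post_init__(self) -> None:
        if not (0 < self.r_min < self.r_max):
            raise ValueError("require 0 < r_min < r_max")
        if self.out_size <= 0:
            raise ValueError("out_size must be > 0")

    @property
    def u_per_ln(self) -> float:
        """Log-polar px per unit of ln(r)."""
        return self.out_size / (math.log(self.r_max) - math.log(self.r_min))

    @property
    def v_per_rad(self) -> float:
        """Log-polar px per radian."""
        return self.out_size / (2.0 * math.pi)

    def radius_angle(self, points) -> tuple[np.ndarray, np.ndarray]:
        """Radius (px) and absolute polar angle (radians) of canvas points."""
        p = np.asarray(points, dtype=float)
        dx = p[..., 0] - self.fixation[0]
        dy = -(p[..., 1] - self.fixation[1])     # y-down screen -> math convention
        r = np.hypot(dx, dy)
        return r, np.arctan2(dy, dx)


def choose_reference(start_edge: EdgeSegment, fixation: tuple[float, float]) -> float:
    """Reference angle (theta = 0 direction): the polar angle of the start
    edge's midpoint relative to fixation."""
    mx, my = start_edge.midpoint
    dx = mx - fixation[0]
    dy = -(my - fixation[1])
    if dx == 0 and dy == 0:
        raise ValueError("start edge midpoint coincides with fixation")
    return math.atan2(dy, dx)


def to_logpolar(points, frame: LogPolarFrame) -> np.ndarray:
    """Map canvas points (..., 2) to (u, v) log-polar coordinates.

    Points closer to fixation than r_min are clipped to r_min (logged);
    a point exactly at fixation is an error.  v is reduced to
    [0, out_size).
    """
    r, theta = frame.radius_angle(points)
    if np.any(r == 0):
        raise ValueError("point exactly at fixation has no log-polar image")
    n_clip = int(np.sum(r < frame.r_min))
    if n_clip:
        logger.info("to_logpolar: clipped %d point(s) to r_min", n_clip)
        r = np.maximum(r, frame.r_min)
    u = (np.log(r) - math.log(frame.r_min)) * frame.u_per_ln
    v = np.mod(theta - frame.theta_ref, 2.0 * math.pi) * frame.v_per_rad
    return np.stack([u, v], axis=-1)


def from_logpolar(uv, frame: LogPolarFrame) -> np.ndarray:
    """Inverse mapping; v beyond out_size wraps by 2*pi periodicity."""
    uv = np.asarray(uv, dtype=float)
    r = frame.r_min * np.exp(uv[..., 0] / frame.u_per_ln)
    theta = frame.theta_ref + uv[..., 1] / frame.v_per_rad
    x = frame.fixation[0] + r * np.cos(theta)
    y = frame.fixation[1] - r * np.sin(theta)
    return np.stack([x, y], axis=-1)
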