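"""Synthetic 2AFC "egg in noise" stimulus generator.

A trial stimulus is a 1920x1080 canvas of 1-px line edges: a grid of
randomly oriented noise edges plus the fragmented boundary of an egg-like
target shape.  The task the stimuli support is a two-alternative forced
choice: does the pointy side of the egg face left or right?

The egg is an ellipse distorted by a coefficient ``k``:

    x^2 / (25^2 * (1 + k*x)) + y^2 / 24^2 = 1      (formula units)

A larger ``k`` gives a more obvious pointy side (here the pointy end lies
toward +x before any mirroring; ``pointing="left"`` mirrors the curve).
The sampled curve is anisotropically rescaled so its circumscribed
rectangle is exactly ``bbox_w x bbox_h`` pixels (450 x 360 by default).

The smooth boundary is fragmented into straight chords of roughly the
noise-edge length, every other chord is erased (support ratio 0.5), and
the retained chords get an orientation jitter about their midpoints.
Noise edges live one per 40-px grid cell, occupying the central 60 % of
the cell, with positional jitter of up to 10 px under a no-overlap
constraint.

Coloring emulates a watercolor-like display: a Worley pattern (Voronoi
partition of 5-9 random seeds, each region one of 20 mid-lightness
categorical colors) colors every edge inside the egg, while background
edges are either uniformly white or randomly colored.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from shapely import contains_xy
from shapely.geometry import Polygon

from ._geom import rotate_about, segment_segment_distance

logger = logging.getLogger(__name__)

# -- canvas layout constants ------------------------------------------------

CANVAS_W = 1920
CANVAS_H = 1080
GRID_CELL = 40                      # px; 48 x 27 cells
GRID_COLS = CANVAS_W // GRID_CELL   # 48
GRID_ROWS = CANVAS_H // GRID_CELL   # 27
NOISE_EDGE_LEN = 24.0               # central 60 % of a 40-px cell
POSITION_JITTER_MAX = 10.0          # px displacement of a noise-edge center
MIN_EDGE_GAP = 2.0                  # px; operational meaning of "no overlap"
EGG_CLEARANCE = 3.0                 # noise edges this close to egg edges are removed
WHITE = (255, 255, 255)

# 20 categorical colors, hues evenly spaced in CIELAB at L ~= 50 with the
# largest in-gamut chroma; all lightness values fall in [40, 60].
PALETTE: tuple[tuple[int, int, int], ...] = (
    (207, 65, 121), (209, 67, 91), (203, 78, 62), (188, 92, 34),
    (168, 105, 2), (143, 117, 0), (114, 126, 0), (80, 133, 24),
    (21, 137, 55), (0, 140, 85), (0, 142, 117), (0, 142, 149),
    (0, 141, 178), (0, 138, 201), (0, 133, 216), (0, 125, 222),
    (72, 114, 217), (132, 101, 202), (170, 86, 180), (194, 72, 152),
)

Pointing = Literal["left", "right"]
Condition = Literal["no_color", "white_background", "random_background"]
CONDITIONS = ("no_color", "white_background", "random_background")


# -- domain types -----------------------------------------------------------

@dataclass(frozen=True)
class EggParams:
    """Target-shape parameters.

    k: distortion coefficient (0.04 or 0.08 in the conditions modeled here).
    pointing: which way the pointy side faces on screen.
    bbox_w, bbox_h: circumscribed rectangle of the egg in px.
    support_ratio: fraction of the boundary physically present (0.5).
    jitter_deg: mean absolute orientation jitter of boundary edges.
    center: egg center on the canvas, or None to be drawn per trial.
    """

    k: float = 0.08
    pointing: Pointing = "right"
    bbox_w: float = 450.0
    bbox_h: float = 360.0
    support_ratio: float = 0.5
    jitter_deg: float = 20.0
    center: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if not (0 < self.support_ratio <= 1):
            raise ValueError("support_ratio must be in (0, 1]")
        if not (0 <= self.jitter_deg <= 180):
            raise ValueError("jitter_deg must be in [0, 180]")
        if not (self.bbox_w > self.bbox_h > 0):
            raise ValueError("require bbox_w > bbox_h > 0")
        if self.pointing not in ("left", "right"):
            raise ValueError("pointing must be 'left' or 'right'")


@dataclass
class EdgeSegment:
    """One line edge: two endpoints (canvas px, y down), a color and a label."""

    p1: tuple[float, float]
    p2: tuple[float, float]
    rgb: tuple[int, int, int] = WHITE
    label: str = "noise_outside"     # boundary | noise_inside | noise_outside | unknown
    grid_cell: Optional[tuple[int, int]] = None   # (col, row) for noise edges

    @property
    def midpoint(self) -> tuple[float, float]:
        return ((self.p1[0] + self.p2[0]) / 2.0, (self.p1[1] + self.p2[1]) / 2.0)

    @property
    def length(self) -> float:
        return math.hypot(self.p2[0] - self.p1[0], self.p2[1] - self.p1[1])


@dataclass
class WorleyPattern:
    """Voronoi partition of 5-9 seeds, one palette color per region."""

    seeds: np.ndarray                 # (n, 2) canvas px
    colors: np.ndarray                # (n,) palette indices
    palette: tuple[tuple[int, int, int], ...] = PALETTE

    def __post_init__(self) -> None:
        self.seeds = np.asarray(self.seeds, dtype=float)
        self.colors = np.asarray(self.colors, dtype=int)
        if not (5 <= len(self.seeds) <= 9):
            raise ValueError("Worley pattern needs 5-9 seeds")
        if len(self.colors) != len(self.seeds):
            raise ValueError("one color index per seed")

    def region_index(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = ((pts[:, None, :] - self.seeds[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)

    def color_at(self, point) -> tuple[int, int, int]:
        idx = int(self.region_index([point])[0])
        return self.palette[self.colors[idx]]


@dataclass
class StimulusCanvas:
    """A complete trial stimulus with ground truth."""

    edges: list[EdgeSegment]
    egg: Optional[EggParams]
    condition: str
    fixation: tuple[float, float] = (CANVAS_W / 2.0, CANVAS_H / 2.0)
    width: int = CANVAS_W
    height: int = CANVAS_H
    worley: Optional[WorleyPattern] = None
    seed: Optional[int] = None
    outline: Optional[np.ndarray] = field(default=None, repr=False)  # unjittered egg polyline

    def boundary_indices(self) -> list[int]:
        return [i for i, e in enumerate(self.edges) if e.label == "boundary"]

    def endpoints_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        p1 = np.array([e.p1 for e in self.edges], dtype=float).reshape(-1, 2)
        p2 = np.array([e.p2 for e in self.edges], dtype=float).reshape(-1, 2)
        return p1, p2

    def colors_array(self) -> np.ndarray:
        return np.array([e.rgb for e in self.edges], dtype=float).reshape(-1, 3)


# -- egg outline ------------------------------------------------------------

def _egg_implicit(x: float, y: float, k: float) -> float:
    return x * x / (625.0 * (1.0 + k * x)) + y * y / 576.0 - 1.0


def make_egg_outline(params: EggParams, n_samples: int = 1024) -> np.ndarray:
    """Sample the egg curve and rescale to the circumscribed pixel rectangle.

    Returns a closed polyline of shape (n_samples + 1, 2) in canvas px
    (first point repeated at the end).  The curve is sampled in formula
    units by root-finding along rays from an interior point, then
    anisotropically scaled so its bounding box is exactly bbox_w x bbox_h
    centered at ``params.center``.
    """
    if n_samples < 64:
        raise ValueError("n_samples must be >= 64")
    if params.center is None:
        raise ValueError("params.center must be set before sampling the outline")
    k = params.k

    # interior anchor: midpoint of the two y=0 crossings
    if k > 0:
        disc = math.sqrt((625.0 * k) ** 2 + 4.0 * 625.0)
        x_hi = (625.0 * k + disc) / 2.0
        x_lo = (625.0 * k - disc) / 2.0
    else:
        x_hi, x_lo = 25.0, -25.0
    xc = (x_hi + x_lo) / 2.0

    thetas = np.linspace(0.0, 2.0 * math.pi, n_samples, endpoint=False)
    pts = np.empty((n_samples, 2))
    for i, th in enumerate(thetas):
        ct, st = math.cos(th), math.sin(th)

        def f(r: float) -> float:
            return _egg_implicit(xc + r * ct, r * st, k)

        # upper bracket: stay inside the 1 + k*x > 0 domain on the -x side
        r_hi = 80.0
        if k > 0 and ct < 0:
            r_hi = min(r_hi, 0.999 * (xc + 1.0 / k) / (-ct))
        tries = 0
        while f(r_hi) <= 0 and tries < 60:
            r_hi = r_hi * 1.5 if not (k > 0 and ct < 0) else r_hi + 0.999 * ((xc + 1.0 / k) / (-ct) - r_hi) * 0.5
            tries += 1
        if f(r_hi) <= 0:
            raise ArithmeticError(f"egg outline root solve failed at angle {th:.6f} rad")
        r = brentq(f, 1e-9, r_hi, xtol=1e-12)
        pts[i] = (xc + r * ct, r * st)

    # anisotropic rescale to the stated pixel bounding box
    xmin, ymin = pts.min(axis=0)
    xmax, ymax = pts.max(axis=0)
    sx = params.bbox_w / (xmax - xmin)
    sy = params.bbox_h / (ymax - ymin)
    cx_f = (xmin + xmax) / 2.0
    cy_f = (ymin + ymax) / 2.0
    out = np.empty_like(pts)
    out[:, 0] = (pts[:, 0] - cx_f) * sx
    out[:, 1] = (pts[:, 1] - cy_f) * sy
    if params.pointing == "left":
        out[:, 0] = -out[:, 0]
        out = out[::-1].copy()       # keep consistent winding
    out[:, 0] += params.center[0]
    out[:, 1] += params.center[1]
    return np.vstack([out, out[:1]])


# -- fragmentation ----------------------------------------------------------

def _polyline_arclength(outline: np.ndarray) -> np.ndarray:
    seg = np.diff(outline, axis=0)
    return np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])


def _point_at_arclength(outline: np.ndarray, s: np.ndarray, cum: np.ndarray) -> np.ndarray:
    s = np.mod(s, cum[-1])
    x = np.interp(s, cum, outline[:, 0])
    y = np.interp(s, cum, outline[:, 1])
    return np.stack([x, y], axis=-1)


def fragment_boundary(
    outline: np.ndarray,
    fragment_len: float = NOISE_EDGE_LEN,
    start_offset: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[EdgeSegment]:
    """Chop the outline into equal-arc chords and keep every other one.

    The perimeter is divided into ``n = round(perimeter / fragment_len)``
    chords (n forced even) starting at ``start_offset`` arc px; retaining
    alternate chords yields a support ratio of exactly 0.5.
    """
    if fragment_len <= 0:
        raise ValueError("fragment_len must be > 0")
    cum = _polyline_arclength(outline)
    perimeter = cum[-1]
    n = int(round(perimeter / fragment_len))
    if n % 2 == 1:
        n -= 1
    if n < 8:
        raise ValueError(f"degenerate egg: only {n} chords at fragment_len={fragment_len}")
    if start_offset is None:
        if rng is None:
            raise ValueError("provide start_offset or rng")
        start_offset = float(rng.uniform(0.0, perimeter))

    s = start_offset + np.arange(n + 1) * (perimeter / n)
    pts = _point_at_arclength(outline, s, cum)
    edges = []
    for i in range(0, n, 2):
        edges.append(EdgeSegment(p1=tuple(pts[i]), p2=tuple(pts[i + 1]), label="boundary"))
    return edges


def apply_orientation_jitter(
    edges: Sequence[EdgeSegment], jitter_deg: float, rng: np.random.Generator
) -> list[EdgeSegment]:
    """Rotate each boundary edge about its midpoint.

    jitter 0: unchanged.  jitter j in [5, 40]: magnitude uniform in
    [j-5, j+5] degrees, random sign.  jitter 180: uniform in [-180, 180].
    """
    for e in edges:
        if e.label != "boundary":
            raise ValueError("orientation jitter applies to boundary edges only")
    if jitter_deg == 0:
        return [replace(e) for e in edges]
    if not (5.0 <= jitter_deg <= 40.0 or jitter_deg == 180.0):
        raise ValueError("jitter_deg must be 0, in [5, 40], or 180")
    out = []
    for e in edges:
        if jitter_deg == 180.0:
            ang = rng.uniform(-180.0, 180.0)
        else:
            mag = rng.uniform(jitter_deg - 5.0, jitter_deg + 5.0)
            ang = mag if rng.random() < 0.5 else -mag
        mid = np.array(e.midpoint)
        p = rotate_about(np.array([e.p1, e.p2]), mid, math.radians(ang))
        out.append(replace(e, p1=tuple(p[0]), p2=tuple(p[1])))
    return out


# -- noise field ------------------------------------------------------------

def _neighbor_cell_pairs() -> np.ndarray:
    """Index pairs of grid cells at Chebyshev distance 1 (the only pairs
    whose 24-px edges can come within 2 px after <=10 px jitter)."""
    idx = np.arange(GRID_COLS * GRID_ROWS).reshape(GRID_ROWS, GRID_COLS)
    pairs = []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        r_lo, r_hi = max(0, -dr), GRID_ROWS - max(0, dr)
        c_lo, c_hi = max(0, -dc), GRID_COLS - max(0, dc)
        a = idx[r_lo:r_hi, c_lo:c_hi]
        b = idx[r_lo + dr:r_hi + dr, c_lo + dc:c_hi + dc]
        pairs.append(np.stack([a.ravel(), b.ravel()], axis=1))
    return np.concatenate(pairs, axis=0)


_NEIGHBOR_PAIRS = _neighbor_cell_pairs()


def make_noise_field(rng: np.random.Generator) -> list[EdgeSegment]:
    """One randomly oriented 24-px edge per 40-px grid cell, positionally
    jittered by up to 10 px under the no-overlap (>= 2 px gap) constraint.

    A cell whose jitter cannot be placed within 100 attempts keeps its
    unjittered center (logged).
    """
    n = GRID_COLS * GRID_ROWS
    cols = np.tile(np.arange(GRID_COLS), GRID_ROWS)
    rows = np.repeat(np.arange(GRID_ROWS), GRID_COLS)
    base_centers = np.stack([cols * GRID_CELL + GRID_CELL / 2.0,
                             rows * GRID_CELL + GRID_CELL / 2.0], axis=1)
    theta = rng.uniform(0.0, math.pi, size=n)
    half = np.stack([np.cos(theta), np.sin(theta)], axis=1) * (NOISE_EDGE_LEN / 2.0)

    def draw_offsets(m: int) -> np.ndarray:
        dist = rng.uniform(0.0, POSITION_JITTER_MAX, size=m)
        ang = rng.uniform(0.0, 2.0 * math.pi, size=m)
        return np.stack([dist * np.cos(ang), dist * np.sin(ang)], axis=1)

    offsets = draw_offsets(n)
    attempts = np.ones(n, dtype=int)
    frozen = np.zeros(n, dtype=bool)     # cells reverted to unjittered centers

    for _ in range(200):
        centers = base_centers + offsets
        e1 = centers - half
        e2 = centers + half
        i, j = _NEIGHBOR_PAIRS[:, 0], _NEIGHBOR_PAIRS[:, 1]
        d = segment_segment_distance(e1[i], e2[i], e1[j], e2[j])
        bad = np.zeros(n, dtype=bool)
        close = d < MIN_EDGE_GAP
        bad[i[close]] = True
        bad[j[close]] = True
        oob = (e1 < 0).any(axis=1) | (e2 < 0).any(axis=1) \
            | (e1[:, 0] > CANVAS_W - 1) | (e2[:, 0] > CANVAS_W - 1) \
            | (e1[:, 1] > CANVAS_H - 1) | (e2[:, 1] > CANVAS_H - 1)
        bad |= oob
        bad &= ~frozen
        if not bad.any():
            break
        exhausted = bad & (attempts >= 100)
        if exhausted.any():
            logger.info("noise field: %d cell(s) kept unjittered after 100 attempts",
                        int(exhausted.sum()))
            offsets[exhausted] = 0.0
            frozen |= exhausted
            bad &= ~exhausted
        m = int(bad.sum())
        if m:
            offsets[bad] = draw_offsets(m)
            attempts[bad] += 1

    centers = base_centers + offsets
    e1 = centers - half
    e2 = centers + half
    return [
        EdgeSegment(p1=(e1[t, 0], e1[t, 1]), p2=(e2[t, 0], e2[t, 1]),
                    label="noise_outside", grid_cell=(int(cols[t]), int(rows[t])))
        for t in range(n)
    ]


# -- Worley pattern ---------------------------------------------------------

def make_worley_pattern(
    rng: np.random.Generator,
    palette: tuple[tuple[int, int, int], ...] = PALETTE,
) -> WorleyPattern:
    """5-9 uniform random seeds, each given a distinct palette color."""
    if len(palette) != 20:
        raise ValueError("palette must have 20 colors")
    n = int(rng.integers(5, 10))
    seeds = np.stack([rng.uniform(0, CANVAS_W, n), rng.uniform(0, CANVAS_H, n)], axis=1)
    colors = rng.choice(len(palette), size=n, replace=False)
    return WorleyPattern(seeds=seeds, colors=colors, palette=palette)


# -- assembly ---------------------------------------------------------------

def _draw_egg_center(rng: np.random.Generator, params: EggParams,
                     fixation: tuple[float, float], peripheral: bool) -> tuple[float, float]:
    if not peripheral:
        # uniform random vector over the disk of radius 0.5 * minor semi-axis
        r = 0.5 * (params.bbox_h / 2.0) * math.sqrt(rng.random())
        a = rng.uniform(0.0, 2.0 * math.pi)
        return (fixation[0] + r * math.cos(a), fixation[1] + r * math.sin(a))
    # peripheral: center outside the circle covering the central 50 % of the
    # canvas area, with the egg bounding box kept on the canvas
    r50 = math.sqrt(0.5 * CANVAS_W * CANVAS_H / math.pi)
    half_w, half_h = params.bbox_w / 2.0, params.bbox_h / 2.0
    for _ in range(10000):
        cx = rng.uniform(half_w, CANVAS_W - half_w)
        cy = rng.uniform(half_h, CANVAS_H - half_h)
        if math.hypot(cx - fixation[0], cy - fixation[1]) > r50:
            return (cx, cy)
    raise RuntimeError("could not place peripheral egg center")


def assemble_stimulus(
    condition: str,
    egg_params: EggParams,
    seed: int | np.random.Generator,
    peripheral: bool = False,
    n_outline_samples: int = 1024,
) -> StimulusCanvas:
    """Generate one complete trial stimulus from a single seed.

    Draw order (fixed for reproducibility): egg center, fragmentation
    start offset, per-edge orientation jitter, noise orientations, noise
    positional jitter, Worley seeds/colors, background colors.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    if isinstance(seed, np.random.Generator):
        rng, seed_val = seed, None
    else:
        rng, seed_val = np.random.default_rng(seed), int(seed)
    fixation = (CANVAS_W / 2.0, CANVAS_H / 2.0)

    params = egg_params
    if params.center is None:
        params = replace(params, center=_draw_egg_center(rng, params, fixation, peripheral))

    outline = make_egg_outline(params, n_outline_samples)
    boundary = fragment_boundary(outline, NOISE_EDGE_LEN, None, rng)
    boundary = apply_orientation_jitter(boundary, params.jitter_deg, rng)

    noise = make_noise_field(rng)

    # drop noise edges that pass within EGG_CLEARANCE px of any egg edge
    bp1 = np.array([e.p1 for e in boundary])
    bp2 = np.array([e.p2 for e in boundary])
    np1 = np.array([e.p1 for e in noise])
    np2 = np.array([e.p2 for e in noise])
    d = segment_segment_distance(np1[:, None], np2[:, None], bp1[None, :], bp2[None, :])
    keep = d.min(axis=1) >= EGG_CLEARANCE
    noise = [e for e, k_ in zip(noise, keep) if k_]

    # region labels from the unjittered outline polygon
    poly = Polygon(outline)
    mids = np.array([e.midpoint for e in noise])
    inside = contains_xy(poly, mids[:, 0], mids[:, 1]) if len(noise) else np.array([], bool)
    for e, ins in zip(noise, inside):
        e.label = "noise_inside" if ins else "noise_outside"

    worley = None
    if condition == "no_color":
        for e in boundary + noise:
            e.rgb = WHITE
    else:
        worley = make_worley_pattern(rng)
        for e in boundary:
            e.rgb = worley.color_at(e.midpoint)
        for e in noise:
            if e.label == "noise_inside":
                e.rgb = worley.color_at(e.midpoint)
            elif condition == "white_background":
                e.rgb = WHITE
            else:  # random_background
                e.rgb = PALETTE[int(rng.integers(0, len(PALETTE)))]

    return StimulusCanvas(
        edges=boundary + noise,
        egg=params,
        condition=condition,
        fixation=fixation,
        worley=worley,
        seed=seed_val,
        outline=outline,
    )
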