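"""Directed interpolation graph in log-polar space.

Every stimulus edge becomes two directed nodes (one per direction of
travel), each carrying the region colors to the walker's left and right.
Nodes are connected when the destination's start point falls inside a
240 x 240 log-polar-px window centered on the source's end point, and
each connection is scored by four features:

    cost = a1 * D^2 / 1920  +  a2 * TA / (2*pi)
         + a3 * CS / 255    +  a4 * (1 - CC / 255)

D  - Euclidean gap between the two nodes in log-polar px (proximity),
TA - |psi1| + |psi2|, the summed bend angles at both ends of the straight
     interpolation (good continuation),
CS - min over the two sides of the mean absolute RGB difference between
     consecutive nodes (color similarity),
CC - mean absolute RGB difference between a node's own two sides
     (color contrast; entered negatively, high contrast is cheap).

Side colors are sampled in the Cartesian frame from a Moore neighborhood
of range three (the 7 x 7 block of 40-px grid cells around an edge's
cell): neighbors are split by the sign of the cross product between the
edge's travel direction and the vector to the neighbor's center, and
averaged channel-wise per side.  A side with no neighbors takes the
canvas background color (black).

Left/right convention: with screen coordinates (y down) and travel
direction d, a neighbor offset w is on the walker's LEFT when
d.x * w.y - d.y * w.x < 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .logpolar import LogPolarFrame
from .stimulus import GRID_CELL, GRID_COLS, GRID_ROWS, EdgeSegment, StimulusCanvas

logger = logging.getLogger(__name__)

WINDOW_PX = 240          # connection window side, log-polar px
DISTANCE_NORM = 1920.0   # normalizer for D^2
_TWO_PI = 2.0 * math.pi


# -- coefficients -----------------------------------------------------------

@dataclass(frozen=True)
class CostCoefficients:
    """Weights [a1, a2, a3, a4] for distance, turning angle, color
    similarity and color contrast."""

    a1: float = 1.0
    a2: float = 1.0
    a3: float = 0.0
    a4: float = 0.0

    def __post_init__(self) -> None:
        if min(self.a1, self.a2, self.a3, self.a4) < 0:
            raise ValueError("cost coefficients must be nonnegative")

    @classmethod
    def from_string(cls, text: str) -> "CostCoefficients":
        parts = [float(p) for p in text.replace("[", "").replace("]", "").split(",")]
        if len(parts) != 4:
            raise ValueError("expected four comma-separated coefficients")
        return cls(*parts)

    @property
    def label(self) -> str:
        def fmt(x: float) -> str:
            return f"{x:g}"
        return f"[{fmt(self.a1)},{fmt(self.a2)},{fmt(self.a3)},{fmt(self.a4)}]"


# -- side-color sampling ----------------------------------------------------

def _edge_arrays(stimulus: StimulusCanvas):
    p1, p2 = stimulus.endpoints_arrays()
    centers = (p1 + p2) / 2.0
    cells = np.clip(np.floor(centers / GRID_CELL).astype(int),
                    [0, 0], [GRID_COLS - 1, GRID_ROWS - 1])
    return p1, p2, centers, cells


def all_side_colors(stimulus: StimulusCanvas) -> tuple[np.ndarray, np.ndarray]:
    """(rgb_left, rgb_right) for every edge, taken in its stored (p1->p2)
    direction.  Vectorized over the whole stimulus."""
    n = len(stimulus.edges)
    p1, p2, centers, cells = _edge_arrays(stimulus)
    colors = stimulus.colors_array()

    left_sum = np.zeros((n, 3))
    right_sum = np.zeros((n, 3))
    left_cnt = np.zeros(n)
    right_cnt = np.zeros(n)

    if n > 1:
        tree = cKDTree(cells.astype(float))
        pairs = tree.query_pairs(3.0, p=np.inf, output_type="ndarray")
        if len(pairs):
            ii = np.concatenate([pairs[:, 0], pairs[:, 1]])
            jj = np.concatenate([pairs[:, 1], pairs[:, 0]])
            d = p2[ii] - p1[ii]
            w = centers[jj] - centers[ii]
            cross = d[:, 0] * w[:, 1] - d[:, 1] * w[:, 0]
            is_left = cross < 0
            np.add.at(left_sum, ii[is_left], colors[jj[is_left]])
            np.add.at(left_cnt, ii[is_left], 1)
            np.add.at(right_sum, ii[~is_left], colors[jj[~is_left]])
            np.add.at(right_cnt, ii[~is_left], 1)

    left = np.where(left_cnt[:, None] > 0, left_sum / np.maximum(left_cnt, 1)[:, None], 0.0)
    right = np.where(right_cnt[:, None] > 0, right_sum / np.maximum(right_cnt, 1)[:, None], 0.0)
    return left, right


def sample_side_colors(edge: EdgeSegment, stimulus: StimulusCanvas
                       ) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Side colors for one edge (p1->p2 direction) against a stimulus.

    The edge itself is excluded from its own neighborhood; an edge not
    present in the stimulus is classified purely by coordinates.
    """
    p1, p2, centers, cells = _edge_arrays(stimulus)
    colors = stimulus.colors_array()
    mid = np.array(edge.midpoint)
    cell = np.clip(np.floor(mid / GRID_CELL).astype(int),
                   [0, 0], [GRID_COLS - 1, GRID_ROWS - 1])
    in_block = (np.abs(cells - cell).max(axis=1) <= 3)
    # exclude the edge itself (either orientation) when it belongs to the stimulus
    qa, qb = np.array(edge.p1), np.array(edge.p2)
    same = ((np.abs(p1 - qa).max(axis=1) < 1e-9) & (np.abs(p2 - qb).max(axis=1) < 1e-9)) \
         | ((np.abs(p1 - qb).max(axis=1) < 1e-9) & (np.abs(p2 - qa).max(axis=1) < 1e-9))
    in_block &= ~same
    d = np.array(edge.p2) - np.array(edge.p1)
    w = centers[in_block] - mid
    cross = d[0] * w[:, 1] - d[1] * w[:, 0]
    nb_colors = colors[in_block]
    out = []
    for side_mask in (cross < 0, cross >= 0):
        out.append(tuple(nb_colors[side_mask].mean(axis=0)) if side_mask.any() else (0.0, 0.0, 0.0))
    return out[0], out[1]


# -- nodes ------------------------------------------------------------------

@dataclass(frozen=True)
class GraphNode:
    """View of one directed log-polar node (for inspection and small tests)."""

    start_pt: tuple[float, float]    # (u, v)
    end_pt: tuple[float, float]
    rgb_left: tuple[float, float, float]
    rgb_right: tuple[float, float, float]
    source_edge: int
    direction: str                   # "forward" | "reversed"
    seam_copy: bool = False


class NodeSet:
    """Array-backed collection of directed nodes.

    Attributes (all length n): start_uv, end_uv (log-polar), cart_start,
    cart_end (canvas px), rgb_left, rgb_right, source_edge, direction
    (0 forward / 1 reversed), seam (bool), base (index of the non-seam
    original of each node).
    """

    def __init__(self, start_uv, end_uv, cart_start, cart_end, rgb_left, rgb_right,
                 source_edge, direction, seam, base):
        self.start_uv = start_uv
        self.end_uv = end_uv
        self.cart_start = cart_start
        self.cart_end = cart_end
        self.rgb_left = rgb_left
        self.rgb_right = rgb_right
        self.source_edge = source_edge
        self.direction = direction
        self.seam = seam
        self.base = base

    def __len__(self) -> int:
        return len(self.source_edge)

    def __getitem__(self, i: int) -> GraphNode:
        return GraphNode(
            start_pt=tuple(self.start_uv[i]),
            end_pt=tuple(self.end_uv[i]),
            rgb_left=tuple(self.rgb_left[i]),
            rgb_right=tuple(self.rgb_right[i]),
            source_edge=int(self.source_edge[i]),
            direction="forward" if self.direction[i] == 0 else "reversed",
            seam_copy=bool(self.seam[i]),
        )

    @property
    def contrast(self) -> np.ndarray:
        """Per-node color contrast CC in [0, 255]."""
        return np.abs(self.rgb_left - self.rgb_right).mean(axis=1)


def _wrap_pi(a: np.ndarray) -> np.ndarray:
    return np.mod(a + math.pi, _TWO_PI) - math.pi


def build_nodes(stimulus: StimulusCanvas, frame: LogPolarFrame) -> NodeSet:
    """Two directed nodes per stimulus edge, plus seam duplicates.

    Endpoint angles are unwrapped around each edge's midpoint angle so an
    edge straddling the 0/2*pi seam keeps contiguous coordinates; every
    node whose midpoint v lies within band_px of the seam is duplicated
    at v + out_size (the duplicate of the start node is the Dijkstra
    goal).
    """
    p1, p2 = stimulus.endpoints_arrays()
    rgb_l, rgb_r = all_side_colors(stimulus)
    n = len(stimulus.edges)

    r1, t1 = frame.radius_angle(p1)
    r2, t2 = frame.radius_angle(p2)
    mids = (p1 + p2) / 2.0
    rm, tm = frame.radius_angle(mids)
    if np.any(rm == 0) or np.any(r1 == 0) or np.any(r2 == 0):
        raise ValueError("an edge endpoint or midpoint lies exactly at fixation")
    n_clip = int(np.sum(r1 < frame.r_min) + np.sum(r2 < frame.r_min))
    if n_clip:
        logger.info("build_nodes: clipped %d endpoint(s) to r_min", n_clip)
    r1c = np.maximum(r1, frame.r_min)
    r2c = np.maximum(r2, frame.r_min)

    u1 = (np.log(r1c) - math.log(frame.r_min)) * frame.u_per_ln
    u2 = (np.log(r2c) - math.log(frame.r_min)) * frame.u_per_ln
    tm_rel = np.mod(tm - frame.theta_ref, _TWO_PI)
    # a midpoint angle of exactly 0 can round to 2*pi - eps; keep it at 0 so
    # the start edge is duplicated across the seam
    tm_rel = np.where(tm_rel > _TWO_PI - 1e-9, tm_rel - _TWO_PI, tm_rel)
    t1_rel = tm_rel + _wrap_pi(t1 - tm)
    t2_rel = tm_rel + _wrap_pi(t2 - tm)
    v1 = t1_rel * frame.v_per_rad
    v2 = t2_rel * frame.v_per_rad
    vm = tm_rel * frame.v_per_rad

    ep1 = np.stack([u1, v1], axis=1)
    ep2 = np.stack([u2, v2], axis=1)

    keep = np.hypot(*(ep2 - ep1).T) > 1e-9
    if not keep.all():
        logger.info("build_nodes: dropped %d edge(s) collapsed at r_min", int((~keep).sum()))

    idx = np.flatnonzero(keep)
    m = len(idx)
    # forward nodes then reversed nodes
    start_uv = np.concatenate([ep1[idx], ep2[idx]])
    end_uv = np.concatenate([ep2[idx], ep1[idx]])
    cart_start = np.concatenate([p1[idx], p2[idx]])
    cart_end = np.concatenate([p2[idx], p1[idx]])
    rgb_left = np.concatenate([rgb_l[idx], rgb_r[idx]])
    rgb_right = np.concatenate([rgb_r[idx], rgb_l[idx]])
    source_edge = np.concatenate([idx, idx])
    direction = np.concatenate([np.zeros(m, int), np.ones(m, int)])
    seam = np.zeros(2 * m, dtype=bool)
    base = np.arange(2 * m)
    vmid = np.concatenate([vm[idx], vm[idx]])

    dup = np.flatnonzero(vmid < frame.band_px)
    if len(dup):
        shift = np.array([0.0, float(frame.out_size)])
        start_uv = np.concatenate([start_uv, start_uv[dup] + shift])
        end_uv = np.concatenate([end_uv, end_uv[dup] + shift])
        cart_start = np.concatenate([cart_start, cart_start[dup]])
        cart_end = np.concatenate([cart_end, cart_end[dup]])
        rgb_left = np.concatenate([rgb_left, rgb_left[dup]])
        rgb_right = np.concatenate([rgb_right, rgb_right[dup]])
        source_edge = np.concatenate([source_edge, source_edge[dup]])
        direction = np.concatenate([direction, direction[dup]])
        seam = np.concatenate([seam, np.ones(len(dup), dtype=bool)])
        base = np.concatenate([base, dup])

    return NodeSet(start_uv, end_uv, cart_start, cart_end, rgb_left, rgb_right,
                   source_edge, direction, seam, base)


# -- connections and features ----------------------------------------------

@dataclass
class Connections:
    """Directed connections with their raw feature values."""

    from_idx: np.ndarray
    to_idx: np.ndarray
    D: np.ndarray
    TA: np.ndarray
    CS: np.ndarray

    def __len__(self) -> int:
        return len(self.from_idx)


def connect_nodes(nodes: NodeSet, window_px: float = WINDOW_PX) -> tuple[np.ndarray, np.ndarray]:
    """A -> B iff B.start lies in the axis-aligned square of side
    ``window_px`` centered on A.end.  Nodes sharing a source edge (self,
    reversed twin, seam copies thereof) are never connected."""
    half = window_px / 2.0
    tree = cKDTree(nodes.start_uv)
    lists = tree.query_ball_point(nodes.end_uv, r=half, p=np.inf)
    from_idx = np.concatenate([np.full(len(l), i, dtype=np.int64) for i, l in enumerate(lists)]) \
        if len(lists) else np.empty(0, np.int64)
    to_idx = np.concatenate([np.asarray(l, dtype=np.int64) for l in lists]) \
        if len(lists) else np.empty(0, np.int64)
    ok = nodes.source_edge[from_idx] != nodes.source_edge[to_idx]
    return from_idx[ok], to_idx[ok]


def compute_features(nodes: NodeSet, from_idx: np.ndarray, to_idx: np.ndarray) -> Connections:
    """Raw (D, TA, CS) per connection, all in log-polar coordinates."""
    a_start = nodes.start_uv[from_idx]
    a_end = nodes.end_uv[from_idx]
    b_start = nodes.start_uv[to_idx]
    b_end = nodes.end_uv[to_idx]

    gap = b_start - a_end
    D = np.hypot(gap[:, 0], gap[:, 1])
    dir_a = a_end - a_start
    dir_b = b_end - b_start
    # zero-length interpolation: take A's direction as the gap direction
    degenerate = D < 1e-12
    gap_dir = np.where(degenerate[:, None], dir_a, gap)

    def ang(u, v):
        cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
        dot = (u * v).sum(axis=1)
        return np.arctan2(cross, dot)

    psi1 = ang(dir_a, gap_dir)
    psi2 = ang(gap_dir, dir_b)
    TA = np.abs(psi1) + np.abs(psi2)

    d_left = np.abs(nodes.rgb_left[from_idx] - nodes.rgb_left[to_idx]).mean(axis=1)
    d_right = np.abs(nodes.rgb_right[from_idx] - nodes.rgb_right[to_idx]).mean(axis=1)
    CS = np.minimum(d_left, d_right)

    return Connections(from_idx=from_idx, to_idx=to_idx, D=D, TA=TA, CS=CS)


# -- scalar feature operations (single-pair API, used by small tests) -------

def turning_angle(a: GraphNode, b: GraphNode) -> float:
    """|psi1| + |psi2| in radians for the interpolation A -> B."""
    a_start, a_end = np.array(a.start_pt), np.array(a.end_pt)
    b_start, b_end = np.array(b.start_pt), np.array(b.end_pt)
    dir_a = a_end - a_start
    gap = b_start - a_end
    if np.hypot(*gap) < 1e-12:
        gap = dir_a
    dir_b = b_end - b_start

    def ang(u, v):
        return math.atan2(u[0] * v[1] - u[1] * v[0], float(np.dot(u, v)))

    return abs(ang(dir_a, gap)) + abs(ang(gap, dir_b))


def color_similarity(a: GraphNode, b: GraphNode) -> float:
    d_left = float(np.abs(np.array(a.rgb_left) - np.array(b.rgb_left)).mean())
    d_right = float(np.abs(np.array(a.rgb_right) - np.array(b.rgb_right)).mean())
    return min(d_left, d_right)


def color_contrast(node: GraphNode) -> float:
    return float(np.abs(np.array(node.rgb_left) - np.array(node.rgb_right)).mean())


def connection_cost(a: GraphNode, b: GraphNode, coeffs: CostCoefficients) -> float:
    """Cost of A -> B; color contrast is attributed to the destination node."""
    d = math.hypot(b.start_pt[0] - a.end_pt[0], b.start_pt[1] - a.end_pt[1])
    ta = turning_angle(a, b)
    cs = color_similarity(a, b)
    cc = color_contrast(b)
    return (coeffs.a1 * d * d / DISTANCE_NORM + coeffs.a2 * ta / _TWO_PI
            + coeffs.a3 * cs / 255.0 + coeffs.a4 * (1.0 - cc / 255.0))


# -- assembled graph --------------------------------------------------------

class BoundaryGraph:
    """Nodes + windowed connections + raw features for one trial frame.

    Features are coefficient-independent, so the same graph can be
    re-scored cheaply for many coefficient sets (common random numbers in
    grid searches).
    """

    def __init__(self, nodes: NodeSet, conns: Connections, frame: LogPolarFrame):
        self.nodes = nodes
        self.conns = conns
        self.frame = frame

    def costs(self, coeffs: CostCoefficients, cc_attribution: str = "destination") -> np.ndarray:
        cc = self.nodes.contrast
        c = self.conns
        if cc_attribution == "destination":
            cc_term = cc[c.to_idx]
        elif cc_attribution == "source":
            cc_term = cc[c.from_idx]
        elif cc_attribution == "mean":
            cc_term = 0.5 * (cc[c.from_idx] + cc[c.to_idx])
        else:
            raise ValueError("cc_attribution must be destination, source or mean")
        return (coeffs.a1 * c.D ** 2 / DISTANCE_NORM
                + coeffs.a2 * c.TA / _TWO_PI
                + coeffs.a3 * c.CS / 255.0
                + coeffs.a4 * (1.0 - cc_term / 255.0))


def build_graph(stimulus: StimulusCanvas, frame: LogPolarFrame,
                window_px: float = WINDOW_PX) -> BoundaryGraph:
    nodes = build_nodes(stimulus, frame)
    from_idx, to_idx = connect_nodes(nodes, window_px)
    conns = compute_features(nodes, from_idx, to_idx)
    return BoundaryGraph(nodes, conns, frame)
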