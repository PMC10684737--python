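"""Global least-cost closed-boundary extraction via Dijkstra.

Because the angular coordinate is 2*pi-periodic, a closed contour around
fixation is exactly a path from the start edge's node at v ~ 0 to that
node's seam duplicate at v + out_size.  Dijkstra on the nonnegative-cost
connection graph therefore yields the globally least-cost *closed*
boundary; mapping the winning node sequence back to the canvas and
joining consecutive edges with straight segments produces the closed
polygon (first vertex == last vertex, exactly).

The direction of travel is not prescribed: both directed nodes of the
start edge are tried and the cheaper solution kept (ties: fewer nodes,
then the lower start-node index).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra as _dijkstra

from .graph import BoundaryGraph, CostCoefficients, build_graph
from .logpolar import LogPolarFrame, choose_reference
from .stimulus import StimulusCanvas

logger = logging.getLogger(__name__)


class NoClosedPathError(RuntimeError):
    """The goal (seam duplicate of the start node) is unreachable."""


@dataclass
class BoundaryPath:
    """A solved closed boundary."""

    node_ids: list[int]                  # start node ... its seam duplicate
    total_cost: float
    polygon: np.ndarray                  # (m, 2) closed: first row == last row
    per_connection_features: np.ndarray  # (len(node_ids)-1, 4): D, TA, CS, CC_dest
    start_edge: Optional[int] = None


def solve_shortest_path(n_nodes: int, from_idx, to_idx, costs, source: int, target: int
                        ) -> tuple[float, list[int]]:
    """Dijkstra s-t shortest path on an explicit directed edge list.

    Returns (total_cost, node path).  Raises NoClosedPathError if the
    target is unreachable.  Zero-cost edges are legal.
    """
    fi = np.asarray(from_idx, dtype=np.int64)
    ti = np.asarray(to_idx, dtype=np.int64)
    cw = np.asarray(costs, dtype=float)
    # parallel edges: keep the cheapest (csr construction would sum them)
    order = np.lexsort((cw, ti, fi))
    fi, ti, cw = fi[order], ti[order], cw[order]
    first = np.ones(len(fi), dtype=bool)
    first[1:] = (fi[1:] != fi[:-1]) | (ti[1:] != ti[:-1])
    m = sp.csr_matrix((cw[first], (fi[first], ti[first])), shape=(n_nodes, n_nodes))
    dist, pred = _dijkstra(m, indices=source, return_predecessors=True)
    if not np.isfinite(dist[target]):
        raise NoClosedPathError(f"no closed path from node {source} to {target}")
    path = [target]
    while path[-1] != source:
        p = pred[path[-1]]
        if p < 0:
            raise NoClosedPathError("predecessor chain broken")
        path.append(int(p))
    path.reverse()
    return float(dist[target]), path


def path_to_polygon(nodes, node_ids: Sequence[int]) -> np.ndarray:
    """Closed Cartesian polygon of a solved path.

    The final node is the seam duplicate of the first, so its Cartesian
    endpoints repeat the first node's; it is dropped and the start vertex
    appended, which closes the polygon exactly.
    """
    verts = []
    for i in node_ids[:-1]:
        verts.append(nodes.cart_start[i])
        verts.append(nodes.cart_end[i])
    verts.append(nodes.cart_start[node_ids[0]])
    return np.array(verts, dtype=float)


def shortest_closed_path(graph: BoundaryGraph, start_edge_id: int,
                         coeffs: CostCoefficients,
                         cc_attribution: str = "destination") -> BoundaryPath:
    """Least-cost closed boundary through the start edge.

    Runs Dijkstra from each of the start edge's two directed nodes to its
    own seam duplicate and keeps the cheaper solution.
    """
    nodes = graph.nodes
    costs = graph.costs(coeffs, cc_attribution)
    starts = np.flatnonzero((nodes.source_edge == start_edge_id) & ~nodes.seam)
    if len(starts) == 0:
        raise ValueError(f"edge {start_edge_id} has no nodes in this graph")

    goals = []
    for s in starts:
        g = np.flatnonzero(nodes.seam & (nodes.base == s))
        if len(g) != 1:
            raise NoClosedPathError(
                f"start node {s} has no seam duplicate; was theta_ref chosen on this edge?")
        goals.append(int(g[0]))

    # graph-built connection lists have unique (from, to) pairs, so the
    # matrix can be assembled directly and both directed starts solved in
    # one Dijkstra call
    n = len(nodes)
    mat = sp.csr_matrix((costs, (graph.conns.from_idx, graph.conns.to_idx)), shape=(n, n))
    dist, pred = _dijkstra(mat, indices=starts, return_predecessors=True)

    candidates = []
    for row, (s, goal) in enumerate(zip(starts, goals)):
        if not np.isfinite(dist[row, goal]):
            continue
        path = [goal]
        while path[-1] != s:
            p = pred[row, path[-1]]
            if p < 0:
                path = None
                break
            path.append(int(p))
        if path is None:
            continue
        path.reverse()
        candidates.append((float(dist[row, goal]), len(path), int(s), path))
    if not candidates:
        raise NoClosedPathError(f"no closed path through edge {start_edge_id}")
    cost, _, _, path = min(candidates, key=lambda c: (c[0], c[1], c[2]))

    feats = _path_features(graph, path)
    return BoundaryPath(
        node_ids=path,
        total_cost=cost,
        polygon=path_to_polygon(nodes, path),
        per_connection_features=feats,
        start_edge=start_edge_id,
    )


def _path_features(graph: BoundaryGraph, path: Sequence[int]) -> np.ndarray:
    c = graph.conns
    cc = graph.nodes.contrast
    n = len(graph.nodes)
    # 1-based connection-index matrix for O(1) (from, to) lookups
    idx_mat = sp.csr_matrix((np.arange(len(c), dtype=np.int64) + 1,
                             (c.from_idx, c.to_idx)), shape=(n, n))
    out = np.zeros((len(path) - 1, 4))
    for j, (a, b) in enumerate(zip(path[:-1], path[1:])):
        k = int(idx_mat[int(a), int(b)]) - 1
        if k < 0:
            raise RuntimeError("path step is not a known connection")
        out[j] = (c.D[k], c.TA[k], c.CS[k], cc[int(b)])
    return out


def solve_stimulus(stimulus: StimulusCanvas, start_edge_id: int,
                   coeffs: CostCoefficients, cc_attribution: str = "destination",
                   graph: Optional[BoundaryGraph] = None) -> BoundaryPath:
    """Convenience wrapper: frame from the start edge, graph, solve."""
    if graph is None:
        theta_ref = choose_reference(stimulus.edges[start_edge_id], stimulus.fixation)
        frame = LogPolarFrame(fixation=stimulus.fixation, theta_ref=theta_ref)
        graph = build_graph(stimulus, frame)
    return shortest_closed_path(graph, start_edge_id, coeffs, cc_attribution)


def estimate_start(stimulus: StimulusCanvas, candidate_edge_ids: Sequence[int],
                   coeffs: CostCoefficients, cc_attribution: str = "destination"
                   ) -> tuple[int, BoundaryPath]:
    """Try several start edges (each with its own reference angle and
    graph) and return the minimum-cost closed boundary."""
    if not len(candidate_edge_ids):
        raise ValueError("need at least one candidate start edge")
    best: Optional[tuple[float, int, BoundaryPath]] = None
    for eid in candidate_edge_ids:
        try:
            path = solve_stimulus(stimulus, int(eid), coeffs, cc_attribution)
        except NoClosedPathError:
            continue
        if best is None or path.total_cost < best[0]:
            best = (path.total_cost, int(eid), path)
    if best is None:
        raise NoClosedPathError("no candidate start edge admits a closed path")
    return best[1], best[2]
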