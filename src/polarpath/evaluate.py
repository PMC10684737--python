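"""Seeded experiments and signal-detection statistics.

The 2AFC convention: left-pointing eggs are "noise" trials, right-pointing
eggs are "signal plus noise".  A hit is responding "right" on a right
trial, a false alarm is responding "right" on a left trial, and

    d' = z(H) - z(F)

with perfect rates corrected to 1/(2n) and 1 - 1/(2n).  The standard
error of d' uses the Macmillan & Creelman variance formula

    SE^2 = H(1-H) / (n_s * phi(z_H)^2) + F(1-F) / (n_n * phi(z_F)^2).

Coefficient sweeps (turning-angle sweep, color grid search) share one
stimulus set and one start edge per trial across all coefficient cells
(common random numbers): each trial's graph features are built once and
only the cost assembly and Dijkstra run are repeated per cell, so
cell-to-cell differences reflect the coefficients alone.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import norm

from .decide import pointing_decision
from .graph import CostCoefficients, build_graph
from .logpolar import LogPolarFrame, choose_reference
from .optimize import NoClosedPathError, shortest_closed_path
from .stimulus import WHITE, EggParams, StimulusCanvas, assemble_stimulus

logger = logging.getLogger(__name__)


# -- d' ---------------------------------------------------------------------

def dprime(hits: int, fas: int, n_signal: int, n_noise: int) -> tuple[float, float]:
    """Sensitivity d' and its standard error from hit/false-alarm counts."""
    if n_signal <= 0 or n_noise <= 0:
        raise ValueError("trial counts must be positive")
    h = hits / n_signal
    f = fas / n_noise
    h = min(max(h, 1.0 / (2 * n_signal)), 1.0 - 1.0 / (2 * n_signal))
    f = min(max(f, 1.0 / (2 * n_noise)), 1.0 - 1.0 / (2 * n_noise))
    zh, zf = norm.ppf(h), norm.ppf(f)
    d = zh - zf
    var = (h * (1 - h) / (n_signal * norm.pdf(zh) ** 2)
           + f * (1 - f) / (n_noise * norm.pdf(zf) ** 2))
    return float(d), float(math.sqrt(var))


# -- experiment harness -----------------------------------------------------

@dataclass
class ExperimentResult:
    """Per-condition outcome of a seeded model run."""

    condition: dict
    coeffs: CostCoefficients
    n_trials: int
    responses: list[tuple[str, str]]          # (truth, response)
    hits: int
    false_alarms: int
    n_signal: int
    n_noise: int
    d_prime: float
    se_d: float
    prop_correct: float
    n_failures: int = 0                       # solver errors counted as guesses

    @property
    def se_prop(self) -> float:
        p = self.prop_correct
        return math.sqrt(p * (1 - p) / self.n_trials)


def _tally(condition: dict, coeffs: CostCoefficients,
           responses: list[tuple[str, str]], n_failures: int) -> ExperimentResult:
    n = len(responses)
    n_signal = sum(1 for t, _ in responses if t == "right")
    n_noise = n - n_signal
    hits = sum(1 for t, r in responses if t == "right" and r == "right")
    fas = sum(1 for t, r in responses if t == "left" and r == "right")
    correct = sum(1 for t, r in responses if t == r)
    d, se = dprime(hits, fas, n_signal, n_noise)
    return ExperimentResult(
        condition=condition, coeffs=coeffs, n_trials=n, responses=responses,
        hits=hits, false_alarms=fas, n_signal=n_signal, n_noise=n_noise,
        d_prime=d, se_d=se, prop_correct=correct / n, n_failures=n_failures)


def filter_white_edges(stimulus: StimulusCanvas) -> StimulusCanvas:
    """Drop every pure-white edge (the white-background filtering variant)."""
    kept = [e for e in stimulus.edges if tuple(e.rgb) != WHITE]
    return StimulusCanvas(
        edges=kept, egg=stimulus.egg, condition=stimulus.condition,
        fixation=stimulus.fixation, width=stimulus.width, height=stimulus.height,
        worley=stimulus.worley, seed=stimulus.seed, outline=stimulus.outline)


def sweep_coefficients(
    coeff_sets: Sequence[CostCoefficients],
    condition: str,
    n_trials: int,
    seed: int,
    k: float = 0.08,
    jitter_deg: float = 20.0,
    filter_white: bool = False,
    peripheral: bool = False,
    cc_attribution: str = "destination",
) -> list[ExperimentResult]:
    """Run the same seeded trials under several coefficient sets.

    Stimuli, start edges and graphs are shared across coefficient sets;
    only cost assembly and the shortest-path run differ per set.
    """
    if n_trials % 2:
        raise ValueError("n_trials must be even (half left, half right)")
    master = np.random.default_rng(seed)
    truths = ["left"] * (n_trials // 2) + ["right"] * (n_trials // 2)
    master.shuffle(truths)
    children = np.random.SeedSequence(seed).spawn(n_trials)

    responses: list[list[tuple[str, str]]] = [[] for _ in coeff_sets]
    failures = [0] * len(coeff_sets)
    cond_desc = dict(condition=condition, k=k, jitter_deg=jitter_deg,
                     filter_white=filter_white, peripheral=peripheral)

    for t, (truth, child) in enumerate(zip(truths, children)):
        rng = np.random.default_rng(child)
        stim = assemble_stimulus(
            condition, EggParams(k=k, pointing=truth, jitter_deg=jitter_deg),
            rng, peripheral=peripheral)
        if filter_white:
            stim = filter_white_edges(stim)
        graph = None
        boundary = stim.boundary_indices()
        start = int(rng.choice(boundary)) if boundary else None
        if start is not None:
            theta_ref = choose_reference(stim.edges[start], stim.fixation)
            frame = LogPolarFrame(fixation=stim.fixation, theta_ref=theta_ref)
            graph = build_graph(stim, frame)
        for ci, coeffs in enumerate(coeff_sets):
            tie_rng = np.random.default_rng([seed, t, ci])
            if graph is None:
                responses[ci].append((truth, "left" if tie_rng.random() < 0.5 else "right"))
                failures[ci] += 1
                continue
            try:
                path = shortest_closed_path(graph, start, coeffs, cc_attribution)
                decision = pointing_decision(path.polygon, tie_rng)
                responses[ci].append((truth, decision.response))
            except (NoClosedPathError, RuntimeError) as exc:
                logger.info("trial %d coeffs %s: solver failure (%s); forced guess",
                            t, coeffs.label, exc)
                responses[ci].append((truth, "left" if tie_rng.random() < 0.5 else "right"))
                failures[ci] += 1

    return [_tally(cond_desc, c, responses[ci], failures[ci])
            for ci, c in enumerate(coeff_sets)]


def run_condition(
    condition: str,
    coeffs: CostCoefficients,
    n_trials: int,
    seed: int,
    k: float = 0.08,
    jitter_deg: float = 20.0,
    filter_white: bool = False,
    peripheral: bool = False,
    cc_attribution: str = "destination",
) -> ExperimentResult:
    """One seeded model experiment (n_trials/2 left + n_trials/2 right)."""
    return sweep_coefficients(
        [coeffs], condition, n_trials, seed, k=k, jitter_deg=jitter_deg,
        filter_white=filter_white, peripheral=peripheral,
        cc_attribution=cc_attribution)[0]


# -- protocol sweeps --------------------------------------------------------

@dataclass
class GridSearchResult:
    a3_grid: np.ndarray
    a4_grid: np.ndarray
    d_prime: np.ndarray        # shape (len(a3_grid), len(a4_grid))
    baseline: float            # d' of the (a3=0, a4=0) contour-only cell
    results: list[ExperimentResult]


def grid_search(
    k: float,
    condition: str,
    a2_fixed: float,
    a3_grid: Sequence[float],
    a4_grid: Sequence[float],
    n_per_cell: int,
    seed: int,
    a1: float = 1.0,
    jitter_deg: float = 20.0,
) -> GridSearchResult:
    """d' over a color-coefficient grid on one shared stimulus set."""
    a3_grid = np.asarray(list(a3_grid), dtype=float)
    a4_grid = np.asarray(list(a4_grid), dtype=float)
    if not len(a3_grid) or not len(a4_grid):
        raise ValueError("coefficient grids must be nonempty")
    cells = [CostCoefficients(a1, a2_fixed, a3, a4) for a3 in a3_grid for a4 in a4_grid]
    baseline_cell = CostCoefficients(a1, a2_fixed, 0.0, 0.0)
    extra = [] if any(c.a3 == 0 and c.a4 == 0 for c in cells) else [baseline_cell]
    results = sweep_coefficients(cells + extra, condition, n_per_cell, seed,
                                 k=k, jitter_deg=jitter_deg)
    mat = np.array([r.d_prime for r in results[:len(cells)]]).reshape(len(a3_grid), len(a4_grid))
    if extra:
        baseline = results[-1].d_prime
    else:
        i3 = int(np.flatnonzero(a3_grid == 0)[0])
        i4 = int(np.flatnonzero(a4_grid == 0)[0])
        baseline = float(mat[i3, i4])
    return GridSearchResult(a3_grid=a3_grid, a4_grid=a4_grid, d_prime=mat,
                            baseline=baseline, results=results[:len(cells)])


def turning_angle_sweep(
    a2_values: Sequence[float],
    k: float,
    n_trials: int,
    seed: int,
    condition: str = "no_color",
    jitter_deg: float = 20.0,
    a1: float = 1.0,
) -> list[ExperimentResult]:
    """d' as a function of the turning-angle coefficient, shared stimuli."""
    cells = [CostCoefficients(a1, a2, 0.0, 0.0) for a2 in a2_values]
    return sweep_coefficients(cells, condition, n_trials, seed, k=k, jitter_deg=jitter_deg)


def jitter_sweep(
    jitter_levels: Sequence[float] = tuple(range(0, 45, 5)),
    coeffs: CostCoefficients = CostCoefficients(1.0, 0.8, 0.0, 0.0),
    n_per_level: int = 400,
    seed: int = 0,
    k: float = 0.04,
    condition: str = "no_color",
) -> list[ExperimentResult]:
    """Proportion correct per orientation-jitter level (no-color protocol)."""
    out = []
    for lvl_i, lvl in enumerate(jitter_levels):
        out.append(run_condition(condition, coeffs, n_per_level,
                                 seed=int(np.random.SeedSequence([seed, lvl_i]).generate_state(1)[0] % (2 ** 31)),
                                 k=k, jitter_deg=float(lvl)))
    return out


# -- local-interpolation baseline ------------------------------------------

def local_interpolation_baseline(stimulus: StimulusCanvas,
                                 max_turn_deg: float = 40.0) -> list[list[int]]:
    """Greedy local chaining (the operation a purely local grouping
    mechanism could perform): each edge endpoint links to its nearest
    other-edge endpoint whose turning angle is at most ``max_turn_deg``;
    connected components of the resulting links are returned as chains
    (lists of edge indices).  Demonstrates local failure at high jitter.
    """
    n = len(stimulus.edges)
    if n == 0:
        return []
    p1, p2 = stimulus.endpoints_arrays()
    pts = np.concatenate([p1, p2])                 # endpoint j of edge (j % n)
    other = np.concatenate([p2, p1])               # the far endpoint
    tree = cKDTree(pts)
    kq = min(2 * n, 26)
    dists, nbrs = tree.query(pts, k=kq)
    max_ta = math.radians(max_turn_deg)

    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for j in range(2 * n):
        e = j % n
        link_pt = pts[j]
        dir_a = link_pt - other[j]
        for q in range(1, kq):
            cand = int(nbrs[j, q])
            ce = cand % n
            if ce == e:
                continue
            gap = pts[cand] - link_pt
            gd = gap if np.hypot(*gap) > 1e-12 else dir_a
            dir_b = other[cand] - pts[cand]
            psi1 = math.atan2(dir_a[0] * gd[1] - dir_a[1] * gd[0], float(np.dot(dir_a, gd)))
            psi2 = math.atan2(gd[0] * dir_b[1] - gd[1] * dir_b[0], float(np.dot(gd, dir_b)))
            if abs(psi1) + abs(psi2) <= max_ta:
                union(e, ce)
                break

    comps: dict[int, list[int]] = {}
    for e in range(n):
        comps.setdefault(find(e), []).append(e)
    return sorted(comps.values(), key=len, reverse=True)
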