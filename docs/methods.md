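# Methods

This note documents the model, the stimulus generator, the numerical
choices, and the scales at which the bundled experiments run.  It states
no empirical number that the tests or `scripts/acceptance.py` do not
themselves compute.

## Model

**Log-polar frame.**  The image is mapped about the fixation point by the
conformal complex logarithm: a point at radius `r` (px) and angle `θ`
(radians, measured counterclockwise after negating the screen's downward
y-axis) maps to

    u = (ln r − ln r_min) / (ln r_max − ln r_min) · 1920
    v = ((θ − θ_ref) mod 2π) / 2π · 1920

`θ_ref` is the angle of the midpoint of the trial's start edge, so the
start edge sits at `v ≈ 0`.  `r_max` is half the canvas diagonal
(≈ 1101 px).  For a *square* 1920 × 1920 output the radial and angular
scales must agree or the map shears local angles; we therefore set
`r_min = r_max · e^{−2π}` (≈ 2.06 px), which makes the two scales equal
(≈ 305.6 log-polar px per ln-unit and per radian) and the map exactly
conformal.  Geometry is kept in continuous coordinates; the raster
exists only for visualization.  Points inside `r_min` are clipped to
`r_min` (logged); this affects essentially no generated edges.

**Graph.**  Every edge yields two directed nodes (endpoint order =
direction of travel) with left/right region colors; reversing a node
swaps both the endpoints and the color pair, so the two directions carry
the same between-side contrast.  Edge endpoint angles are unwrapped
around the edge's midpoint angle so an edge straddling the 0/2π seam
keeps contiguous coordinates.  Every node whose midpoint `v` lies within
240 px of the seam is duplicated at `v + 1920`; the duplicate of the
start node is the goal, which turns "find a closed contour around
fixation" into a plain s–t shortest-path problem.  Connectivity is
windowed: A → B iff B's start point lies in the axis-aligned
240 × 240-px square centered on A's end point; nodes sharing a source
edge are never connected (prevents zero-cost backtracking through a
node's own twin or seam copy).

**Cost.**  `a1·D²/1920 + a2·TA/2π + a3·CS/255 + a4·(1 − CC/255)` with all
features computed in log-polar coordinates.  `D` is the Euclidean gap
from A's end to B's start (squared to penalize long interpolations
progressively; scaling the shape about fixation leaves `D` unchanged).
`TA = |ψ₁| + |ψ₂|` where ψ₁ is the signed bend from A's direction onto
the interpolation segment and ψ₂ the bend from the interpolation onto
B's direction; when the gap has zero length the interpolation direction
is taken as A's direction (the limit as the gap shrinks).  RGB
differences are collapsed to scalars by the channel-wise mean absolute
difference, so the /255 normalizers land in [0, 1].  `CC` is attributed
to the *destination* node, so each node's contrast is counted exactly
once along a path; attribution to the source or the pair mean is
available as an option (`cc_attribution`) since the choice is not forced
by the cost function's definition.

**Optimization.**  Dijkstra (scipy.sparse.csgraph) runs from each of the
start edge's two directed nodes to its own seam duplicate; the cheaper
solution wins (ties: fewer nodes, then lower node index; ties *within*
a run follow scipy's deterministic scan order).  Parallel duplicate
connections keep the cheapest cost.  An unreachable goal raises an
error; the experiment harness records such trials as forced random
guesses, preserving the trial count like a forced-choice subject.  This
genuinely occurs when a large egg-center displacement leaves fixation
within ~60 px of the boundary: consecutive retained boundary fragments
then subtend more than the 240-px angular window and, in the
white-filtered condition, no other colored edges bridge the gap.

**Decision.**  The closed polygon (edge segments alternating with
straight interpolations; first vertex equals last exactly) is split by
the vertical line at the midpoint of its x-range; the response is the
side with the smaller area.  Exact ties draw a seeded random response.
Self-intersecting polygons (possible for noisy solutions) fall back to
areas counted on an even-odd rasterized mask at 1-px resolution.

## Stimulus generator

The generator emulates the 2AFC display: a 1920 × 1080 canvas, 48 × 27
grid of 40 × 40-px cells, one 24-px noise edge per cell (the central
60 %), centers jittered by a uniform amount in [0, 10] px in a uniform
direction under a no-overlap constraint (minimum segment separation
2 px, since edges are 1 px thick; a cell that cannot be placed in 100
attempts keeps its unjittered center).  The egg
`x²/(25²(1 ± kx)) + y²/24² = 1` is sampled in formula units by
root-finding along rays (closed-form quadratic branches serve as the
test oracle) and anisotropically rescaled so its circumscribed rectangle
is exactly 450 × 360 px; `pointing="left"` mirrors the curve.  The egg
center is displaced from fixation by a uniform random vector over the
disk of radius 0.5 × minor semi-axis (fixation always stays inside the
shape); the peripheral variant instead places the center outside the
circle covering the central 50 % of the canvas area.  The boundary is
divided into `round(perimeter/24)` equal-arc chords (forced even, random
starting offset), and every other chord is kept — support ratio exactly
0.5.  Orientation jitter `j` rotates each retained chord about its
midpoint by a magnitude uniform in [j−5°, j+5°] with random sign
(`j = 0`: none; `j = 180`: uniform in ±180°).  Noise edges passing
within 3 px of an egg edge are removed to avoid T-junctions.  Region
membership for coloring uses the un-jittered outline polygon.  Worley
coloring draws 5–9 uniform seeds, each with a distinct color from a
fixed 20-color palette (categorical hues at CIELAB lightness ≈ 50,
within the stated 40–60 band; the display's exact colors are not
published, so the palette is this package's own).  All per-trial
randomness flows from one seed in a fixed draw order.

What the generator does *not* emulate: monitor colorimetry, rendering
anti-aliasing, and any deviation of the original stimulus files from
their printed construction rules.  Passing tests therefore validate the
method on stimuli with the published statistical structure, not
bit-identical reproductions.

## Experiments and scales

`run_condition` runs n/2 left- and n/2 right-pointing trials in seeded
random order; left-pointing is the "noise" class, so
`d′ = z(hits) − z(false alarms)` with rates 0 and 1 replaced by 1/(2n)
and 1 − 1/(2n), and `SE²(d′) = H(1−H)/(n_s·φ(z_H)²) + F(1−F)/(n_n·φ(z_F)²)`.
The start edge of each trial is a uniformly random retained boundary
edge; `estimate_start` (minimum cost over several candidate starts) is
available separately.  The white-filter variant removes edges with RGB
exactly (255, 255, 255) before graph construction.

Coefficient sweeps (the color grid search and the turning-angle sweep)
share one stimulus set, one start edge, and one graph per trial across
all coefficient cells — features are coefficient-independent, so only
cost assembly and the Dijkstra run repeat per cell.  Differences between
cells therefore reflect the coefficients alone (common random numbers).

Problem sizes used by the bundled suites, chosen to keep a full run on
one CPU comfortable: the white-filtered discrimination runs the full
400 trials; the jitter sweep runs 9 levels (0°–40°, step 5°) at 100
trials per level; the turning-angle sweep runs 11 coefficients (0–4,
step 0.4, at k = 0.08, the distortion whose chosen coefficient 1.2 feeds
the white-filtered protocol) at 100 trials per point; the
color-coefficient grid check runs a 3 × 3 grid on the random-background
condition at 50 trials per cell; the shortest-path oracle comparison
uses 1000 random graphs of at most 10 nodes.
`scripts/acceptance.py` recomputes the white-filtered d′ from scratch at
n = 400.

## Known limitations

- The model is defined only for fixation inside the shape; the
  peripheral stimulus variant is generated but not modeled.
- Interpolations are straight segments; no spline/elastica smoothing.
- Color is compared in RGB, not a perceptually uniform space.
- With strong turning-angle weighting the least-cost path can favor
  smooth large-radius contours through the noise field (log-polar hop
  distances shrink with radius), which bounds attainable accuracy at
  low jitter slightly below ceiling.
- Jitter-180° protocols and fitting coefficients to individual subjects
  are out of scope.
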