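"""Graph construction: nodes, side colors, connectivity window, cost features."""

import math

import numpy as np
import pytest

import polarpath as pp
from polarpath.graph import (
    WINDOW_PX,
    GraphNode,
    all_side_colors,
    build_nodes,
    compute_features,
    connect_nodes,
)
from polarpath.logpolar import LogPolarFrame, choose_reference


def node(start, end, left=(255, 255, 255), right=(255, 255, 255)):
    return GraphNode(start_pt=start, end_pt=end, rgb_left=left, rgb_right=right,
                     source_edge=0, direction="forward")


def frame_for(stimulus, edge_id):
    theta = choose_reference(stimulus.edges[edge_id], stimulus.fixation)
    return LogPolarFrame(fixation=stimulus.fixation, theta_ref=theta)


class TestNodes:
    def test_two_directed_nodes_per_edge(self, white_bg_stimulus):
        stim = white_bg_stimulus
        nodes = build_nodes(stim, frame_for(stim, stim.boundary_indices()[0]))
        non_seam = ~nodes.seam
        assert non_seam.sum() == 2 * len(stim.edges)
        # each edge appears once forward, once reversed
        fwd = nodes.source_edge[non_seam & (nodes.direction == 0)]
        rev = nodes.source_edge[non_seam & (nodes.direction == 1)]
        assert sorted(fwd) == sorted(rev) == list(range(len(stim.edges)))

    def test_reversed_twin_swaps_endpoints_and_colors(self, white_bg_stimulus):
        stim = white_bg_stimulus
        nodes = build_nodes(stim, frame_for(stim, stim.boundary_indices()[0]))
        m = len(stim.edges)
        for i in range(0, 20):
            f, r = nodes[i], nodes[i + m]       # build order: forward block then reversed
            assert f.source_edge == r.source_edge
            assert np.allclose(f.start_pt, r.end_pt) and np.allclose(f.end_pt, r.start_pt)
            assert f.rgb_left == r.rgb_right and f.rgb_right == r.rgb_left

    def test_twins_share_color_contrast(self, white_bg_stimulus):
        stim = white_bg_stimulus
        nodes = build_nodes(stim, frame_for(stim, stim.boundary_indices()[0]))
        m = len(stim.edges)
        cc = nodes.contrast
        assert np.allclose(cc[:m], cc[m:2 * m])

    def test_empty_stimulus_gives_empty_nodeset(self):
        stim = pp.StimulusCanvas(edges=[], egg=None, condition="no_color")
        nodes = build_nodes(stim, LogPolarFrame(fixation=stim.fixation))
        assert len(nodes) == 0


class TestSideColors:
    def test_all_white_surround_gives_white_both_sides(self, no_color_stimulus):
        left, right = all_side_colors(no_color_stimulus)
        # interior edges have neighbors on both sides; all colors are white
        has_both = (left.sum(axis=1) > 0) & (right.sum(axis=1) > 0)
        assert has_both.mean() > 0.9
        assert np.allclose(left[has_both], 255.0) and np.allclose(right[has_both], 255.0)

    def test_reversing_edge_swaps_sides(self, white_bg_stimulus):
        stim = white_bg_stimulus
        e = stim.edges[stim.boundary_indices()[0]]
        l1, r1 = pp.sample_side_colors(e, stim)
        rev = pp.EdgeSegment(p1=e.p2, p2=e.p1, rgb=e.rgb, label=e.label)
        l2, r2 = pp.sample_side_colors(rev, stim)
        assert np.allclose(l1, r2) and np.allclose(r1, l2)

    def test_boundary_interior_side_tracks_worley_color(self):
        """Across colored stimuli, the side of a boundary edge facing the egg
        interior should match the local Worley color better than the
        exterior side does."""
        hits = total = 0
        for seed in range(15):
            stim = pp.assemble_stimulus("white_background",
                                        pp.EggParams(k=0.08, jitter_deg=20), seed)
            left, right = all_side_colors(stim)
            cx, cy = stim.egg.center
            for i in stim.boundary_indices():
                e = stim.edges[i]
                ref = np.array(stim.worley.color_at(e.midpoint), dtype=float)
                d = np.array(e.p2) - np.array(e.p1)
                w = np.array([cx, cy]) - np.array(e.midpoint)
                inward_is_left = d[0] * w[1] - d[1] * w[0] < 0
                inner = left[i] if inward_is_left else right[i]
                outer = right[i] if inward_is_left else left[i]
                hits += (np.abs(inner - ref).mean() < np.abs(outer - ref).mean())
                total += 1
        assert hits / total >= 0.9


class TestConnectivity:
    def test_matches_brute_force_window(self, white_bg_stimulus):
        stim = white_bg_stimulus
        nodes = build_nodes(stim, frame_for(stim, stim.boundary_indices()[0]))
        fi, ti = connect_nodes(nodes)
        got = set(zip(fi.tolist(), ti.tolist()))
        sub = np.arange(min(len(nodes), 120))
        half = WINDOW_PX / 2.0
        for a in sub:
            for b in sub:
                ok = (nodes.source_edge[a] != nodes.source_edge[b]
                      and abs(nodes.start_uv[b, 0] - nodes.end_uv[a, 0]) <= half
                      and abs(nodes.start_uv[b, 1] - nodes.end_uv[a, 1]) <= half)
                assert ((int(a), int(b)) in got) == ok

    def test_never_connects_self_or_twin(self, white_bg_stimulus):
        stim = white_bg_stimulus
        nodes = build_nodes(stim, frame_for(stim, stim.boundary_indices()[0]))
        fi, ti = connect_nodes(nodes)
        assert (nodes.source_edge[fi] != nodes.source_edge[ti]).all()


class TestTurningAngle:
    def test_collinear_codirected_is_zero(self):
        a = node((0.0, 0.0), (10.0, 0.0))
        b = node((20.0, 0.0), (30.0, 0.0))
        assert pp.turning_angle(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_reversed_second_edge_is_pi(self):
        a = node((0.0, 0.0), (10.0, 0.0))
        b = node((30.0, 0.0), (20.0, 0.0))
        assert pp.turning_angle(a, b) == pytest.approx(math.pi, abs=1e-12)

    def test_right_angle_elbow_bisected_is_half_pi(self):
        # A travels +x into a 45-deg gap, B leaves the gap at 90 deg to A
        a = node((0.0, 0.0), (10.0, 0.0))
        b = node((15.0, 5.0), (15.0, 15.0))
        assert pp.turning_angle(a, b) == pytest.approx(math.pi / 2, abs=1e-12)

    def test_zero_gap_uses_first_direction(self):
        a = node((0.0, 0.0), (10.0, 0.0))
        b = node((10.0, 0.0), (20.0, 10.0))
        assert pp.turning_angle(a, b) == pytest.approx(math.pi / 4, abs=1e-12)

    def test_direction_permutations_differ(self):
        p, q, r, s = (0.0, 0.0), (10.0, 3.0), (18.0, 10.0), (30.0, 8.0)
        tas = {round(pp.turning_angle(node(*pair_a), node(*pair_b)), 9)
               for pair_a in ((p, q), (q, p)) for pair_b in ((r, s), (s, r))}
        assert len(tas) >= 3


class TestColorFeatures:
    def test_color_similarity_examples(self):
        a = node((0, 0), (1, 0), left=(200, 0, 0), right=(0, 0, 0))
        b = node((2, 0), (3, 0), left=(200, 0, 0), right=(255, 255, 255))
        assert pp.color_similarity(a, b) == 0.0
        a = node((0, 0), (1, 0), left=(10, 10, 10), right=(10, 10, 10))
        b = node((2, 0), (3, 0), left=(40, 10, 10), right=(10, 70, 10))
        assert pp.color_similarity(a, b) == pytest.approx(10.0)

    def test_color_contrast_examples(self):
        assert pp.color_contrast(node((0, 0), (1, 0))) == 0.0
        assert pp.color_contrast(
            node((0, 0), (1, 0), left=(255, 255, 255), right=(0, 0, 0))) == 255.0
        assert pp.color_contrast(
            node((0, 0), (1, 0), left=(255, 0, 0), right=(0, 0, 255))) == pytest.approx(170.0)

    def test_connection_cost_hand_arithmetic(self):
        """D=48, TA=pi/2, CS=10, CC_B=170 with coeffs [1,2,1,1]."""
        a = node((0.0, 0.0), (10.0, 0.0),
                 left=(10, 10, 10), right=(20, 20, 20))
        gap = 48.0 / math.sqrt(2)
        b = node((10.0 + gap, gap), (10.0 + gap, gap + 10.0),
                 left=(180, 180, 180), right=(10, 10, 10))
        coeffs = pp.CostCoefficients(1, 2, 1, 1)
        # 1.2 + 0.5 + 0.0392157 + 0.3333333
        assert pp.connection_cost(a, b, coeffs) == pytest.approx(2.0725490196, abs=1e-9)

    def test_zero_cost_cases(self):
        a = node((0.0, 0.0), (10.0, 0.0))
        b = node((10.0, 0.0), (20.0, 0.0))
        assert pp.connection_cost(a, b, pp.CostCoefficients(1, 1, 0, 0)) == 0.0
        b2 = node((10.0, 0.0), (20.0, 0.0), left=(5, 5, 5), right=(5, 5, 5))
        assert pp.connection_cost(a, b2, pp.CostCoefficients(0, 0, 0, 1)) == 1.0

    def test_negative_coefficients_rejected(self):
        with pytest.raises(ValueError):
            pp.CostCoefficients(1, -0.5, 0, 0)


class TestGraphProperties:
    def test_costs_nonnegative(self, white_bg_stimulus):
        stim = white_bg_stimulus
        g = pp.build_graph(stim, frame_for(stim, stim.boundary_indices()[0]))
        for coeffs in (pp.CostCoefficients(1, 1.2, 0, 0), pp.CostCoefficients(1, 2, 3, 1)):
            assert (g.costs(coeffs) >= 0).all()

    def test_reversal_symmetry_of_contour_features(self, ring_stimulus):
        frame = frame_for(ring_stimulus, 0)
        nodes = build_nodes(ring_stimulus, frame)
        fi, ti = connect_nodes(nodes)
        c = compute_features(nodes, fi, ti)
        m = len(ring_stimulus.edges)

        def twin(i):
            # forward block then reversed block (non-seam); seam copies at end
            if nodes.seam[i]:
                return None
            return i + m if i < m else i - m

        lookup = {(int(a), int(b)): k for k, (a, b) in enumerate(zip(fi, ti))}
        checked = 0
        for k in range(len(fi)):
            a, b = int(fi[k]), int(ti[k])
            ra, rb = twin(a), twin(b)
            if ra is None or rb is None:
                continue
            k2 = lookup.get((rb, ra))
            if k2 is None:
                continue
            assert c.D[k] == pytest.approx(c.D[k2], abs=1e-9)
            assert c.TA[k] == pytest.approx(c.TA[k2], abs=1e-9)
            checked += 1
        assert checked > 10

    def test_scale_invariance_of_colorfree_costs(self):
        """Scaling all coordinates about fixation leaves D and TA unchanged."""
        base = pp.assemble_stimulus("no_color", pp.EggParams(k=0.08, jitter_deg=20), 3)
        # keep a compact subset so the scaled version stays on canvas
        fix = np.array(base.fixation)
        keep = [e for e in base.edges
                if np.hypot(*(np.array(e.midpoint) - fix)) < 250]
        stim1 = pp.StimulusCanvas(edges=keep, egg=base.egg, condition="no_color")
        scaled_edges = []
        for e in keep:
            p1 = tuple(fix + (np.array(e.p1) - fix) * 1.5)
            p2 = tuple(fix + (np.array(e.p2) - fix) * 1.5)
            scaled_edges.append(pp.EdgeSegment(p1=p1, p2=p2, rgb=e.rgb, label=e.label))
        stim2 = pp.StimulusCanvas(edges=scaled_edges, egg=base.egg, condition="no_color")
        f1 = frame_for(stim1, 0)
        f2 = frame_for(stim2, 0)
        n1, n2 = build_nodes(stim1, f1), build_nodes(stim2, f2)
        fi1, ti1 = connect_nodes(n1)
        fi2, ti2 = connect_nodes(n2)
        assert np.array_equal(fi1, fi2) and np.array_equal(ti1, ti2)
        c1 = compute_features(n1, fi1, ti1)
        c2 = compute_features(n2, fi2, ti2)
        assert np.allclose(c1.D, c2.D, atol=1e-6)
        assert np.allclose(c1.TA, c2.TA, atol=1e-6)

    def test_color_permutation_does_not_change_colorfree_path(self, white_bg_stimulus):
        stim = white_bg_stimulus
        start = stim.boundary_indices()[0]
        coeffs = pp.CostCoefficients(1, 1.2, 0, 0)
        p1 = pp.solve_stimulus(stim, start, coeffs)
        recolored = pp.StimulusCanvas(
            edges=[pp.EdgeSegment(p1=e.p1, p2=e.p2, label=e.label,
                                  rgb=pp.PALETTE[(i * 7) % 20])
                   for i, e in enumerate(stim.edges)],
            egg=stim.egg, condition=stim.condition, fixation=stim.fixation)
        p2 = pp.solve_stimulus(recolored, start, coeffs)
        assert p1.node_ids == p2.node_ids
        assert p1.total_cost == pytest.approx(p2.total_cost, abs=1e-9)

    def test_coefficient_parsing_and_label(self):
        c = pp.CostCoefficients.from_string("1,1.2,0,0")
        assert c == pp.CostCoefficients(1.0, 1.2, 0.0, 0.0)
        assert c.label == "[1,1.2,0,0]"
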