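import numpy as np
import pytest

from spiralflow.graph import Node, Segment, VascularGraph
from spiralflow.hemodynamics import (
    FlowProblem,
    classify_terminals,
    segment_conductance,
    solve_flow,
)

MU = 3.5e-3


def hagen_poiseuille_g(r_um, l_um, mu=MU):
    return np.pi * (r_um * 1e-6) ** 4 / (8 * mu * l_um * 1e-6)


def _tube_graph(r_um=50.0, l_um=1000.0, n_nodes=2, parallel=1):
    g = VascularGraph(voxel_size_um=1.0)
    g.nodes[0] = Node(np.array([0.0, 0.0, 0.0]), radius_um=r_um)
    g.nodes[1] = Node(np.array([l_um, 0.0, 0.0]), radius_um=r_um)
    nid = 2
    for k in range(parallel):
        chain = [0]
        for i in range(1, n_nodes - 1):
            # parallel copies share identical geometry (distinct node ids)
            g.nodes[nid] = Node(
                np.array([l_um * i / (n_nodes - 1), 0.0, 0.0]), radius_um=r_um
            )
            chain.append(nid)
            nid += 1
        chain.append(1)
        g.segments[k] = Segment(chain=chain, vessel_class=1)
    return g


class TestSegmentConductance:
    def test_closed_form_uniform_tube(self):
        g = _tube_graph()
        cond = segment_conductance(g.segment_positions(0), g.segment_radii(0), MU)
        assert cond == pytest.approx(7.0125e-13, rel=1e-3)
        assert cond == pytest.approx(hagen_poiseuille_g(50, 1000), rel=1e-12)

    def test_series_split_invariance(self):
        g1 = _tube_graph(n_nodes=2)
        g2 = _tube_graph(n_nodes=3)
        c1 = segment_conductance(g1.segment_positions(0), g1.segment_radii(0), MU)
        c2 = segment_conductance(g2.segment_positions(0), g2.segment_radii(0), MU)
        assert c2 == pytest.approx(c1, rel=1e-12)

    def test_fourth_power_radius_scaling(self):
        g1 = _tube_graph(r_um=40.0)
        g2 = _tube_graph(r_um=20.0)
        c1 = segment_conductance(g1.segment_positions(0), g1.segment_radii(0), MU)
        c2 = segment_conductance(g2.segment_positions(0), g2.segment_radii(0), MU)
        assert c1 / c2 == pytest.approx(16.0, rel=1e-12)

    def test_nonpositive_radius_rejected(self):
        g = _tube_graph()
        with pytest.raises(ValueError, match="radii"):
            segment_conductance(g.segment_positions(0), np.array([0.0, 0.0]), MU)


class TestSolveFlow:
    def test_single_tube_matches_closed_form(self):
        g = _tube_graph(n_nodes=12)
        sol = solve_flow(FlowProblem(g, inlets=[0], outlets=[1], viscosity=MU))
        r_expected = 1.0 / hagen_poiseuille_g(50, 1000)
        assert sol.resistance == pytest.approx(r_expected, rel=1e-9)
        assert sol.conductance == pytest.approx(1.0 / r_expected, rel=1e-9)

    def test_two_parallel_tubes_double_conductance(self):
        g1 = _tube_graph(n_nodes=6, parallel=1)
        g2 = _tube_graph(n_nodes=6, parallel=2)
        s1 = solve_flow(FlowProblem(g1, [0], [1], viscosity=MU))
        s2 = solve_flow(FlowProblem(g2, [0], [1], viscosity=MU))
        assert s2.conductance == pytest.approx(2 * s1.conductance, rel=1e-12)

    def test_resistance_invariant_under_pressure_gradient(self):
        g = _tube_graph(n_nodes=8)
        r = [
            solve_flow(FlowProblem(g, [0], [1], delta_p=dp, viscosity=MU)).resistance
            for dp in (1000.0, 2000.0)
        ]
        assert r[0] == pytest.approx(r[1], rel=1e-12)

    def test_flow_scales_linearly_with_pressure(self):
        g = _tube_graph(n_nodes=8)
        q = [
            solve_flow(FlowProblem(g, [0], [1], delta_p=dp, viscosity=MU)).total_outflow
            for dp in (500.0, 1500.0)
        ]
        assert q[1] == pytest.approx(3 * q[0], rel=1e-12)

    def test_series_parallel_composition_against_two_resistor_formulas(self):
        rng = np.random.default_rng(8)
        r = float(rng.uniform(20, 60))
        lengths = rng.uniform(300, 900, size=2)
        g = VascularGraph(voxel_size_um=1.0)
        for nid, x in ((0, 0.0), (2, lengths[0]), (1, lengths.sum())):
            g.nodes[nid] = Node(np.array([x, 0.0, 0.0]), radius_um=r)
        g.segments[0] = Segment(chain=[0, 2], vessel_class=1)
        g.segments[1] = Segment(chain=[2, 1], vessel_class=1)
        sol = solve_flow(FlowProblem(g, [0], [1], viscosity=MU))
        g_a = hagen_poiseuille_g(r, lengths[0])
        g_b = hagen_poiseuille_g(r, lengths[1])
        series = 1.0 / (1.0 / g_a + 1.0 / g_b)
        assert sol.conductance == pytest.approx(series, rel=1e-9)
        # parallel: add a direct bypass segment 0-1
        g.segments[2] = Segment(chain=[0, 1], vessel_class=1)
        g_c = hagen_poiseuille_g(r, float(lengths.sum()))
        sol2 = solve_flow(FlowProblem(g, [0], [1], viscosity=MU))
        assert sol2.conductance == pytest.approx(series + g_c, rel=1e-9)

    def test_radius_scaling_never_decreases_conductance(self):
        rng = np.random.default_rng(12)
        g = _random_tree(rng, n_segments=40)
        inlets, outlets = _leaf_split(g)
        base = solve_flow(FlowProblem(g, inlets, outlets, viscosity=MU)).conductance
        for nid in g.nodes:
            g.nodes[nid].radius_um *= 1.3
        scaled = solve_flow(FlowProblem(g, inlets, outlets, viscosity=MU)).conductance
        assert scaled > base

    def test_uniform_radius_scaling_is_fourth_power(self):
        g = _tube_graph(n_nodes=10)
        base = solve_flow(FlowProblem(g, [0], [1], viscosity=MU)).conductance
        for nid in g.nodes:
            g.nodes[nid].radius_um *= 2.0
        scaled = solve_flow(FlowProblem(g, [0], [1], viscosity=MU)).conductance
        assert scaled == pytest.approx(16 * base, rel=1e-9)

    def test_no_path_reports_zero_conductance_not_error(self):
        g = _tube_graph()
        g2 = _tube_graph()
        # two disjoint tubes; inlet on one, outlet on the other
        merged = VascularGraph(voxel_size_um=1.0)
        merged.nodes.update(g.nodes)
        merged.segments[0] = g.segments[0]
        for nid, n in g2.nodes.items():
            merged.nodes[nid + 10] = Node(n.position + 500.0, radius_um=n.radius_um)
        merged.segments[1] = Segment(chain=[10, 11], vessel_class=1)
        sol = solve_flow(FlowProblem(merged, [0], [11], viscosity=MU))
        assert sol.conductance == 0.0
        assert "no inlet-outlet path" in sol.diagnostic

    def test_interior_conservation(self):
        rng = np.random.default_rng(3)
        g = _random_tree(rng, n_segments=60)
        inlets, outlets = _leaf_split(g)
        sol = solve_flow(FlowProblem(g, inlets, outlets, viscosity=MU))
        assert sol.total_outflow > 0
        assert sol.max_interior_residual <= 1e-10 * sol.total_outflow


def _random_tree(rng, n_segments):
    """Random tree of straight segments with random radii and lengths."""
    g = VascularGraph(voxel_size_um=1.0)
    g.nodes[0] = Node(np.zeros(3), radius_um=float(rng.uniform(30, 60)))
    for i in range(1, n_segments + 1):
        parent = int(rng.integers(0, i))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        length = float(rng.uniform(100, 600))
        g.nodes[i] = Node(
            g.nodes[parent].position + direction * length,
            radius_um=float(rng.uniform(15, 60)),
        )
        g.segments[i - 1] = Segment(chain=[parent, i], vessel_class=1)
    return g


def _leaf_split(g):
    leaves = g.terminals()
    half = max(1, len(leaves) // 2)
    return leaves[:half], leaves[half:]


class TestClassifyTerminals:
    def test_tree_phantom_roles_match_ground_truth(self, site_phantom, site_graph):
        inlets, outlets, roles = classify_terminals(site_graph, site_phantom.labels)
        truth_roles = sorted(t.role for t in site_phantom.truth_terminals)
        assert sorted(roles.values()) == truth_roles

    def test_terminal_near_canal_only_is_outlet(self):
        import spiralflow as sf

        labels = np.zeros((40, 21, 21), dtype=np.uint8)
        labels[5:30, 8:13, 8:13] = 1  # spiral column (odd width: axis on centers)
        labels[30:36, 8:13, 8:13] = 3  # canal cap at the far end
        labels[2:5, 8:13, 8:13] = 2  # radial cap at the near end
        lv = sf.LabelVolume(labels, 1.0)
        g = sf.build_graph(sf.skeletonize(lv.class_mask((1, 2, 3))), lv)
        inlets, outlets, roles = classify_terminals(g, lv)
        assert len(inlets) == 1 and len(outlets) == 1
        # the outlet is the terminal nearer the canal cap
        assert g.nodes[outlets[0]].position[0] > g.nodes[inlets[0]].position[0]

    def test_isolated_spiral_rejected(self):
        import spiralflow as sf

        labels = np.zeros((30, 16, 16), dtype=np.uint8)
        labels[5:25, 6:10, 6:10] = 1
        lv = sf.LabelVolume(labels, 1.0)
        g = sf.build_graph(sf.skeletonize(lv.class_mask((1,))), lv)
        with pytest.raises(ValueError, match="ill-posed"):
            classify_terminals(g, lv)


def test_flow_problem_validation():
    g = _tube_graph()
    with pytest.raises(ValueError, match="disjoint"):
        FlowProblem(g, inlets=[0], outlets=[0])
    with pytest.raises(ValueError, match="delta_p"):
        FlowProblem(g, inlets=[0], outlets=[1], delta_p=-1.0)
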