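import numpy as np
import pytest

from spiralflow.graph import Node, Segment, VascularGraph
from spiralflow.morphometry import (
    apply_size_filter,
    measure_segments,
    summarize_site,
)


def _segment_graph(specs, voxel_size_um=1.0):
    """Build a graph from [(positions, radii, vessel_class), ...]."""
    g = VascularGraph(voxel_size_um=voxel_size_um)
    nid = 0
    for sid, (positions, radii, cls) in enumerate(specs):
        chain = []
        for p, r in zip(positions, radii):
            g.nodes[nid] = Node(np.asarray(p, float), radius_um=float(r))
            chain.append(nid)
            nid += 1
        g.segments[sid] = Segment(chain=chain, vessel_class=cls)
    return g


class TestMeasureSegments:
    def test_collinear_chain_length(self):
        g = _segment_graph(
            [([(0, 0, 0), (10, 0, 0), (25, 0, 0)], [5, 5, 5], 1)]
        )
        measure_segments(g, integration_step_vox=0)
        assert g.segments[0].length_um == pytest.approx(25.0)

    def test_constant_radius_frustum_equals_cylinder(self):
        n = 40
        pos = [(2.5 * i, 0, 0) for i in range(n)]
        g = _segment_graph([(pos, [7.0] * n, 1)])
        measure_segments(g, integration_step_vox=0)
        L = 2.5 * (n - 1)
        assert g.segments[0].volume_um3 == pytest.approx(np.pi * 49 * L, rel=1e-12)

    def test_two_node_frustum_formula(self):
        g = _segment_graph([([(0, 0, 0), (3, 0, 0)], [2.0, 4.0], 1)])
        measure_segments(g, integration_step_vox=0)
        assert g.segments[0].volume_um3 == pytest.approx(np.pi * 28.0, rel=1e-12)

    def test_unset_radii_rejected(self):
        g = _segment_graph([([(0, 0, 0), (5, 0, 0)], [np.nan, 3.0], 1)])
        with pytest.raises(ValueError, match="unset"):
            measure_segments(g)

    def test_refinement_changes_length_below_tolerance(self):
        # same smooth arc sampled at two densities
        t1 = np.linspace(0, np.pi / 2, 60)
        t2 = np.linspace(0, np.pi / 2, 240)
        mk = lambda t: [(100 * np.cos(a), 100 * np.sin(a), 0.0) for a in t]
        g1 = _segment_graph([(mk(t1), [8.0] * len(t1), 1)])
        g2 = _segment_graph([(mk(t2), [8.0] * len(t2), 1)])
        measure_segments(g1, integration_step_vox=0)
        measure_segments(g2, integration_step_vox=0)
        rel = abs(g2.segments[0].length_um - g1.segments[0].length_um) / g1.segments[0].length_um
        assert rel < 1e-3


class TestSizeFilter:
    def test_strict_threshold_example(self):
        specs = []
        for mean_r, length in ((5.0, 50.0), (10.0, 8.0), (12.0, 40.0)):
            n = 5
            pos = [(length * i / (n - 1), 0, 0) for i in range(n)]
            specs.append((pos, [mean_r] * n, 1))
        g = _segment_graph(specs)
        measure_segments(g, integration_step_vox=0)
        view = apply_size_filter(g, 10.0, 10.0)
        assert view.segment_ids == [2]  # only (12 um, 40 um) survives both

    def test_exact_threshold_excluded(self):
        pos = [(10.0 * i, 0, 0) for i in range(2)]
        g = _segment_graph([(pos, [10.0, 10.0], 1)])
        measure_segments(g, integration_step_vox=0)
        view = apply_size_filter(g, 10.0, 10.0)
        assert view.segment_ids == []  # length == 10 and radius == 10: strict >
        assert view.node_ids == []

    def test_zero_thresholds_are_identity(self):
        g = _segment_graph([([(0, 0, 0), (30, 0, 0)], [4.0, 4.0], 1)])
        measure_segments(g, integration_step_vox=0)
        view = apply_size_filter(g, 0.0, 0.0)
        assert view.segment_ids == [0]
        assert view.node_ids == [0, 1]


class TestSummarizeSite:
    def _uniform_two_segment_graph(self):
        specs = []
        for length in (100.0, 200.0):
            n = 9
            pos = [(length * i / (n - 1), len(specs) * 50.0, 0) for i in range(n)]
            specs.append((pos, [10.0] * n, 1))
        g = _segment_graph(specs)
        measure_segments(g, integration_step_vox=0)
        return g

    def test_means_and_ratio(self):
        view = apply_size_filter(self._uniform_two_segment_graph(), 5.0, 10.0)
        s = summarize_site(view, "siteX")
        assert s.mean_segment_length_um == pytest.approx(150.0)
        assert s.mean_diameter_um == pytest.approx(20.0)
        assert s.length_to_diameter_ratio == pytest.approx(7.5)
        assert s.n_segments == 2
        assert s.total_length_um == pytest.approx(300.0)

    def test_node_basis_vs_segment_basis(self):
        # one long thin + one short thick segment: node-mean diameter is
        # dominated by the long segment, segment-mean length is unweighted
        long_pos = [(i * 10.0, 0, 0) for i in range(21)]  # 200 um, r 6
        short_pos = [(i * 10.0, 50, 0) for i in range(3)]  # 20 um, r 20
        g = _segment_graph([(long_pos, [6.0] * 21, 1), (short_pos, [20.0] * 3, 1)])
        measure_segments(g, integration_step_vox=0)
        view = apply_size_filter(g, 0.0, 0.0)
        s = summarize_site(view, "basis")
        node_mean_d = (21 * 12.0 + 3 * 40.0) / 24
        assert s.mean_diameter_um == pytest.approx(node_mean_d)
        assert s.mean_segment_length_um == pytest.approx((200.0 + 20.0) / 2)

    def test_empty_after_filter_names_site(self):
        g = _segment_graph([([(0, 0, 0), (5, 0, 0)], [2.0, 2.0], 1)])
        measure_segments(g, integration_step_vox=0)
        view = apply_size_filter(g, 10.0, 10.0)
        with pytest.raises(ValueError, match="siteZ"):
            summarize_site(view, "siteZ")

    def test_restricted_to_spiral_class(self):
        g = _segment_graph(
            [
                ([(0, 0, 0), (100, 0, 0)], [15.0, 15.0], 1),
                ([(0, 50, 0), (400, 50, 0)], [30.0, 30.0], 2),  # radial: excluded
            ]
        )
        measure_segments(g, integration_step_vox=0)
        view = apply_size_filter(g, 10.0, 10.0)
        s = summarize_site(view, "classes")
        assert s.n_segments == 1
        assert s.mean_diameter_um == pytest.approx(30.0)

    def test_histograms_sum_to_counts(self):
        view = apply_size_filter(self._uniform_two_segment_graph(), 5.0, 10.0)
        s = summarize_site(view, "hist")
        assert sum(s.length_histogram["counts"]) == s.n_segments
        assert sum(s.radii_histogram["counts"]) == 18  # all filtered nodes


def test_end_to_end_helix_diameter_recovery(calibration):
    from spiralflow.phantoms import make_tube_phantom
    from spiralflow.pipeline import PipelineConfig, run_site

    ph = make_tube_phantom("helix", radius_um=24.0, length_um=600.0, voxel_size_um=8.0)
    cfg = PipelineConfig(
        min_subnetwork_segments=1,
        max_radius_vox=12.0,
        calibration=calibration,
        require_flow=False,
    )
    rep = run_site(ph, cfg, site_id="helix")
    # mean diameter within half a voxel of the 48 um ground truth
    assert abs(rep.summary.mean_diameter_um - 48.0) <= 0.5 * 8.0
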