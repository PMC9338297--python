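import numpy as np
import pytest

from conftest import digital_cylinder, merge_graphs, path_graph
from spiralflow.graph import (
    Node,
    Segment,
    VascularGraph,
    build_graph,
    filter_subnetworks,
    prune_spurious,
    resample_nodes,
)
from spiralflow.skeleton import SkeletonVoxels, skeletonize
from spiralflow.voxelio import LabelVolume


def _labels_for(shape, code=1):
    return LabelVolume(np.full(shape, code, dtype=np.uint8), 1.0)


def _skel_from_voxels(voxels, shape):
    vox = np.asarray(voxels, dtype=np.int64)
    order = np.lexsort((vox[:, 2], vox[:, 1], vox[:, 0]))
    return SkeletonVoxels(vox[order], shape)


class TestBuildGraph:
    def test_straight_path_is_one_segment(self):
        vox = [(z, 5, 5) for z in range(2, 12)]
        g = build_graph(_skel_from_voxels(vox, (16, 11, 11)), _labels_for((16, 11, 11)))
        assert len(g.segments) == 1
        assert len(g.terminals()) == 2
        assert g.junctions() == []
        assert len(g.segments[0].chain) == 10

    def test_y_skeleton_three_segments_one_junction(self):
        vox = (
            [(z, 5, 5) for z in range(0, 6)]
            + [(6 + k, 5 + k, 5) for k in range(1, 5)]
            + [(6 + k, 5 - k, 5) for k in range(1, 5)]
        )
        vox.append((6, 5, 5))
        shape = (12, 11, 11)
        g = build_graph(_skel_from_voxels(vox, shape), _labels_for(shape))
        assert len(g.segments) == 3
        assert len(g.terminals()) == 3
        juncs = g.junctions()
        assert len(juncs) == 1
        occ = g.endpoint_occurrences()
        assert occ[juncs[0]] == 3

    def test_pure_cycle_anchored_at_lexicographic_minimum(self):
        # 8-voxel digital circle in one plane
        ring = [(0, 0), (0, 1), (0, 2), (1, 2), (2, 2), (2, 1), (2, 0), (1, 0)]
        vox = [(1, y + 2, x + 2) for y, x in ring]
        shape = (3, 8, 8)
        g = build_graph(_skel_from_voxels(vox, shape), _labels_for(shape))
        assert len(g.segments) == 1
        chain = g.segments[0].chain
        assert chain[0] == chain[-1]
        anchor_voxel = g.nodes[chain[0]].voxel
        assert anchor_voxel == (1, 2, 2)  # lowest lexicographic index
        comps, cycles = g.chain_graph_topology()
        assert (comps, cycles) == (1, 1)

    def test_class_transfer_by_majority(self):
        vox = [(z, 3, 3) for z in range(8)]
        labels = np.zeros((8, 7, 7), dtype=np.uint8)
        labels[:5, 3, 3] = 1  # spiral majority
        labels[5:, 3, 3] = 2
        g = build_graph(
            _skel_from_voxels(vox, labels.shape), LabelVolume(labels, 1.0)
        )
        assert g.segments[0].vessel_class == 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            build_graph(
                _skel_from_voxels([(0, 0, 0), (1, 1, 1)], (4, 4, 4)),
                _labels_for((5, 5, 5)),
            )

    def test_graph_topology_matches_skeleton_topology(self):
        from spiralflow.skeleton import component_count, cycle_count

        mask, _ = digital_cylinder(radius_vox=4, length_vox=40)
        sk = skeletonize(mask)
        g = build_graph(sk, _labels_for(mask.shape))
        comps, cycles = g.chain_graph_topology()
        m = sk.to_mask()
        assert comps == component_count(m)
        assert cycles == cycle_count(m)


class TestPruneSpurious:
    def _tube_with_spur(self):
        # thick tube (radius 5) split at mid-length by a 1-voxel spur
        g = VascularGraph(voxel_size_um=1.0)
        for i in range(11):  # main chain along x, 50 um long
            g.nodes[i] = Node(np.array([5.0 * i, 0.0, 0.0]), radius_um=5.0)
        g.nodes[100] = Node(np.array([25.0, 1.0, 0.0]), radius_um=5.0)  # 1-voxel spur
        g.segments[0] = Segment(chain=list(range(0, 6)), vessel_class=1)
        g.segments[1] = Segment(chain=list(range(5, 11)), vessel_class=1)
        g.segments[2] = Segment(chain=[5, 100], vessel_class=1)
        return g

    def test_short_terminal_spur_removed_and_halves_merged(self):
        g = prune_spurious(self._tube_with_spur())
        assert len(g.segments) == 1
        assert 100 not in g.nodes
        chain = next(iter(g.segments.values())).chain
        assert len(chain) == 11  # full main chain survives as one segment

    def test_no_short_spurs_is_fixed_point(self):
        # Y-junction with three long branches: nothing to prune or merge
        g = VascularGraph(voxel_size_um=1.0)
        g.nodes[0] = Node(np.array([0.0, 0.0, 0.0]), radius_um=5.0)
        for k, tip in enumerate(([100.0, 0, 0], [-50.0, 90, 0], [-50.0, -90, 0])):
            g.nodes[k + 1] = Node(np.array(tip, float), radius_um=5.0)
            g.segments[k] = Segment(chain=[0, k + 1], vessel_class=1)
        out = prune_spurious(g)
        assert {tuple(s.chain) for s in out.segments.values()} == {
            tuple(s.chain) for s in g.segments.values()
        }

    def test_idempotent(self):
        once = prune_spurious(self._tube_with_spur())
        twice = prune_spurious(once)
        assert {tuple(s.chain) for s in twice.segments.values()} == {
            tuple(s.chain) for s in once.segments.values()
        }

    def test_junction_cluster_link_contracted(self):
        g = VascularGraph(voxel_size_um=1.0)
        # two junctions 2 um apart, each with two long branches; radii 5 um
        pts = {
            0: [0, 0, 0], 1: [10, 0, 0],  # branch ends
            2: [20, 0, 0], 3: [22, 0, 0],  # the junction pair
            4: [30, 10, 0], 5: [30, -10, 0],
        }
        for nid, p in pts.items():
            g.nodes[nid] = Node(np.array(p, float), radius_um=5.0)
        g.segments[0] = Segment(chain=[0, 2], vessel_class=1)
        g.segments[1] = Segment(chain=[1, 2], vessel_class=1)
        g.segments[2] = Segment(chain=[2, 3], vessel_class=1)  # 2 um micro-link
        g.segments[3] = Segment(chain=[3, 4], vessel_class=1)
        g.segments[4] = Segment(chain=[3, 5], vessel_class=1)
        out = prune_spurious(g)
        assert len(out.segments) == 4  # micro-link gone, one 4-way junction
        assert len(out.junctions()) == 1


class TestFilterSubnetworks:
    def test_components_below_threshold_removed(self):
        comps = [
            path_graph(5, first_node=0, first_segment=0),
            path_graph(29, first_node=100, first_segment=100),
            path_graph(30, first_node=300, first_segment=300),
            path_graph(120, first_node=500, first_segment=500),
        ]
        g = merge_graphs(comps)
        out = filter_subnetworks(g, min_segments=30)
        sizes = sorted(
            np.bincount(list(out.subnetwork_labels().values())).tolist()
        )
        assert sizes == [30, 120]

    def test_single_large_component_unchanged(self):
        g = path_graph(100)
        out = filter_subnetworks(g, min_segments=30)
        assert set(out.segments) == set(g.segments)

    def test_all_below_threshold_warns_and_empties(self):
        g = path_graph(5)
        with pytest.warns(UserWarning, match="below"):
            out = filter_subnetworks(g, min_segments=30)
        assert len(out.segments) == 0

    def test_monotone_in_threshold(self):
        comps = [
            path_graph(k, first_node=i * 1000, first_segment=i * 1000)
            for i, k in enumerate([3, 8, 15, 40])
        ]
        g = merge_graphs(comps)
        kept = [
            len(filter_subnetworks(g, min_segments=t).segments) for t in (1, 5, 10, 30)
        ]
        assert kept == sorted(kept, reverse=True)


class TestResampleNodes:
    def _three_disjoint_segments(self):
        g = VascularGraph(voxel_size_um=1.0)
        nid = 0
        for sid, length in enumerate((50.0, 30.0, 20.0)):
            a, b = nid, nid + 1
            g.nodes[a] = Node(np.array([0.0, 10.0 * sid, 0.0]))
            g.nodes[b] = Node(np.array([length, 10.0 * sid, 0.0]))
            g.segments[sid] = Segment(chain=[a, b], vessel_class=1)
            nid += 2
        return g

    def test_largest_remainder_allocation(self):
        g = resample_nodes(self._three_disjoint_segments(), total_nodes=100)
        counts = sorted(len(s.chain) for s in g.segments.values())
        assert counts == [20, 30, 50]
        assert g.total_node_count() == 100

    def test_phantom_graph_hits_exact_default_budget(self, site_graph):
        g = resample_nodes(site_graph, total_nodes=10000)
        assert g.total_node_count() == 10000

    def test_single_segment_preserves_arc_length(self):
        g = VascularGraph(voxel_size_um=1.0)
        g.nodes[0] = Node(np.array([0.0, 0.0, 0.0]))
        g.nodes[1] = Node(np.array([123.4, 0.0, 0.0]))
        g.segments[0] = Segment(chain=[0, 1], vessel_class=1)
        out = resample_nodes(g, total_nodes=57)
        assert len(out.segments[0].chain) == 57
        assert out.chain_length_um(0) == pytest.approx(123.4, rel=1e-9)
        spacings = np.diff(
            [out.nodes[n].position[0] for n in out.segments[0].chain]
        )
        np.testing.assert_allclose(spacings, spacings[0], rtol=1e-9)

    def test_budget_too_small_rejected(self):
        g = self._three_disjoint_segments()
        with pytest.raises(ValueError, match="budget"):
            resample_nodes(g, total_nodes=5)

    def test_resampling_preserves_topology_and_endpoints(self, site_graph):
        before = site_graph.chain_graph_topology()
        out = resample_nodes(site_graph, total_nodes=5000)
        assert out.chain_graph_topology() == before
        for sid, seg in site_graph.segments.items():
            assert out.segments[sid].chain[0] == seg.chain[0]
            assert out.segments[sid].chain[-1] == seg.chain[-1]

    def test_arc_length_change_below_half_percent(self, site_graph):
        total_before = sum(
            site_graph.chain_length_um(sid) for sid in site_graph.segments
        )
        out = resample_nodes(site_graph, total_nodes=10000)
        total_after = sum(out.chain_length_um(sid) for sid in out.segments)
        assert abs(total_after - total_before) / total_before < 0.005
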