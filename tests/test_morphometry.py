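"""Centerline extraction and branch morphometry on analytic phantoms."""

import numpy as np
import pytest

from renolymph.core import BinaryMask, physical_volume
from renolymph.graph import Branch, VesselGraph
from renolymph.morphometry import (
    diameter_label_volume,
    graph_from_skeleton,
    measure_branches,
    prune_spurs,
    skeletonize,
    summarize_network,
    trace_plexus,
)
from renolymph.phantom import rasterize

SP = (1.0, 1.0, 1.0)


def tube_mask(p0, p1, radius, shape, spacing=SP):
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    g = VesselGraph(
        nodes={0: p0, 1: p1},
        branches=[Branch(id=1, centerline=np.linspace(p0, p1, 40),
                         endpoints=(0, 1), mean_diameter=2 * radius)],
    )
    _, mem = rasterize(g, shape, spacing)
    return BinaryMask(mem.labels > 0, spacing)


def multi_tube_mask(segments, shape, spacing=SP):
    nodes, branches = {}, []
    nid = 0
    for i, (p0, p1, r) in enumerate(segments, start=1):
        nodes[nid] = np.asarray(p0, float)
        nodes[nid + 1] = np.asarray(p1, float)
        branches.append(
            Branch(id=i, centerline=np.linspace(np.asarray(p0, float),
                                                np.asarray(p1, float), 40),
                   endpoints=(nid, nid + 1), mean_diameter=2 * r)
        )
        nid += 2
    g = VesselGraph(nodes=nodes, branches=branches)
    _, mem = rasterize(g, shape, spacing)
    return BinaryMask(mem.labels > 0, spacing)


class TestSkeletonize:
    def test_straight_tube_single_path(self):
        mask = tube_mask((40, 40, 10), (40, 40, 70), 5, (80, 80, 80))
        skel, iso = skeletonize(mask)
        g = graph_from_skeleton(skel, iso)
        assert g.n_branches == 1
        # endpoints near the tube ends (within one radius)
        b = g.branches[0]
        ends = sorted([b.centerline[0][2], b.centerline[-1][2]])
        assert ends[0] <= 10 + 6 and ends[1] >= 70 - 6

    def test_sphere_collapses(self):
        z, y, x = np.mgrid[0:40, 0:40, 0:40]
        ball = (z - 20) ** 2 + (y - 20) ** 2 + (x - 20) ** 2 <= 100
        skel, iso = skeletonize(BinaryMask(ball, SP))
        assert skel.sum() <= 5

    def test_torus_single_cycle(self):
        z, y, x = np.mgrid[0:30, 0:100, 0:100]
        rho = np.sqrt((y - 50.0) ** 2 + (x - 50.0) ** 2)
        torus = (rho - 30.0) ** 2 + (z - 15.0) ** 2 <= 25.0
        skel, iso = skeletonize(BinaryMask(torus, SP))
        g = graph_from_skeleton(skel, iso)
        # a pure cycle: one self-loop branch, Euler characteristic 0
        assert g.n_branches == 1
        b = g.branches[0]
        assert b.endpoints[0] == b.endpoints[1]
        assert b.length == pytest.approx(2 * np.pi * 30.0, rel=0.05)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            skeletonize(BinaryMask(np.zeros((4, 4, 4), dtype=bool), SP))

    def test_anisotropic_resampling(self):
        # same tube, anisotropic voxels: length must still be right
        mask = tube_mask((40, 60, 10), (40, 60, 130), 6,
                         (30, 120, 144), spacing=(2.77, 1.0, 1.0))
        graph = trace_plexus(mask)
        assert graph.n_branches == 1
        assert graph.branches[0].length == pytest.approx(120.0, rel=0.05)


class TestGraphFromSkeleton:
    def test_straight_tube_length(self):
        mask = tube_mask((60, 60, 10), (60, 60, 130), 6, (120, 120, 144))
        graph = trace_plexus(mask)
        assert graph.n_branches == 1
        assert graph.branches[0].length == pytest.approx(120.0, abs=2.0)

    def test_symmetric_y(self):
        stem = ((20, 60, 10), (20, 60, 60), 5)
        arm1 = ((20, 60, 60), (20, 30, 100), 4)
        arm2 = ((20, 60, 60), (20, 90, 100), 4)
        mask = multi_tube_mask([stem, arm1, arm2], (40, 120, 120))
        graph = trace_plexus(mask)
        assert graph.n_branches == 3
        deg = graph.node_degrees()
        assert sorted(deg.values()) == [1, 1, 1, 3]

    def test_ring_circumference(self):
        z, y, x = np.mgrid[0:30, 0:130, 0:130]
        rho = np.sqrt((y - 65.0) ** 2 + (x - 65.0) ** 2)
        ring = (rho - 50.0) ** 2 + (z - 15.0) ** 2 <= 16.0
        graph = trace_plexus(BinaryMask(ring, SP))
        total = graph.total_length()
        assert total == pytest.approx(2 * np.pi * 50.0, rel=0.03)


class TestPruneSpurs:
    def _y_graph(self):
        nodes = {
            0: np.array([0.0, 0.0, 0.0]),
            1: np.array([0.0, 0.0, 50.0]),
            2: np.array([0.0, 40.0, 90.0]),
            3: np.array([0.0, -3.0, 52.0]),
        }
        branches = [
            Branch(id=1, centerline=np.linspace(nodes[0], nodes[1], 20), endpoints=(0, 1)),
            Branch(id=2, centerline=np.linspace(nodes[1], nodes[2], 20), endpoints=(1, 2)),
            Branch(id=3, centerline=np.linspace(nodes[1], nodes[3], 4), endpoints=(1, 3)),
        ]
        return VesselGraph(nodes=nodes, branches=branches)

    def test_zero_min_length_identity(self):
        g = self._y_graph()
        out = prune_spurs(g, 0.0)
        assert out.n_branches == 3

    def test_short_spur_removed_and_merged(self):
        g = self._y_graph()
        out = prune_spurs(g, 10.0)
        # the 3.6 µm spur goes; the two real branches merge into one
        assert out.n_branches == 1
        assert out.branches[0].length == pytest.approx(
            g.branches[0].length + g.branches[1].length, rel=1e-6
        )

    def test_never_disconnects(self):
        g = self._y_graph()
        for cut in (0.0, 5.0, 10.0, 1000.0):
            out = prune_spurs(g, cut)
            assert out.n_branches >= 1
            assert out.is_connected()

    def test_surface_bump_pruned(self):
        mask = tube_mask((20, 40, 10), (20, 40, 110), 6, (40, 80, 120))
        # add a small bump on the surface
        bump = tube_mask((20, 46, 60), (20, 52, 60), 3, (40, 80, 120))
        merged = BinaryMask(mask.data | bump.data, SP)
        graph = trace_plexus(merged)
        assert graph.n_branches == 1


class TestMeasureBranches:
    def test_cylinder_diameter(self):
        mask = tube_mask((60, 60, 10), (60, 60, 130), 6, (120, 120, 144))
        graph = trace_plexus(mask)
        assert graph.branches[0].mean_diameter == pytest.approx(12.0, abs=1.0)

    def test_tapered_tube_mean_diameter(self):
        # cone-like tube, radius 5 -> 10: mean diameter ≈ 15
        p0, p1 = np.array([60.0, 60.0, 10.0]), np.array([60.0, 60.0, 130.0])
        pts = np.linspace(p0, p1, 25)
        nodes = {0: p0, 1: p1}
        branches = [
            Branch(id=i + 1, centerline=pts[i:i + 2], endpoints=(0, 1),
                   mean_diameter=2 * (5 + 5 * (i + 0.5) / 24))
            for i in range(24)
        ]
        # rasterize as segments of stepwise radius; re-label as one mask
        g = VesselGraph(nodes={0: p0, 1: p1}, branches=branches)
        _, mem = rasterize(g, (120, 120, 144), SP)
        mask = BinaryMask(mem.labels > 0, SP)
        graph = trace_plexus(mask)
        assert graph.n_branches == 1
        assert graph.branches[0].mean_diameter == pytest.approx(15.0, rel=0.10)

    def test_volume_conservation(self):
        stem = ((20, 60, 10), (20, 60, 60), 5)
        arm1 = ((20, 60, 60), (20, 30, 100), 4)
        arm2 = ((20, 60, 60), (20, 90, 100), 4)
        mask = multi_tube_mask([stem, arm1, arm2], (40, 120, 120))
        graph = trace_plexus(mask)
        assert sum(b.volume for b in graph.branches) == pytest.approx(
            physical_volume(mask), abs=1e-6
        )

    def test_length_at_least_span(self):
        stem = ((20, 60, 10), (20, 60, 60), 5)
        arm1 = ((20, 60, 60), (20, 30, 100), 4)
        mask = multi_tube_mask([stem, arm1], (40, 120, 120))
        graph = trace_plexus(mask)
        for b in graph.branches:
            # refined length may exceed the raw polyline; compare to span
            assert b.length >= b.euclidean_span - 1.0


class TestSummarize:
    def test_empty(self):
        s = summarize_network(VesselGraph(nodes={}, branches=[]))
        assert (s.n_branches, s.length_range, s.max_mean_diameter, s.total_volume) == (
            0, 0.0, 0.0, 0.0,
        )

    def test_length_range(self):
        nodes = {i: np.array([0.0, 0.0, float(i)]) for i in range(6)}
        branches = [
            Branch(id=i, centerline=np.array([[0, 0, 0], [0, 0, L]], float),
                   endpoints=(0, 1), mean_diameter=5.0, volume=1.0)
            for i, L in enumerate([10, 20, 30, 40, 50], start=1)
        ]
        s = summarize_network(VesselGraph(nodes=nodes, branches=branches))
        assert s.length_range == pytest.approx(40.0)
        assert s.n_branches == 5


class TestRotationInvariance:
    def test_quarter_turn(self):
        stem = ((30, 60, 10), (30, 60, 60), 5)
        arm1 = ((30, 60, 60), (30, 30, 100), 4)
        arm2 = ((30, 60, 60), (30, 90, 100), 4)
        mask = multi_tube_mask([stem, arm1, arm2], (60, 120, 120))
        rotated = BinaryMask(np.rot90(mask.data, k=1, axes=(1, 2)).copy(), SP)
        s0 = summarize_network(trace_plexus(mask))
        s1 = summarize_network(trace_plexus(rotated))
        assert s1.n_branches == s0.n_branches
        assert s1.total_volume == pytest.approx(s0.total_volume, rel=1e-6)
        assert s1.length_range == pytest.approx(s0.length_range, rel=0.05, abs=2.0)
        assert s1.max_mean_diameter == pytest.approx(s0.max_mean_diameter, rel=0.05)


class TestDiameterBins:
    def test_single_bin(self):
        mask = tube_mask((20, 40, 10), (20, 40, 110), 6, (40, 80, 120))
        graph = trace_plexus(mask)
        bins = diameter_label_volume(graph, mask, bin_edges=(20.0, 70.0))
        labels = np.unique(bins.labels)
        assert set(labels) == {0, 1}  # background + "<20 µm"

    def test_large_tube_top_bin(self):
        big = tube_mask((80, 80, 10), (80, 80, 150), 40, (160, 160, 160))
        graph = trace_plexus(big)
        bins = diameter_label_volume(graph, big, bin_edges=(20.0, 70.0))
        fg = bins.labels[big.data]
        assert set(np.unique(fg)) == {3}  # ">70 µm"
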