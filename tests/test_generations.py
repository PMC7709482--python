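"""Skeletonization, monopodial generation assignment and label spreading."""

import numpy as np
import pytest

from genstereo.core import LabelVolume
from genstereo.generations import (assign_generations, generation_volume,
                                   skeletonize, spread_labels)
from genstereo.phantom import expected_skeleton_branches


def tube_mask(shape, start, end, radius):
    """Binary mask of one cylinder between two voxel points."""
    grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"),
                    axis=-1).astype(float)
    a, b = np.asarray(start, float), np.asarray(end, float)
    ab = b - a
    t = np.clip(((grid - a) @ ab) / (ab @ ab), 0, 1)
    d = np.linalg.norm(grid - (a + t[..., None] * ab), axis=-1)
    return d <= radius


class TestSkeletonize:
    def test_straight_tube_single_branch(self):
        mask = tube_mask((30, 80, 30), (15, 8, 15), (15, 72, 15), 6)
        skel = skeletonize(LabelVolume(mask.astype(np.uint8), spacing=7.0))
        assert len(skel.branches) == 1
        assert len(skel.end_nodes()) == 2
        assert not skel.junction_nodes()

    def test_y_tube_three_branches_one_junction(self):
        shape = (40, 90, 70)
        mask = (tube_mask(shape, (20, 6, 20), (20, 50, 20), 6) |
                tube_mask(shape, (20, 50, 20), (20, 84, 40), 6) |
                tube_mask(shape, (20, 50, 20), (20, 84, 6), 6))
        skel = skeletonize(LabelVolume(mask.astype(np.uint8), spacing=7.0))
        assert len(skel.branches) == 3
        assert len(skel.junction_nodes()) == 1
        assert len(skel.end_nodes()) == 3

    def test_phantom_branch_count_matches_truth(self, default_tree, default_chain):
        tree, _ = default_tree
        skel, _, _ = default_chain
        assert len(skel.branches) == expected_skeleton_branches(tree)

    def test_three_by_three_phantom_branch_count(self):
        from genstereo.core import LUMEN
        from genstereo.phantom import TreeSpec, build_tree, rasterize
        spec = TreeSpec(branches_per_parent=3, trunk_length=2800.0,
                        length_decay=(0.2, 0.3), lumen_radius=(70.0, 34.0, 22.0),
                        wall_thickness=(16.0, 9.0, 7.0), station_span=0.5)
        tree, _ = build_tree(spec)
        ph = rasterize(tree, spacing=min(spec.lumen_radius) / 3.5)
        mask = LabelVolume((ph.compartments.data == LUMEN).astype(np.uint8),
                           spacing=ph.compartments.spacing,
                           origin=ph.compartments.origin)
        skel = skeletonize(mask, anchors=[tree.root.start])
        assert len(skel.branches) == expected_skeleton_branches(tree)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            skeletonize(LabelVolume(np.zeros((8, 8, 8), np.uint8), spacing=7.0))

    def test_node_radius_is_physical_edt(self):
        mask = tube_mask((30, 60, 30), (15, 6, 15), (15, 54, 15), 6)
        skel = skeletonize(LabelVolume(mask.astype(np.uint8), spacing=7.0))
        mid_radii = [skel.graph.nodes[n]["radius"]
                     for path in skel.branches.values() for n in path[5:-5]]
        assert np.median(mid_radii) == pytest.approx(6 * 7.0, rel=0.25)


class TestAssignGenerations:
    def test_single_path_all_generation_one(self):
        mask = tube_mask((30, 80, 30), (15, 8, 15), (15, 72, 15), 6)
        skel = skeletonize(LabelVolume(mask.astype(np.uint8), spacing=7.0))
        gm = assign_generations(skel, (15 * 7.0, 8 * 7.0, 15 * 7.0))
        assert set(gm.branch_generation.values()) == {1}

    def test_trunk_with_short_lateral(self):
        shape = (40, 110, 80)
        mask = (tube_mask(shape, (20, 6, 20), (20, 100, 20), 6) |
                tube_mask(shape, (20, 40, 20), (20, 60, 55), 5))
        skel = skeletonize(LabelVolume(mask.astype(np.uint8), spacing=7.0))
        gm = assign_generations(skel, (20 * 7.0, 6 * 7.0, 20 * 7.0))
        assert sorted(gm.branch_generation.values()) == [1, 1, 2]

    def test_phantom_generations_match_generator(self, default_tree, default_chain):
        from conftest import skeleton_probe_agreement
        tree, _ = default_tree
        skel, gm, _ = default_chain
        ok, total = skeleton_probe_agreement(tree, skel, gm)
        assert ok == total

    def test_generations_non_decreasing_from_root(self, default_chain):
        skel, gm, _ = default_chain
        # walk branch tree from the generation-1 chain outward
        node_branches = {}
        for b, path in skel.branches.items():
            for n in (path[0], path[-1]):
                node_branches.setdefault(n, []).append(b)
        for b, path in skel.branches.items():
            for n in (path[0], path[-1]):
                for other in node_branches[n]:
                    if other != b:
                        diff = abs(gm.branch_generation[b] - gm.branch_generation[other])
                        assert diff <= 1

    def test_override_table_honoured(self, default_chain):
        skel, gm, _ = default_chain
        some_branch = next(iter(skel.branches))
        gm2 = assign_generations(skel, root=next(iter(skel.end_nodes())),
                                 overrides={some_branch: 9})
        assert gm2.branch_generation[some_branch] == 9

    def test_unknown_root_rejected(self, default_chain):
        skel, _, _ = default_chain
        with pytest.raises(ValueError):
            assign_generations(skel, root=10 ** 9)

    def test_cyclic_graph_rejected(self):
        import networkx as nx
        from genstereo.generations import SkeletonGraph
        g = nx.cycle_graph(6)
        for i in g.nodes:
            g.nodes[i].update(index=(0, i, 0), coord=(0.0, float(i), 0.0), radius=1.0)
        # attach a stub so a root end-node exists
        g.add_node(6, index=(0, 6, 0), coord=(0.0, 6.0, 0.0), radius=1.0)
        g.add_edge(0, 6, length=1.0)
        for a, b in g.edges:
            g.edges[a, b]["length"] = 1.0
        branches = {1: [6, 0], 2: [0, 1, 2, 3], 3: [3, 4, 5, 0]}
        skel = SkeletonGraph(g, branches, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="cycle"):
            assign_generations(skel, 6)


class TestSpreadLabels:
    def test_single_branch_covers_whole_mask(self):
        mask = tube_mask((30, 60, 30), (15, 6, 15), (15, 54, 15), 6)
        vol = LabelVolume(mask.astype(np.uint8), spacing=7.0)
        skel = skeletonize(vol)
        out = spread_labels(skel, {b: 5 for b in skel.branches}, vol)
        assert set(np.unique(out.data[mask])) == {5}
        assert (out.data[~mask] == 0).all()

    def test_two_parallel_tubes_keep_own_labels(self):
        shape = (50, 60, 50)
        t1 = tube_mask(shape, (12, 6, 12), (12, 54, 12), 6)
        t2 = tube_mask(shape, (36, 6, 36), (36, 54, 36), 6)
        vol = LabelVolume((t1 | t2).astype(np.uint8), spacing=7.0)
        skel = skeletonize(vol)
        assert len(skel.branches) == 2
        # identify which branch lies in which tube by a node position
        labels = {}
        for b, path in skel.branches.items():
            idx = skel.node_index(path[len(path) // 2])
            labels[b] = 1 if t1[idx] else 2
        out = spread_labels(skel, labels, vol)
        assert set(np.unique(out.data[t1])) == {1}
        assert set(np.unique(out.data[t2])) == {2}

    def test_partition_conservation(self, lumen_mask, default_chain):
        _, _, voxels = default_chain
        assert np.array_equal(voxels.voxel_map.data > 0, lumen_mask.data > 0)

    def test_marker_outside_mask_rejected(self):
        mask = tube_mask((30, 60, 30), (15, 6, 15), (15, 54, 15), 6)
        vol = LabelVolume(mask.astype(np.uint8), spacing=7.0)
        skel = skeletonize(vol)
        hollow = mask.copy()
        for path in skel.branches.values():
            hollow[skel.node_index(path[len(path) // 2])] = False
        with pytest.raises(ValueError, match="outside the mask"):
            spread_labels(skel, {b: b for b in skel.branches},
                          LabelVolume(hollow.astype(np.uint8), spacing=7.0))

    def test_spread_volumes_near_analytic(self, default_tree, default_chain):
        _, truth = default_tree
        _, _, voxels = default_chain
        vvol = voxels.voxel_map.voxel_volume_um3
        for g, analytic in truth.lumen_volume_mm3.items():
            est = np.count_nonzero(voxels.voxel_map.data == g) * vvol / 1e9
            assert est == pytest.approx(analytic, rel=0.05)
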