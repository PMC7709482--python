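"""Shared fixtures: phantoms and the centerline chain, built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from genstereo.core import LUMEN, LabelVolume
from genstereo.generations import assign_generations, generation_volume, skeletonize
from genstereo.phantom import TreeSpec, build_tree, rasterize


@pytest.fixture(scope="session")
def default_tree():
    tree, truth = build_tree(TreeSpec())
    return tree, truth


@pytest.fixture(scope="session")
def default_phantom(default_tree):
    tree, truth = default_tree
    return rasterize(tree, spacing=7.0)


@pytest.fixture(scope="session")
def lumen_mask(default_phantom):
    ph = default_phantom
    return LabelVolume((ph.compartments.data == LUMEN).astype(np.uint8),
                       spacing=ph.compartments.spacing,
                       origin=ph.compartments.origin,
                       vertical_axis=ph.compartments.vertical_axis)


@pytest.fixture(scope="session")
def default_chain(default_tree, lumen_mask):
    """Skeleton, generation assignment and spread labels of the default phantom."""
    tree, truth = default_tree
    skel = skeletonize(lumen_mask, anchors=[tree.root.start])
    genmap = assign_generations(skel, tuple(tree.root.start))
    voxels = generation_volume(skel, genmap, lumen_mask)
    return skel, genmap, voxels


@pytest.fixture(scope="session")
def annulus_phantom():
    """Single annular cylinder along the vertical axis with wide parenchyma."""
    spec = TreeSpec(n_generations=1, branches_per_parent=0, trunk_length=1400.0,
                    lumen_radius=(50.0,), wall_thickness=(20.0,))
    tree, truth = build_tree(spec)
    ph = rasterize(tree, spacing=7.0, margin=320.0)
    return tree, truth, ph


def skeleton_probe_agreement(tree, skel, genmap) -> tuple[int, int]:
    """Phantom oracle for generation labels.

    Every generator branch is probed at 75% of its axis length — far from
    junction territory, where generation membership is unambiguous — and
    the skeleton branch covering the probe must carry the generator's
    generation.  Returns (agreeing branches, total branches).
    """
    node_ids = list(skel.graph.nodes)
    coords = np.array([skel.graph.nodes[n]["coord"] for n in node_ids])
    branch_of: dict[int, set[int]] = {}
    for b, path in skel.branches.items():
        for n in path:
            branch_of.setdefault(n, set()).add(b)
    ok = total = 0
    for b in tree.branches:
        probe = b.start + 0.75 * (b.end - b.start)
        d = np.linalg.norm(coords - probe, axis=1)
        node = node_ids[int(np.argmin(d))]
        total += 1
        if d.min() > b.lumen_radius + 14.0:
            continue  # probe not covered by the skeleton: disagreement
        generations = {genmap.branch_generation.get(br) for br in branch_of[node]}
        ok += b.generation in generations
    return ok, total
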