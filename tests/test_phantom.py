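"""Phantom generator: tree construction, ground truth, rasterisation, imaging."""

import math

import numpy as np
import pytest

from genstereo.core import LUMEN, PARENCHYMA, WALL, LabelVolume
from genstereo.phantom import (CenterlineTree, SectionTransform, TreeSpec,
                               apply_section_transform, build_tree,
                               expected_skeleton_branches, random_tree_spec,
                               rasterize, simulate_sections, simulate_uct,
                               tree_truth)
from genstereo.sectioning import SectionPlan


def brute_force_branch_counts(n_generations: int, branches_per_parent: int) -> dict[int, int]:
    """Independent enumeration of the branching recursion."""
    counts = {1: 1}
    for g in range(2, n_generations + 1):
        counts[g] = counts[g - 1] * branches_per_parent
    return counts


class TestBuildTree:
    def test_degenerate_tree_is_single_trunk(self):
        spec = TreeSpec(branches_per_parent=0)
        tree, truth = build_tree(spec)
        assert len(tree.branches) == 1
        assert tree.root.generation == 1

    @pytest.mark.parametrize("n_gen,bpp", [(3, 2), (2, 3), (3, 1)])
    def test_branch_counts_match_recursion(self, n_gen, bpp):
        spec = TreeSpec(n_generations=n_gen, branches_per_parent=bpp,
                        lumen_radius=(70.0, 40.0, 28.0)[:n_gen])
        tree, truth = build_tree(spec)
        assert truth.n_branches == brute_force_branch_counts(n_gen, bpp)

    def test_trunk_lumen_volume_closed_form(self):
        spec = TreeSpec(n_generations=1, branches_per_parent=0,
                        trunk_length=1000.0, lumen_radius=(50.0,),
                        wall_thickness=(20.0,))
        _, truth = build_tree(spec)
        expected_mm3 = math.pi * 50.0**2 * 1000.0 / 1e9
        assert truth.lumen_volume_mm3[1] == pytest.approx(expected_mm3, rel=1e-12)
        assert truth.luminal_surface_mm2[1] == pytest.approx(
            2 * math.pi * 50.0 * 1000.0 / 1e6, rel=1e-12)

    @pytest.mark.parametrize("bad", [
        dict(lumen_radius=(50.0, 60.0, 28.0)),              # calibre not decreasing
        dict(wall_thickness=(0.0, 12.0, 8.0)),              # non-positive wall
        dict(trunk_length=-5.0),
        dict(n_generations=0),
        dict(length_decay=(1.5, 0.4)),
    ])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            build_tree(TreeSpec(**bad))

    def test_analytic_volumes_additive_and_rotation_invariant(self, default_tree):
        tree, truth = default_tree
        per_branch = {}
        for b in tree.branches:
            per_branch[b.generation] = per_branch.get(b.generation, 0.0) + \
                b.lumen_volume_um3() / 1e9
        for g, v in truth.lumen_volume_mm3.items():
            assert v == pytest.approx(per_branch[g], rel=1e-12)
        # rotating every branch about the origin leaves the volumes unchanged
        theta = 0.7
        rot = np.array([[1, 0, 0],
                        [0, math.cos(theta), -math.sin(theta)],
                        [0, math.sin(theta), math.cos(theta)]])
        import dataclasses
        rotated = [dataclasses.replace(b, start=rot @ b.start, end=rot @ b.end)
                   for b in tree.branches]
        truth_rot = tree_truth(CenterlineTree(rotated, tree.spec))
        for g in truth.lumen_volume_mm3:
            assert truth_rot.lumen_volume_mm3[g] == pytest.approx(
                truth.lumen_volume_mm3[g], rel=1e-9)

    def test_random_specs_validate(self):
        for seed in range(5):
            spec = random_tree_spec(seed)
            spec.validate()
            radii = spec.lumen_radius
            assert all(radii[i + 1] < radii[i] for i in range(len(radii) - 1))


class TestRasterize:
    def test_voxel_volume_matches_analytic_cylinder(self):
        spec = TreeSpec(n_generations=1, branches_per_parent=0, trunk_length=1000.0,
                        lumen_radius=(50.0,), wall_thickness=(20.0,))
        tree, truth = build_tree(spec)
        ph = rasterize(tree, spacing=3.0)
        vox = ph.voxel_lumen_volume_mm3(1)
        assert vox == pytest.approx(truth.lumen_volume_mm3[1], rel=0.02)

    def test_halving_spacing_reduces_volume_error(self):
        spec = TreeSpec(n_generations=1, branches_per_parent=0, trunk_length=700.0,
                        lumen_radius=(50.0,), wall_thickness=(20.0,))
        tree, truth = build_tree(spec)
        errs = []
        for spacing in (14.0, 7.0):
            ph = rasterize(tree, spacing=spacing)
            errs.append(abs(ph.voxel_lumen_volume_mm3(1) - truth.lumen_volume_mm3[1]))
        assert errs[1] < errs[0]

    def test_empty_tree_all_parenchyma(self):
        spec = TreeSpec(branches_per_parent=0)
        tree, _ = build_tree(spec)
        empty = CenterlineTree([], spec)
        ph = rasterize(empty, spacing=20.0)
        assert (ph.compartments.data == PARENCHYMA).all()

    def test_compartment_counts_conserved(self, default_phantom):
        counts = default_phantom.compartments.label_counts()
        assert set(counts) <= {PARENCHYMA, LUMEN, WALL}
        assert sum(counts.values()) == int(np.prod(default_phantom.compartments.shape))

    def test_tree_exceeding_domain_names_branch(self, default_tree):
        tree, _ = default_tree
        with pytest.raises(ValueError, match="branch"):
            rasterize(tree, spacing=7.0, origin=(0.0, 0.0, 0.0), shape=(10, 10, 10))


class TestSimulateUct:
    def test_noiseless_blurless_is_piecewise_constant(self, default_phantom):
        vol = simulate_uct(default_phantom.compartments, noise_sd=0.0, blur_fwhm=0.0)
        data = default_phantom.compartments.data
        for cls, val in [(PARENCHYMA, 130.0), (LUMEN, 200.0), (WALL, 40.0)]:
            assert (vol.data[data == cls] == val).all()

    def test_deterministic_under_fixed_seed(self, default_phantom):
        a = simulate_uct(default_phantom.compartments, seed=9, parenchyma_texture=20.0)
        b = simulate_uct(default_phantom.compartments, seed=9, parenchyma_texture=20.0)
        np.testing.assert_array_equal(a.data, b.data)

    def test_noise_sd_matches_request(self, default_phantom):
        vol = simulate_uct(default_phantom.compartments, noise_sd=10.0, blur_fwhm=0.0,
                           seed=2)
        region = vol.data[default_phantom.compartments.data == PARENCHYMA]
        assert region.size >= 10_000
        assert np.std(region) == pytest.approx(10.0, rel=0.05)

    def test_negative_noise_rejected(self, default_phantom):
        with pytest.raises(ValueError):
            simulate_uct(default_phantom.compartments, noise_sd=-1.0)


class TestSimulateSections:
    @pytest.fixture(scope="class")
    def uct(self, default_phantom):
        return simulate_uct(default_phantom.compartments, noise_sd=3.0,
                            blur_fwhm=8.0, seed=4, parenchyma_texture=20.0)

    def test_zero_amplitude_equals_plane_extraction(self, uct):
        from genstereo.sectioning import extract_section
        plan = SectionPlan(60, 2.0, 5, 15, random_start=3, section_normal=0)
        stack = simulate_sections(uct, plan, deform_amplitude=0.0, seed=1)
        ref = extract_section(uct, plan, stack.section_indices[0], order=1)
        np.testing.assert_allclose(stack.sections[0], ref)

    def test_known_translation_stored_exactly(self, uct):
        tf = SectionTransform(np.eye(2), np.array([10.0 / 7.0, 0.0]), None)
        pts = np.array([[5.0, 5.0], [20.0, 31.0]])
        np.testing.assert_allclose(tf.map_points(pts) - pts,
                                   [[10.0 / 7.0, 0.0]] * 2)

    def test_landmark_displacement_bounded_by_amplitude(self, uct):
        amplitude = 30.0  # µm
        plan = SectionPlan(60, 2.0, 3, 20, random_start=5, section_normal=0)
        stack = simulate_sections(uct, plan, deform_amplitude=amplitude, seed=8)
        rng = np.random.default_rng(0)
        px = float(np.mean(stack.pixel_spacing))
        for tf, sec in zip(stack.true_transforms, stack.sections):
            landmarks = rng.uniform(0, np.array(sec.shape) - 1, size=(100, 2))
            disp = tf.map_points(landmarks) - landmarks
            assert np.hypot(disp[:, 0], disp[:, 1]).max() * px <= amplitude + 1e-6

    def test_warp_identity_transform(self, uct):
        img = uct.data[10]
        out = apply_section_transform(img, SectionTransform(np.eye(2), np.zeros(2), None))
        np.testing.assert_allclose(out, img)


def test_expected_skeleton_branches_formula(default_tree):
    tree, _ = default_tree
    # 1 trunk with 2 daughters -> 3 pieces; each daughter has 2 of its own
    assert expected_skeleton_branches(tree) == 3 + 2 * 3 + 4 * 1
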