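"""Test systems, counting and the stereological estimators."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genstereo.core import LUMEN, WALL
from genstereo.stereology import (CountRecord, SectionField, TestSystem,
                                  build_test_system, count_field, crop_field,
                                  cycloid_arc, estimate_reference_volume,
                                  estimate_total_volumes, estimate_volume_fraction,
                                  estimate_wall_metrics, ingest_counts,
                                  results_table, sample_field_origins, write_counts)


class TestTestSystem:
    def test_default_two_level_grid_factor(self):
        ts = build_test_system()
        assert ts.factor == 8
        assert ts.n_fine == 16 and ts.n_coarse == 2

    def test_default_l_point(self):
        ts = build_test_system()
        # 36 arcs of length 4r with 2 end points each: L_point = 2r = 52 µm
        assert ts.l_point == pytest.approx(52.0, abs=0.01)
        assert len(ts.arcs) == 36
        assert len(ts.arc_endpoints) == 72

    def test_arc_length_closed_form(self):
        arc = cycloid_arc(26.0, n_samples=256)
        length = np.linalg.norm(np.diff(arc, axis=0), axis=1).sum()
        assert length == pytest.approx(4 * 26.0, rel=1e-4)

    def test_cycloid_minor_axis_vertical(self):
        arc = cycloid_arc(26.0)
        v_span = arc[:, 0].max() - arc[:, 0].min()
        u_span = arc[:, 1].max() - arc[:, 1].min()
        assert v_span == pytest.approx(2 * 26.0, rel=1e-6)      # minor, vertical
        assert u_span == pytest.approx(math.pi * 26.0, rel=1e-6)  # major

    def test_cycloid_orientation_density_sine_weighted(self):
        """Tangent length density must be ∝ sin(angle to vertical)."""
        arc = cycloid_arc(1.0, n_samples=20000)
        seg = np.diff(arc, axis=0)
        lengths = np.hypot(seg[:, 0], seg[:, 1])
        ang = np.arccos(np.abs(seg[:, 0]) / lengths)  # angle to vertical (v) axis
        # length-weighted histogram of angle should follow sin
        hist, edges = np.histogram(ang, bins=12, range=(0, math.pi / 2),
                                   weights=lengths)
        centers = (edges[:-1] + edges[1:]) / 2
        expected = np.sin(centers)
        expected *= hist.sum() / expected.sum()
        assert np.allclose(hist, expected, rtol=0.12)

    def test_probes_inside_field(self):
        ts = build_test_system(seed=17)
        for pts in (ts.fine_points, ts.coarse_points):
            assert (pts >= 0).all()
            assert (pts[:, 0] <= ts.field_size[0]).all()
            assert (pts[:, 1] <= ts.field_size[1]).all()

    def test_field_too_small_for_arcs_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            build_test_system(field_size=(100.0, 100.0))


def brute_force_count(field: SectionField, ts: TestSystem, g: int) -> CountRecord:
    """Independent pixel/arc-sampling counter (plain Python loops)."""
    nr, nc = field.generation.shape
    sv, su = field.pixel_spacing

    def nearest(p):
        i, j = int(round(p[0] / sv)), int(round(p[1] / su))
        return (i, j) if 0 <= i < nr and 0 <= j < nc else None

    p_ref = sum(1 for p in ts.coarse_points
                if (ij := nearest(p)) and field.reference[ij])
    p_fine = sum(1 for p in ts.fine_points
                 if (ij := nearest(p)) and field.generation[ij] == g)
    p_wall = p_lumen = 0
    for p in ts.arc_endpoints:
        ij = nearest(p)
        if ij and field.generation[ij] == g:
            if field.compartment[ij] == WALL:
                p_wall += 1
            elif field.compartment[ij] == LUMEN:
                p_lumen += 1

    indicator = ((field.generation == g) & (field.compartment == LUMEN)).astype(float)

    def bilinear(p):
        v, u = p[0] / sv, p[1] / su
        i0, j0 = int(math.floor(v)), int(math.floor(u))
        fv, fu = v - i0, u - j0
        total = 0.0
        for di, wi in ((0, 1 - fv), (1, fv)):
            for dj, wj in ((0, 1 - fu), (1, fu)):
                i, j = i0 + di, j0 + dj
                val = indicator[i, j] if 0 <= i < nr and 0 <= j < nc else 0.0
                total += wi * wj * val
        return total

    inter = 0
    step = min(sv, su)
    for arc in ts.arcs:
        seg = np.linalg.norm(np.diff(arc, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        n = max(int(math.ceil(s[-1] / step)), 1)
        si = np.linspace(0.0, s[-1], n + 1)
        pts = np.stack([np.interp(si, s, arc[:, 0]), np.interp(si, s, arc[:, 1])], axis=1)
        member = [bilinear(p) > 0.5 for p in pts]
        valid = [0.0 <= p[0] / sv <= nr - 1 and 0.0 <= p[1] / su <= nc - 1
                 for p in pts]
        inter += sum(1 for k in range(len(pts) - 1)
                     if valid[k] and valid[k + 1] and member[k] != member[k + 1])
    return CountRecord(field.field_id, g, p_ref, p_fine, p_wall + p_lumen,
                       p_wall, p_lumen, inter)


class TestCountField:
    def test_field_entirely_lumen(self):
        shape = (80, 120)
        field = SectionField(np.ones(shape, np.int32),
                             np.full(shape, LUMEN, np.int32),
                             np.ones(shape, bool), (7.0, 7.0))
        ts = build_test_system(field_size=(560.0, 840.0), offset=(0.0, 0.0))
        rec = count_field(field, ts, generations=[1])[0]
        assert rec.p_lumen == len(ts.arc_endpoints)
        assert rec.p_wall == 0
        assert rec.i == 0
        assert rec.p_artery_fine == ts.n_fine

    def test_empty_reference_field(self):
        shape = (80, 120)
        field = SectionField(np.zeros(shape, np.int32), np.zeros(shape, np.int32),
                             np.ones(shape, bool), (7.0, 7.0))
        ts = build_test_system(field_size=(560.0, 840.0), seed=0)
        rec = count_field(field, ts, generations=[1])[0]
        assert rec.p_artery_fine == rec.p_artery_ends == rec.i == 0
        assert rec.p_ref == ts.n_coarse

    def test_oversized_test_system_rejected(self):
        field = SectionField(np.zeros((10, 10), np.int32), np.zeros((10, 10), np.int32),
                             np.ones((10, 10), bool), (7.0, 7.0))
        ts = build_test_system(field_size=(560.0, 840.0), seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            count_field(field, ts)

    def test_matches_brute_force_oracle(self, default_phantom):
        """Automatic counting equals the independent loop counter exactly."""
        comp = default_phantom.compartments.data
        gen = default_phantom.generation_map.data
        rng = np.random.default_rng(123)
        fs = (480.0, 720.0)
        checked = 0
        for trial in range(20):
            z = int(rng.integers(5, comp.shape[0] - 5))
            gen_img = np.where(comp[z] > 0, gen[z], 0)
            ref = np.ones_like(gen_img, bool)
            ext = (gen_img.shape[0] * 7.0, gen_img.shape[1] * 7.0)
            origin = (rng.uniform(-100, ext[0] - fs[0] + 100),
                      rng.uniform(-100, ext[1] - fs[1] + 100))
            field = crop_field(gen_img, comp[z], ref, (7.0, 7.0), origin, fs,
                               field_id=f"t{trial}")
            ts = build_test_system(field_size=fs, seed=int(rng.integers(2 ** 31)))
            for g in (1, 2, 3):
                fast = count_field(field, ts, generations=[g])[0]
                slow = brute_force_count(field, ts, g)
                assert fast == slow
                checked += 1
        assert checked == 60


class TestEstimators:
    def test_worked_example_volume_fraction(self):
        # one fine-grid hit out of 16, both coarse points on reference
        rec = CountRecord("f", 2, p_ref=2, p_artery_fine=1)
        assert estimate_volume_fraction([rec], factor=8)[2] == pytest.approx(0.0625)

    def test_worked_example_wall_metrics(self):
        recs = [CountRecord("f", 2, 2, 1, 7, 1, 6, 4),
                CountRecord("f", 1, 2, 0, 13, 4, 9, 2)]
        wm = estimate_wall_metrics(recs, l_point_um=52.0)
        assert wm[2].lumen_to_wall == pytest.approx(6.0)
        assert wm[2].t_wall_um == pytest.approx(6.5)
        assert wm[1].lumen_to_wall == pytest.approx(2.25)
        assert wm[1].t_wall_um == pytest.approx(52.0)

    def test_zero_artery_counts_give_zero_fraction(self):
        recs = [CountRecord("a", 1, 2), CountRecord("b", 1, 2)]
        assert estimate_volume_fraction(recs)[1] == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            estimate_volume_fraction([CountRecord("a", 1, 0)])

    def test_undefined_metrics_flagged_not_zero(self):
        rec = CountRecord("f", 1, 2, 0, 5, 0, 5, 0)  # no wall hits, no intersections
        wm = estimate_wall_metrics([rec])
        assert wm[1].lumen_to_wall is None
        assert wm[1].t_wall_um is None
        assert wm[1].vv_wall == 0.0 and wm[1].vv_lumen == 1.0

    @given(st.lists(
        st.tuples(st.integers(0, 20), st.integers(0, 20), st.integers(0, 30),
                  st.integers(0, 10), st.integers(1, 5)),
        min_size=1, max_size=20))
    @settings(max_examples=80, deadline=None)
    def test_wall_plus_lumen_fraction_identity(self, raw):
        """V_V(wall) + V_V(lumen) = 1 exactly whenever defined."""
        recs = [CountRecord(f"f{i}", g, 2, 0, w + l, w, l, i2)
                for i, (w, l, i2, _, g) in enumerate(raw)]
        wm = estimate_wall_metrics(recs)
        for g, m in wm.items():
            if m.vv_wall is not None:
                assert m.vv_wall + m.vv_lumen == pytest.approx(1.0, abs=1e-12)

    def test_ratio_of_sums_invariant_to_field_order_and_batching(self):
        rng = np.random.default_rng(5)
        recs = [CountRecord(f"f{i}", 1, int(rng.integers(1, 3)),
                            int(rng.integers(0, 5)), 0, 0, 0, 0)
                for i in range(30)]
        v1 = estimate_volume_fraction(recs)[1]
        rng.shuffle(recs)
        v2 = estimate_volume_fraction(recs)[1]
        assert v1 == v2
        # batch pooling: concatenating per-batch records changes nothing
        batches = [recs[:10], recs[10:25], recs[25:]]
        v3 = estimate_volume_fraction([r for b in batches for r in b])[1]
        assert v3 == v1

    def test_total_volume_product(self):
        totals = estimate_total_volumes({1: 0.01, 2: 0.002}, 3.5)
        assert totals[1] == pytest.approx(0.035)
        assert totals[2] == pytest.approx(0.007)

    def test_reference_volume_from_point_counts(self):
        from genstereo.sectioning import SectionPlan
        plan = SectionPlan(140, 2.0, 20, 50, random_start=1)
        v = estimate_reference_volume(plan, [10] * 20, area_per_point_um2=1e4)
        # 20 sections x 10 points x 1e4 µm² x 2 µm x (70/20) weight
        assert v == pytest.approx(20 * 10 * 1e4 * 2.0 * 3.5 / 1e9)

    def test_results_table_shape_and_units(self):
        recs = [CountRecord("f", 1, 2, 1, 13, 4, 9, 2)]
        vv = estimate_volume_fraction(recs)
        wall = estimate_wall_metrics(recs)
        table = results_table(vv, estimate_total_volumes(vv, 2.0), wall)
        assert "Generation 1" in table.columns
        assert "V_V (artery/lung) [%]" in table.index
        assert "T (wall) [um]" in table.index


class TestSphereSurfaceDensity:
    def test_cycloid_intersections_recover_sphere_surface(self):
        """S_V = 2ΣI/ΣL within 5% for an isotropic (spherical) surface."""
        R, px, n = 300.0, 7.0, 100
        ax = (np.arange(n) + 0.5) * px - n * px / 2
        zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
        sphere = (zz ** 2 + yy ** 2 + xx ** 2) <= R ** 2
        rng = np.random.default_rng(3)
        I_tot, L_tot = 0, 0.0
        for rep in range(3):
            for z in range(0, n, 2):
                ts = build_test_system(field_size=(n * px, n * px), n_arcs=36,
                                       seed=int(rng.integers(2 ** 31)))
                field = SectionField(sphere[z].astype(np.int32),
                                     np.where(sphere[z], LUMEN, 0),
                                     np.ones((n, n), bool), (px, px))
                rec = count_field(field, ts, generations=[1], probes=("cycloids",))[0]
                I_tot += rec.i
                L_tot += ts.total_arc_length()
        # sampling every second section thins I and L equally: the ratio is
        # unbiased for S_V regardless of the section sampling fraction
        s_v = 2 * I_tot / L_tot
        s_v_true = 4 * math.pi * R ** 2 / (n * px) ** 3
        assert s_v == pytest.approx(s_v_true, rel=0.05)


class TestCountSheets:
    def test_round_trip(self, tmp_path):
        recs = [CountRecord("f1", 1, 2, 1, 13, 4, 9, 2),
                CountRecord("f1", 2, 2, 0, 7, 1, 6, 4)]
        path = tmp_path / "counts.csv"
        write_counts(recs, path)
        assert ingest_counts(path) == recs

    def test_two_row_sheet(self):
        text = ("field_id,generation,p_ref,p_artery_fine,p_artery_ends,p_wall,p_lumen,i\n"
                "a,1,2,1,5,2,3,4\nb,2,2,0,0,0,0,0\n")
        recs = ingest_counts(io.StringIO(text))
        assert len(recs) == 2

    def test_inconsistent_row_names_line(self):
        text = ("field_id,generation,p_ref,p_artery_fine,p_artery_ends,p_wall,p_lumen,i\n"
                "a,1,2,1,5,2,3,4\nb,1,2,1,5,2,4,4\n")
        with pytest.raises(ValueError, match="line 3"):
            ingest_counts(io.StringIO(text))

    def test_negative_count_rejected(self):
        text = ("field_id,generation,p_ref,p_artery_fine,p_artery_ends,p_wall,p_lumen,i\n"
                "a,1,-1,1,5,2,3,4\n")
        with pytest.raises(ValueError, match="line 2"):
            ingest_counts(io.StringIO(text))

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            ingest_counts(io.StringIO("field_id,generation\na,1\n"))


def test_field_origins_cover_borders():
    origins = sample_field_origins((200, 300), (7.0, 7.0), (480.0, 720.0), seed=1)
    assert origins, "tiling must produce at least one field"
    vs = [o[0] for o in origins]
    assert min(vs) < 0 or min(vs) < 480.0  # border-straddling fields retained
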