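"""Design-based stereology: test systems, counting and estimators.

This module implements the counting workflow for generation-labelled
vessel profiles on vertical sections:

* a two-level point grid (fine grid for the structure of interest, coarse
  grid for the reference space, one coarse point standing for
  ``factor`` fine points),
* a cycloid test-line system for surfaces on vertical sections.  Cycloid
  arcs have their minor axis parallel to the vertical axis, which makes
  their length distribution sine-weighted with respect to the vertical
  direction — the condition for unbiased surface estimation on vertical
  sections.  Arc end points double as a point grid for wall/lumen hits.

Estimators (ratios of summed counts, pooled over fields before dividing):

* volume fraction          ``V_V(g) = ΣP_fine(g) / (ΣP_ref · factor)``
* total volume             ``V(g) = V_V(g) · V(reference)``
* wall / lumen fractions   ``V_V(wall/artery) = ΣP_wall / ΣP_ends`` etc.
* lumen-to-wall ratio      ``ΣP_lumen / ΣP_wall``
* arithmetic mean wall thickness
                           ``T_wall = (ΣP_wall · L_point) / (2 · ΣI)``

where ``I`` counts intersections of the cycloids with the luminal surface
and ``L_point`` is the test-line length per end point (``2r`` for
half-cycloid arcs of generating-circle radius ``r``: each arc has length
``4r`` and two end points).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import LUMEN, WALL

# ---------------------------------------------------------------------------
# Test system
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TestSystem:
    """Geometry of the probes for one field of view.

    Coordinates are physical (µm) in the field frame, ordered
    ``(v, u)`` = (vertical/row, horizontal/column).  ``fine_points`` and
    ``coarse_points`` are ``(n, 2)`` arrays; ``arcs`` is a list of
    ``(m, 2)`` polylines; ``arc_endpoints`` is ``(2·n_arcs, 2)``.
    """

    field_size: tuple[float, float]
    fine_points: np.ndarray
    coarse_points: np.ndarray
    arcs: list[np.ndarray]
    l_point: float
    factor: int
    cycloid_radius: float
    offset: tuple[float, float]

    @property
    def n_fine(self) -> int:
        return len(self.fine_points)

    @property
    def n_coarse(self) -> int:
        return len(self.coarse_points)

    @property
    def arc_endpoints(self) -> np.ndarray:
        return np.array([p for arc in self.arcs for p in (arc[0], arc[-1])])

    def total_arc_length(self) -> float:
        return float(sum(np.linalg.norm(np.diff(arc, axis=0), axis=1).sum()
                         for arc in self.arcs))


def cycloid_arc(radius: float, n_samples: int = 512, flip_u: bool = False,
                flip_v: bool = False) -> np.ndarray:
    """Polyline of one half-cycloid arc, minor axis along v (vertical).

    Parameterisation ``u = r(θ − sin θ)``, ``v = r(1 − cos θ)`` for
    ``θ ∈ [0, π]``: the arc spans ``π r`` horizontally and ``2 r``
    vertically (the minor axis), has length ``4 r`` and two end points.
    Its tangent-direction density is proportional to the sine of the angle
    to the vertical axis.  ``flip_u``/``flip_v`` mirror the arc so grids
    can alternate orientation.
    """
    theta = np.linspace(0.0, math.pi, n_samples + 1)
    u = radius * (theta - np.sin(theta))
    v = radius * (1.0 - np.cos(theta))
    if flip_u:
        u = radius * math.pi - u
    if flip_v:
        v = 2.0 * radius - v
    return np.stack([v, u], axis=1)


def build_test_system(field_size: tuple[float, float] = (480.0, 720.0),
                      n_fine: int = 16, n_coarse: int = 2, n_arcs: int = 36,
                      cycloid_radius: float = 26.0, seed: int | None = 0,
                      offset: tuple[float, float] | None = None,
                      arc_samples: int = 512) -> TestSystem:
    """Build the default two-level point grid plus cycloid system.

    Defaults: 16 fine points (4×4 lattice), 2 coarse points (a subset of
    the fine lattice, factor 16/2 = 8), 36 half-cycloid arcs of
    generating-circle radius 26 µm laid out on a 6×6 lattice with
    alternating mirroring, giving ``L_point = 2·26 = 52`` µm.  A uniform
    random offset (one lattice period) positions all probes; pass
    ``offset`` explicitly for reproducible placements.
    """
    fv, fu = (float(field_size[0]), float(field_size[1]))
    if fv <= 0 or fu <= 0 or cycloid_radius <= 0:
        raise ValueError("field size and cycloid radius must be positive")
    if n_fine % n_coarse != 0:
        raise ValueError("n_fine must be an integer multiple of n_coarse")
    factor = n_fine // n_coarse

    n_rows = int(round(math.sqrt(n_fine)))
    if n_rows * n_rows != n_fine:
        raise ValueError("n_fine must be a perfect square (lattice layout)")
    pitch = (fv / n_rows, fu / n_rows)

    a_rows = int(round(math.sqrt(n_arcs)))
    if a_rows * a_rows != n_arcs:
        raise ValueError("n_arcs must be a perfect square (lattice layout)")
    arc_cell = (fv / a_rows, fu / a_rows)
    if arc_cell[0] < 2 * cycloid_radius or arc_cell[1] < math.pi * cycloid_radius:
        raise ValueError(
            f"field {field_size} too small for {n_arcs} arcs of radius {cycloid_radius}")

    if offset is None:
        rng = np.random.default_rng(seed)
        offset = (float(rng.uniform(0, pitch[0])), float(rng.uniform(0, pitch[1])))

    # fine lattice with the random offset, wrapped into the field
    vv = (offset[0] + pitch[0] * (np.arange(n_rows) + 0.5)) % fv
    uu = (offset[1] + pitch[1] * (np.arange(n_rows) + 0.5)) % fu
    fine = np.array([(v, u) for v in np.sort(vv) for u in np.sort(uu)])

    # coarse points: an evenly spread subset of the fine lattice
    stride = n_fine // n_coarse
    coarse_idx = (np.arange(n_coarse) * stride + stride // 2) % n_fine
    coarse = fine[coarse_idx]

    arcs: list[np.ndarray] = []
    span_v, span_u = 2 * cycloid_radius, math.pi * cycloid_radius
    for i in range(a_rows):
        for j in range(a_rows):
            cell_v = (offset[0] + i * arc_cell[0]) % fv
            cell_u = (offset[1] + j * arc_cell[1]) % fu
            arc = cycloid_arc(cycloid_radius, arc_samples,
                              flip_u=(j % 2 == 1), flip_v=(i % 2 == 1))
            pos = arc + np.array([cell_v + (arc_cell[0] - span_v) / 2,
                                  cell_u + (arc_cell[1] - span_u) / 2])
            arcs.append(pos)

    total_len = sum(np.linalg.norm(np.diff(a, axis=0), axis=1).sum() for a in arcs)
    l_point = float(total_len / (2 * len(arcs)))
    return TestSystem((fv, fu), fine, coarse, arcs, l_point, factor,
                      cycloid_radius, tuple(offset))


# ---------------------------------------------------------------------------
# Fields and counting
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SectionField:
    """One field of view on a generation-labelled section.

    ``generation`` holds the arterial generation per pixel (0 = not
    artery); ``compartment`` distinguishes lumen and wall pixels of those
    profiles; ``reference`` marks the reference space (the organ).  Pixel
    centres sit at ``index · pixel_spacing`` in field coordinates, with
    rows along the vertical axis.
    """

    generation: np.ndarray
    compartment: np.ndarray
    reference: np.ndarray
    pixel_spacing: tuple[float, float]
    field_id: str = "field"

    def __post_init__(self) -> None:
        self.generation = np.asarray(self.generation)
        self.compartment = np.asarray(self.compartment)
        self.reference = np.asarray(self.reference).astype(bool)
        if not (self.generation.shape == self.compartment.shape == self.reference.shape):
            raise ValueError("generation, compartment and reference must share one shape")
        if np.isscalar(self.pixel_spacing):
            self.pixel_spacing = (float(self.pixel_spacing),) * 2
        else:
            self.pixel_spacing = tuple(float(s) for s in self.pixel_spacing)

    @property
    def extent_um(self) -> tuple[float, float]:
        return (self.generation.shape[0] * self.pixel_spacing[0],
                self.generation.shape[1] * self.pixel_spacing[1])


@dataclasses.dataclass
class CountRecord:
    """Counting events of one field for one arterial generation.

    ``p_ref`` is the per-field coarse-grid reference count (identical on
    every generation row of the same field; estimator pooling counts it
    once per field).  ``p_artery_fine`` are fine-grid hits on the artery
    profile (wall + lumen); ``p_wall``/``p_lumen`` are cycloid end-point
    hits (their sum ``p_artery_ends`` is the line-end tally, distinct from
    the fine-grid tally); ``i`` counts cycloid–luminal-surface
    intersections.
    """

    field_id: str
    generation: int
    p_ref: int
    p_artery_fine: int = 0
    p_artery_ends: int = 0
    p_wall: int = 0
    p_lumen: int = 0
    i: int = 0

    def validate(self) -> None:
        counts = [self.p_ref, self.p_artery_fine, self.p_artery_ends,
                  self.p_wall, self.p_lumen, self.i]
        if any(c < 0 or int(c) != c for c in counts):
            raise ValueError(f"counts must be non-negative integers: {self}")
        if self.p_wall + self.p_lumen != self.p_artery_ends:
            raise ValueError(
                f"p_wall + p_lumen must equal p_artery_ends "
                f"({self.p_wall} + {self.p_lumen} != {self.p_artery_ends}) in {self}")


def _nearest_pixel(points: np.ndarray, spacing: tuple[float, float],
                   shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Map physical points to nearest pixel indices; returns (indices, valid)."""
    idx = np.round(points / np.asarray(spacing)).astype(int)
    valid = ((idx[:, 0] >= 0) & (idx[:, 0] < shape[0]) &
             (idx[:, 1] >= 0) & (idx[:, 1] < shape[1]))
    return idx, valid


def _sample_arc(arc: np.ndarray, step_um: float) -> np.ndarray:
    """Resample an arc polyline at approximately uniform arc-length steps."""
    seg = np.linalg.norm(np.diff(arc, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(math.ceil(total / step_um)), 1)
    si = np.linspace(0.0, total, n + 1)
    v = np.interp(si, s, arc[:, 0])
    u = np.interp(si, s, arc[:, 1])
    return np.stack([v, u], axis=1)


def count_field(field: SectionField, ts: TestSystem,
                generations: Sequence[int] | None = None,
                probes: Sequence[str] = ("points", "cycloids")) -> list[CountRecord]:
    """Count all stereological events of one field, per generation.

    Point hits resolve by nearest pixel centre (the raster is the ground
    truth; no sub-pixel adjudication).  Intersections are sign-changes of
    the bilinearly interpolated lumen-class indicator (threshold 0.5)
    along each cycloid, sampled at one-pixel arc-length steps: a
    tangential graze that does not cross the boundary contributes
    nothing.  Interpolation and the one-pixel step act as boundary
    anti-aliasing — nearest-pixel membership at sub-pixel steps would
    measure the staircase perimeter of the digitised boundary, which
    exceeds the underlying smooth surface by up to 4/π.

    ``probes`` restricts the work to the point grids and/or the cycloid
    system (volume fractions need only the grids).
    """
    shape = field.generation.shape
    if ts.field_size[0] > field.extent_um[0] + field.pixel_spacing[0] or \
       ts.field_size[1] > field.extent_um[1] + field.pixel_spacing[1]:
        raise ValueError(f"test-system field {ts.field_size} exceeds the image "
                         f"extent {field.extent_um}")
    if generations is None:
        present = np.unique(field.generation)
        generations = [int(g) for g in present if g > 0] or [1]

    do_points = "points" in probes
    do_cycloids = "cycloids" in probes

    p_ref = 0
    if do_points:
        fine_idx, fine_ok = _nearest_pixel(ts.fine_points, field.pixel_spacing, shape)
        coarse_idx, coarse_ok = _nearest_pixel(ts.coarse_points, field.pixel_spacing, shape)
        p_ref = int(sum(field.reference[tuple(ix)] for ix, ok in zip(coarse_idx, coarse_ok) if ok))

    if do_cycloids:
        ends_idx, ends_ok = _nearest_pixel(ts.arc_endpoints, field.pixel_spacing, shape)
        step = min(field.pixel_spacing)
        arc_samples = [_sample_arc(arc, step) for arc in ts.arcs]
        arc_coords = [(s_arc / np.asarray(field.pixel_spacing)).T for s_arc in arc_samples]

    records = []
    for g in generations:
        p_fine = 0
        if do_points:
            for ix, ok in zip(fine_idx, fine_ok):
                if ok and field.generation[tuple(ix)] == g:
                    p_fine += 1
        p_wall = p_lumen = inter = 0
        if do_cycloids:
            for ix, ok in zip(ends_idx, ends_ok):
                if ok and field.generation[tuple(ix)] == g:
                    comp = field.compartment[tuple(ix)]
                    if comp == WALL:
                        p_wall += 1
                    elif comp == LUMEN:
                        p_lumen += 1
            indicator = ((field.generation == g) &
                         (field.compartment == LUMEN)).astype(np.float32)
            for coords in arc_coords:
                vals = ndimage.map_coordinates(indicator, coords, order=1,
                                               mode="constant", cval=0.0)
                member = vals > 0.5
                # transitions count only between consecutive in-image samples;
                # an arc leaving the field is censored, not a surface crossing
                valid = ((coords[0] >= 0) & (coords[0] <= shape[0] - 1) &
                         (coords[1] >= 0) & (coords[1] <= shape[1] - 1))
                both = valid[1:] & valid[:-1]
                inter += int(np.count_nonzero(both & (member[1:] != member[:-1])))
        rec = CountRecord(field.field_id, g, p_ref, p_fine,
                          p_wall + p_lumen, p_wall, p_lumen, inter)
        rec.validate()
        records.append(rec)
    return records


def sample_field_origins(section_shape: tuple[int, int], pixel_spacing: tuple[float, float],
                         field_size: tuple[float, float], seed: int = 0,
                         spacing_factor: float = 1.0) -> list[tuple[float, float]]:
    """Systematically place field origins over a section with a random start.

    Fields tile the section at ``field_size × spacing_factor`` pitch with
    one uniform random offset — systematic uniform random sampling of test
    fields within the section.
    """
    rng = np.random.default_rng(seed)
    ext = (section_shape[0] * pixel_spacing[0], section_shape[1] * pixel_spacing[1])
    pitch = (field_size[0] * spacing_factor, field_size[1] * spacing_factor)
    off = (rng.uniform(0, pitch[0]), rng.uniform(0, pitch[1]))
    # fields straddling the section boundary are kept (probes falling outside
    # simply count nothing); dropping them would over-sample the centre
    origins = []
    v = off[0] - pitch[0]
    while v < ext[0]:
        if v + field_size[0] > 0:
            u = off[1] - pitch[1]
            while u < ext[1]:
                if u + field_size[1] > 0:
                    origins.append((v, u))
                u += pitch[1]
        v += pitch[0]
    return origins


def crop_field(generation: np.ndarray, compartment: np.ndarray, reference: np.ndarray,
               pixel_spacing: tuple[float, float], origin_um: tuple[float, float],
               field_size: tuple[float, float], field_id: str = "field") -> SectionField:
    """Cut one field window (physical origin and size in µm) out of a section.

    The window may straddle the section boundary; pixels outside the
    section are background with ``reference = False`` so probes landing
    there count nothing.
    """
    r0 = int(round(origin_um[0] / pixel_spacing[0]))
    c0 = int(round(origin_um[1] / pixel_spacing[1]))
    nr = int(round(field_size[0] / pixel_spacing[0]))
    nc = int(round(field_size[1] / pixel_spacing[1]))
    gen = np.zeros((nr, nc), dtype=generation.dtype)
    comp = np.zeros((nr, nc), dtype=compartment.dtype)
    ref = np.zeros((nr, nc), dtype=bool)
    ir0, ir1 = max(r0, 0), min(r0 + nr, generation.shape[0])
    ic0, ic1 = max(c0, 0), min(c0 + nc, generation.shape[1])
    if ir0 < ir1 and ic0 < ic1:
        dst = (slice(ir0 - r0, ir1 - r0), slice(ic0 - c0, ic1 - c0))
        src = (slice(ir0, ir1), slice(ic0, ic1))
        gen[dst] = generation[src]
        comp[dst] = compartment[src]
        ref[dst] = reference[src]
    return SectionField(gen, comp, ref, pixel_spacing, field_id=field_id)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def _pool(records: Iterable[CountRecord]) -> tuple[pd.DataFrame, int]:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    if df.empty:
        raise ValueError("no count records supplied")
    # p_ref is a per-field quantity repeated on each generation row
    p_ref_total = int(df.groupby("field_id")["p_ref"].first().sum())
    return df, p_ref_total


def estimate_volume_fraction(records: Iterable[CountRecord],
                             factor: int = 8) -> dict[int, float]:
    """Per-generation volume fraction ``V_V = ΣP_fine / (ΣP_ref · factor)``.

    Counts are pooled over fields before dividing (ratio of sums).
    """
    df, p_ref_total = _pool(records)
    if p_ref_total <= 0:
        raise ValueError("total reference point count is zero; V_V undefined")
    sums = df.groupby("generation")["p_artery_fine"].sum()
    return {int(g): float(s) / (p_ref_total * factor) for g, s in sums.items()}


def estimate_reference_volume(plan, records_or_areas,
                              area_per_point_um2: float | None = None) -> float:
    """Cavalieri estimate of the reference volume (mm³) from SURS sections.

    ``records_or_areas`` is either a sequence of per-section areas (µm²)
    or per-section reference point counts together with
    ``area_per_point_um2`` (the area one grid point stands for).
    """
    from .sectioning import cavalieri_volume

    values = np.asarray(list(records_or_areas), dtype=float)
    if values.size == 0:
        raise ValueError("no sections supplied for the Cavalieri estimate")
    if area_per_point_um2 is not None:
        values = values * area_per_point_um2
    return cavalieri_volume(plan, values)


@dataclasses.dataclass
class WallMetrics:
    """Per-generation wall/lumen composition of the arterial profiles."""

    vv_wall: float | None
    vv_lumen: float | None
    lumen_to_wall: float | None
    t_wall_um: float | None


def estimate_wall_metrics(records: Iterable[CountRecord],
                          l_point_um: float = 52.0) -> dict[int, WallMetrics]:
    """Wall fractions, lumen-to-wall ratio and mean wall thickness.

    All are ratios of summed counts.  ``T_wall = (ΣP_wall · L_point)/(2·ΣI)``
    estimates the arithmetic mean wall thickness (wall volume per unit
    luminal surface).  Undefined quantities (zero denominators) come back
    as ``None`` rather than zero.
    """
    df, _ = _pool(records)
    out: dict[int, WallMetrics] = {}
    for g, sub in df.groupby("generation"):
        pw, pl, ii = int(sub["p_wall"].sum()), int(sub["p_lumen"].sum()), int(sub["i"].sum())
        ends = pw + pl
        vv_wall = pw / ends if ends > 0 else None
        vv_lumen = pl / ends if ends > 0 else None
        ltw = pl / pw if pw > 0 else None
        t_wall = (pw * l_point_um) / (2.0 * ii) if ii > 0 else None
        out[int(g)] = WallMetrics(vv_wall, vv_lumen, ltw, t_wall)
    return out


def estimate_total_volumes(vv: dict[int, float], reference_volume_mm3: float) -> dict[int, float]:
    """Total per-generation volume ``V = V_V · V(reference)`` (mm³)."""
    return {g: f * reference_volume_mm3 for g, f in vv.items()}


def results_table(vv: dict[int, float], totals: dict[int, float],
                  wall: dict[int, WallMetrics]) -> pd.DataFrame:
    """Human-readable per-generation results table (V_V in %, T_wall in µm)."""
    rows = {}
    gens = sorted(set(vv) | set(wall))
    rows["V_V (artery/lung) [%]"] = [round(100 * vv.get(g, float("nan")), 3) for g in gens]
    rows["V (artery, lung) [mm3]"] = [round(totals.get(g, float("nan")), 3) for g in gens]
    rows["lumen-to-wall ratio"] = [
        None if g not in wall or wall[g].lumen_to_wall is None else round(wall[g].lumen_to_wall, 3)
        for g in gens]
    rows["T (wall) [um]"] = [
        None if g not in wall or wall[g].t_wall_um is None else round(wall[g].t_wall_um, 2)
        for g in gens]
    return pd.DataFrame(rows, index=[f"Generation {g}" for g in gens]).T


# ---------------------------------------------------------------------------
# Manual count sheets
# ---------------------------------------------------------------------------

CSV_COLUMNS = ["field_id", "generation", "p_ref", "p_artery_fine",
               "p_artery_ends", "p_wall", "p_lumen", "i"]


def ingest_counts(path_or_buffer) -> list[CountRecord]:
    """Read a manual count sheet (CSV) into validated records.

    Expected header: ``field_id, generation, p_ref, p_artery_fine,
    p_artery_ends, p_wall, p_lumen, i``.  Rows violating the count
    invariants are rejected with their line number.
    """
    df = pd.read_csv(path_or_buffer)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count sheet is missing columns: {missing}")
    records = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        rec = CountRecord(str(row.field_id), int(row.generation), int(row.p_ref),
                          int(row.p_artery_fine), int(row.p_artery_ends),
                          int(row.p_wall), int(row.p_lumen), int(row.i))
        try:
            rec.validate()
        except ValueError as err:
            raise ValueError(f"invalid count sheet row at line {pos}: {err}") from err
        records.append(rec)
    return records


def write_counts(records: Iterable[CountRecord], path) -> None:
    """Write records as a count-sheet CSV (round-trips with ingest_counts)."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])[CSV_COLUMNS]
    df.to_csv(path, index=False)
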