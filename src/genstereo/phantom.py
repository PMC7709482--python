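"""Synthetic monopodial vessel-tree phantoms with analytic ground truth.

The phantom emulates the arterial tree of a small-mammal lung: a single
longitudinal trunk (generation 1) running along the vertical axis of the
organ, with smaller lateral daughters branching off at a fixed angle
(generation 2), which in turn carry their own laterals (generation 3), and
so on.  Each branch is a circular cylinder with a lumen of radius ``r``
and a concentric wall annulus of thickness ``t``, embedded in parenchyma.

Because every branch is an analytic cylinder, per-generation lumen/wall
volumes and luminal surface areas are available in closed form, which is
what makes the phantom usable as ground truth for point counting,
surface-intersection counting and wall-thickness estimation downstream.

The generator is deliberately built so that the monopodial continuation
rule used by the generation analysis (the trunk continuation has the
largest downstream subtree length at every junction) holds by
construction: daughters attach only along a proximal fraction of their
parent (``station_span``) and their subtree length is validated against
the remaining parent length.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import LUMEN, PARENCHYMA, WALL, LabelVolume, VoxelVolume

UM3_PER_MM3 = 1e9
UM2_PER_MM2 = 1e6


# ---------------------------------------------------------------------------
# Tree specification and geometry
# ---------------------------------------------------------------------------

def _per_generation(value, n: int, name: str) -> tuple[float, ...]:
    """Expand a scalar or sequence to one value per generation."""
    if np.isscalar(value):
        return (float(value),) * n
    value = tuple(float(v) for v in value)
    if len(value) < n:
        raise ValueError(f"{name} must provide at least {n} per-generation values, got {len(value)}")
    return value[:n]


@dataclasses.dataclass(frozen=True)
class TreeSpec:
    """Parameters of a monopodial phantom tree.

    Lengths and radii are in µm.  ``length_decay`` gives the daughter/parent
    length ratio per generation step (scalar or one value per step);
    ``lumen_radius`` and ``wall_thickness`` are per generation and lumen
    calibre must be strictly decreasing.  ``station_span`` is the fraction
    of the parent length over which daughter attachment stations are
    spread (daughters sit proximally, as lateral branches do on the
    organ-length trunk).
    """

    n_generations: int = 3
    branches_per_parent: int = 2
    trunk_length: float = 1900.0
    length_decay: float | Sequence[float] = (0.28, 0.33)
    lumen_radius: Sequence[float] = (70.0, 40.0, 28.0)
    wall_thickness: Sequence[float] = (18.0, 12.0, 8.0)
    branch_angle: float = 75.0
    station_span: float = 0.45
    seed: int = 0

    def validate(self) -> None:
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.branches_per_parent < 0:
            raise ValueError("branches_per_parent must be >= 0")
        if self.trunk_length <= 0:
            raise ValueError("trunk_length must be positive")
        radii = _per_generation(self.lumen_radius, self.n_generations, "lumen_radius")
        walls = _per_generation(self.wall_thickness, self.n_generations, "wall_thickness")
        for g, (r, t) in enumerate(zip(radii, walls), start=1):
            if r <= 0 or t <= 0:
                raise ValueError(f"lumen_radius and wall_thickness must be positive (generation {g})")
        for g in range(1, self.n_generations):
            if radii[g] >= radii[g - 1]:
                raise ValueError(
                    f"lumen calibre must strictly decrease: generation {g + 1} radius "
                    f"{radii[g]} >= generation {g} radius {radii[g - 1]}")
        decays = _per_generation(self.length_decay, max(self.n_generations - 1, 1), "length_decay")
        for d in decays:
            if not 0 < d <= 1:
                raise ValueError(f"length_decay values must lie in (0, 1], got {d}")
        if not 0 < self.station_span <= 1:
            raise ValueError("station_span must lie in (0, 1]")
        if not 0 < self.branch_angle < 90:
            raise ValueError("branch_angle must lie strictly between 0 and 90 degrees")

    # convenience accessors -----------------------------------------------
    def radius(self, generation: int) -> float:
        return _per_generation(self.lumen_radius, self.n_generations, "lumen_radius")[generation - 1]

    def wall(self, generation: int) -> float:
        return _per_generation(self.wall_thickness, self.n_generations, "wall_thickness")[generation - 1]

    def length(self, generation: int) -> float:
        L = self.trunk_length
        if generation == 1:
            return L
        decays = _per_generation(self.length_decay, self.n_generations - 1, "length_decay")
        for step in range(generation - 1):
            L *= decays[step]
        return L


@dataclasses.dataclass
class Branch:
    """One cylindrical tree segment in physical (z, y, x) coordinates."""

    branch_id: int
    generation: int
    parent_id: int | None
    start: np.ndarray
    end: np.ndarray
    lumen_radius: float
    wall_thickness: float

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def direction(self) -> np.ndarray:
        return (self.end - self.start) / self.length

    @property
    def outer_radius(self) -> float:
        return self.lumen_radius + self.wall_thickness

    def lumen_volume_um3(self) -> float:
        return math.pi * self.lumen_radius**2 * self.length

    def wall_volume_um3(self) -> float:
        return math.pi * (self.outer_radius**2 - self.lumen_radius**2) * self.length

    def luminal_surface_um2(self) -> float:
        return 2.0 * math.pi * self.lumen_radius * self.length


@dataclasses.dataclass
class CenterlineTree:
    """The phantom's analytic centerline tree."""

    branches: list[Branch]
    spec: TreeSpec
    vertical_axis: int = 1

    def branch(self, branch_id: int) -> Branch:
        return next(b for b in self.branches if b.branch_id == branch_id)

    def children(self, branch_id: int) -> list[Branch]:
        return [b for b in self.branches if b.parent_id == branch_id]

    @property
    def root(self) -> Branch:
        return next(b for b in self.branches if b.parent_id is None)

    def subtree_length(self, branch_id: int) -> float:
        b = self.branch(branch_id)
        return b.length + sum(self.subtree_length(c.branch_id) for c in self.children(branch_id))


@dataclasses.dataclass
class GroundTruth:
    """Closed-form per-generation quantities of a phantom tree.

    Volumes are plain sums of branch cylinders; overlap at junctions is
    not subtracted (the attachment geometry keeps it far below the
    rasterisation tolerance).  Volumes in mm³, surfaces in mm².
    """

    lumen_volume_mm3: dict[int, float]
    wall_volume_mm3: dict[int, float]
    luminal_surface_mm2: dict[int, float]
    branch_generation: dict[int, int]
    n_branches: dict[int, int]
    total_domain_mm3: float | None = None

    @property
    def generations(self) -> list[int]:
        return sorted(self.lumen_volume_mm3)

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        return json.dumps(payload, indent=2, sort_keys=True)


def _orthonormal_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to ``direction`` and to each other."""
    d = direction / np.linalg.norm(direction)
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 0.0, 1.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def build_tree(spec: TreeSpec) -> tuple[CenterlineTree, GroundTruth]:
    """Construct the analytic centerline tree and its ground truth.

    The trunk (generation 1) runs along the vertical (y) axis from the
    origin.  Daughters of every branch attach at equispaced stations over
    the proximal ``station_span`` fraction of the parent, leave the parent
    at ``branch_angle`` from its axis, and alternate azimuth from side to
    side with a slow progressive twist so successive daughter pairs do not
    share one plane.  A daughter's own cylinder starts at the parent's
    luminal surface, so the analytic cylinder sums count junction space
    essentially once.
    """
    spec.validate()
    branches: list[Branch] = []
    next_id = [1]
    angle = math.radians(spec.branch_angle)

    def grow(start: np.ndarray, direction: np.ndarray, generation: int,
             parent_id: int | None) -> None:
        length = spec.length(generation)
        end = start + direction * length
        branch = Branch(next_id[0], generation, parent_id, start.copy(), end,
                        spec.radius(generation), spec.wall(generation))
        next_id[0] += 1
        branches.append(branch)
        if generation >= spec.n_generations or spec.branches_per_parent == 0:
            return
        u, v = _orthonormal_frame(direction)
        n = spec.branches_per_parent
        # deterministic azimuth pattern: strict side alternation plus a slow
        # twist per pair, offset per branch so sibling families interleave
        base_twist = 0.7548776662 * branch.branch_id  # irrational turns, decorrelates families
        r_parent = branch.lumen_radius
        for k in range(n):
            frac = spec.station_span * (k + 1) / (n + 1)
            station = start + direction * (length * frac)
            azimuth = base_twist + (k % 2) * math.pi + (k // 2) * (math.pi / 3.0)
            radial = math.cos(azimuth) * u + math.sin(azimuth) * v
            d_child = math.cos(angle) * direction + math.sin(angle) * radial
            d_child /= np.linalg.norm(d_child)
            # child axis starts where it pierces the parent luminal surface
            child_start = station + d_child * (r_parent / math.sin(angle))
            grow(child_start, d_child, generation + 1, branch.branch_id)

    trunk_dir = np.zeros(3)
    trunk_dir[1] = 1.0  # vertical axis y
    grow(np.zeros(3), trunk_dir, 1, None)

    tree = CenterlineTree(branches, spec)
    _check_monopodial_dominance(tree)

    lumen: dict[int, float] = {}
    wall: dict[int, float] = {}
    surface: dict[int, float] = {}
    nb: dict[int, int] = {}
    gen_of: dict[int, int] = {}
    for b in branches:
        g = b.generation
        lumen[g] = lumen.get(g, 0.0) + b.lumen_volume_um3() / UM3_PER_MM3
        wall[g] = wall.get(g, 0.0) + b.wall_volume_um3() / UM3_PER_MM3
        surface[g] = surface.get(g, 0.0) + b.luminal_surface_um2() / UM2_PER_MM2
        nb[g] = nb.get(g, 0) + 1
        gen_of[b.branch_id] = g
    truth = GroundTruth(lumen, wall, surface, gen_of, nb)
    return tree, truth


def _check_monopodial_dominance(tree: CenterlineTree, margin: float = 1.1,
                                radius_slack: float = 4.0) -> None:
    """Verify the trunk-continuation rule is recoverable from lengths alone.

    At every attachment station, the remaining parent length downstream of
    the station (plus any later subtrees) must exceed the daughter's whole
    subtree length with margin, otherwise a length-based generation
    analysis could not reproduce the generator's labels.  The absolute
    slack of ``radius_slack`` parent radii absorbs the systematic length
    distortions of a voxel skeleton: the junction node is displaced into
    the parent, the daughter centerline gains an in-parent connector of
    about one parent radius, and terminal centerlines retract from tube
    ends by about one tube radius.
    """
    for parent in tree.branches:
        children = tree.children(parent.branch_id)
        if not children:
            continue
        p_start, p_len = parent.start, parent.length
        d = parent.direction

        def station_of(c: Branch) -> float:
            return float(np.dot(c.start - p_start, d))

        children = sorted(children, key=station_of)
        for i, c in enumerate(children):
            remaining_parent = p_len - station_of(c)
            later = sum(tree.subtree_length(c2.branch_id) for c2 in children[i + 1:])
            continuation = remaining_parent + later
            lateral = tree.subtree_length(c.branch_id)
            need = margin * lateral + radius_slack * parent.lumen_radius
            if continuation < need:
                raise ValueError(
                    f"monopodial dominance violated at branch {parent.branch_id}: "
                    f"continuation length {continuation:.0f} µm vs lateral subtree "
                    f"{lateral:.0f} µm (need >= {need:.0f} µm)")


def random_tree_spec(seed: int, max_draws: int = 200) -> TreeSpec:
    """Draw a random monopodial tree specification.

    Samples realistic small-animal arterial geometry (organ-length trunk,
    short proximal laterals, strictly decreasing calibre) and keeps the
    first draw that passes :func:`build_tree` validation, including the
    monopodial-dominance margin; deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_draws):
        n_gen = int(rng.integers(2, 4))
        bpp = int(rng.integers(2, 4))
        r1 = float(rng.uniform(55, 75))
        ratios = rng.uniform(0.5, 0.62, size=n_gen - 1)
        radii = [r1]
        for q in ratios:
            radii.append(max(radii[-1] * q, 18.0))
        walls = [max(0.25 * r, 6.0) for r in radii]
        decays = tuple(float(rng.uniform(0.2, 0.27)) if i == 0 else float(rng.uniform(0.28, 0.34))
                       for i in range(n_gen - 1)) or (1.0,)
        spec = TreeSpec(
            n_generations=n_gen,
            branches_per_parent=bpp,
            trunk_length=float(rng.uniform(1700, 2400)),
            length_decay=decays,
            lumen_radius=tuple(radii),
            wall_thickness=tuple(walls),
            branch_angle=float(rng.uniform(68, 80)),
            station_span=float(rng.uniform(0.4, 0.5)),
            seed=seed,
        )
        try:
            spec.validate()
            build_tree(spec)
        except ValueError:
            continue
        return spec
    raise RuntimeError(f"no valid random tree spec found for seed {seed}")


def expected_skeleton_branches(tree: CenterlineTree) -> int:
    """Number of junction-to-junction/end pieces the centerline decomposes into.

    Each branch with ``k`` daughters attached at interior stations is split
    into ``k + 1`` pieces.
    """
    return sum(len(tree.children(b.branch_id)) + 1 for b in tree.branches)


# ---------------------------------------------------------------------------
# Rasterisation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PhantomVolumes:
    """Voxelised phantom: compartments, branch ownership, generation map."""

    compartments: LabelVolume   # PARENCHYMA / LUMEN / WALL
    branch_map: LabelVolume     # branch id per artery voxel, 0 outside
    generation_map: LabelVolume  # generation per artery voxel, 0 outside
    tree: CenterlineTree
    truth: GroundTruth

    @property
    def lumen_mask(self) -> np.ndarray:
        return self.compartments.data == LUMEN

    def voxel_lumen_volume_mm3(self, generation: int) -> float:
        n = int(np.count_nonzero((self.generation_map.data == generation) & self.lumen_mask))
        return n * self.compartments.voxel_volume_um3 / UM3_PER_MM3


def _cylinder_distance(points: np.ndarray, start: np.ndarray, end: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Radial distance to the segment axis and an in-span mask.

    Branches are finite open cylinders (no end caps), so a point belongs
    to a branch only if its axial coordinate falls within the segment.
    """
    v = end - start
    L = float(np.linalg.norm(v))
    d = v / L
    s = (points - start) @ d
    radial = np.linalg.norm(points - start - s[:, None] * d, axis=1)
    return radial, (s >= 0.0) & (s <= L)


def rasterize(tree: CenterlineTree, spacing: float | Sequence[float] = 7.0,
              margin: float | None = None,
              origin: Sequence[float] | None = None,
              shape: Sequence[int] | None = None) -> PhantomVolumes:
    """Voxelise a centerline tree into compartment, branch and generation maps.

    Ties at compartment boundaries resolve to the innermost compartment
    (lumen over wall over parenchyma).  Voxels covered by several branches
    are owned by the branch whose axis is nearest.  If ``origin``/``shape``
    are given, every branch capsule must fit inside the domain; otherwise
    the domain is auto-fitted with ``margin`` µm of parenchyma (default
    twice the largest outer radius).
    """
    spacing3 = np.asarray([spacing] * 3, dtype=float) if np.isscalar(spacing) else np.asarray(spacing, dtype=float)
    if np.any(spacing3 <= 0):
        raise ValueError("spacing must be positive")
    branches = tree.branches
    if margin is None:
        margin = 2.0 * max((b.outer_radius for b in branches), default=50.0)

    if branches:
        lo = np.min([np.minimum(b.start, b.end) - b.outer_radius for b in branches], axis=0)
        hi = np.max([np.maximum(b.start, b.end) + b.outer_radius for b in branches], axis=0)
    else:
        lo = np.zeros(3)
        hi = np.full(3, 100.0)
    if origin is None:
        origin = lo - margin
        # Anchor the grid a quarter voxel off the root axis: parallel
        # thinning can retract a free-ended tube entirely when its axis is
        # voxel-symmetric (half-integer offsets), so break the symmetry.
        anchor = branches[0].start if branches else np.zeros(3)
        k = np.ceil((anchor - origin) / spacing3 - 0.25)
        origin = anchor - (k + 0.25) * spacing3
    origin = np.asarray(origin, dtype=float)
    if shape is None:
        shape = np.ceil((hi + margin - origin) / spacing3).astype(int) + 1
    shape = tuple(int(s) for s in shape)

    upper = origin + (np.asarray(shape) - 1) * spacing3
    for b in branches:
        b_lo = np.minimum(b.start, b.end) - b.outer_radius
        b_hi = np.maximum(b.start, b.end) + b.outer_radius
        if np.any(b_lo < origin - 0.5 * spacing3) or np.any(b_hi > upper + 0.5 * spacing3):
            raise ValueError(f"branch {b.branch_id} (generation {b.generation}) exceeds the "
                             f"rasterisation domain {origin}..{upper}")

    comp = np.zeros(shape, dtype=np.uint8)
    branch_map = np.zeros(shape, dtype=np.int32)
    gen_map = np.zeros(shape, dtype=np.uint8)
    best = np.full(shape, np.inf, dtype=np.float32)

    for b in branches:
        b_lo = np.minimum(b.start, b.end) - b.outer_radius
        b_hi = np.maximum(b.start, b.end) + b.outer_radius
        i_lo = np.maximum(np.floor((b_lo - origin) / spacing3).astype(int), 0)
        i_hi = np.minimum(np.ceil((b_hi - origin) / spacing3).astype(int) + 1, shape)
        if np.any(i_lo >= i_hi):
            continue
        sl = tuple(slice(a, z) for a, z in zip(i_lo, i_hi))
        idx = np.indices([z - a for a, z in zip(i_lo, i_hi)], dtype=float)
        pts = (idx.reshape(3, -1).T + i_lo) * spacing3 + origin
        radial, in_span = _cylinder_distance(pts, b.start, b.end)
        d = np.where(in_span, radial, np.inf).reshape(idx.shape[1:])

        inner = d <= b.lumen_radius
        outer = d <= b.outer_radius
        comp_box = comp[sl]
        comp_box[inner] = LUMEN
        comp_box[outer & ~inner & (comp_box != LUMEN)] = WALL

        own = outer & (d < best[sl])
        branch_map[sl][own] = b.branch_id
        gen_map[sl][own] = b.generation
        best[sl][own] = d[own].astype(np.float32)

    meta = dict(spacing=tuple(spacing3), origin=tuple(origin), vertical_axis=tree.vertical_axis)
    truth = dataclasses.replace(
        tree_truth(tree), total_domain_mm3=float(np.prod(shape) * np.prod(spacing3) / UM3_PER_MM3))
    return PhantomVolumes(
        LabelVolume(comp, **meta), LabelVolume(branch_map, **meta),
        LabelVolume(gen_map, **meta), tree, truth)


def tree_truth(tree: CenterlineTree) -> GroundTruth:
    """Closed-form ground truth recomputed directly from the branch list
    (valid also for trees edited after :func:`build_tree`)."""
    lumen: dict[int, float] = {}
    wall: dict[int, float] = {}
    surface: dict[int, float] = {}
    nb: dict[int, int] = {}
    gen_of: dict[int, int] = {}
    for b in tree.branches:
        g = b.generation
        lumen[g] = lumen.get(g, 0.0) + b.lumen_volume_um3() / UM3_PER_MM3
        wall[g] = wall.get(g, 0.0) + b.wall_volume_um3() / UM3_PER_MM3
        surface[g] = surface.get(g, 0.0) + b.luminal_surface_um2() / UM2_PER_MM2
        nb[g] = nb.get(g, 0) + 1
        gen_of[b.branch_id] = g
    return GroundTruth(lumen, wall, surface, gen_of, nb)


# ---------------------------------------------------------------------------
# µCT appearance
# ---------------------------------------------------------------------------

# Inverted-µCT convention: embedding-medium-filled spaces (vessel lumina,
# airways, alveolar airspace) appear bright, tissue appears dark.
DEFAULT_INTENSITIES = {PARENCHYMA: 130.0, LUMEN: 200.0, WALL: 40.0}


def simulate_uct(labels: LabelVolume, noise_sd: float = 8.0, blur_fwhm: float = 10.0,
                 seed: int = 0, intensities: dict[int, float] | None = None,
                 parenchyma_texture: float = 0.0, texture_scale_um: float = 60.0) -> VoxelVolume:
    """Render a compartment map as a µCT-like grayscale volume.

    Class intensities follow the inverted convention (plastic-filled spaces
    bright, tissue dark).  ``parenchyma_texture`` adds a smooth speckle to
    the parenchyma class emulating the alveolar air/septa mix (0 disables
    it); then a Gaussian blur of ``blur_fwhm`` µm and additive Gaussian
    noise of ``noise_sd`` are applied.  Deterministic for a fixed seed.
    """
    if noise_sd < 0 or blur_fwhm < 0:
        raise ValueError("noise_sd and blur_fwhm must be >= 0")
    lut = dict(DEFAULT_INTENSITIES)
    if intensities:
        lut.update(intensities)
    data = labels.data
    out = np.zeros(data.shape, dtype=np.float32)
    for cls, val in lut.items():
        out[data == cls] = val
    rng = np.random.default_rng(seed)
    if parenchyma_texture > 0:
        speckle = rng.standard_normal(data.shape).astype(np.float32)
        sig = tuple(texture_scale_um / (2.3548 * s) for s in labels.spacing)
        speckle = ndimage.gaussian_filter(speckle, sig)
        sd = speckle.std()
        if sd > 0:
            speckle *= parenchyma_texture / sd
        out[data == PARENCHYMA] += speckle[data == PARENCHYMA]
    if blur_fwhm > 0:
        sigma = tuple(blur_fwhm / (2.3548 * s) for s in labels.spacing)
        out = ndimage.gaussian_filter(out, sigma)
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=out.shape).astype(np.float32)
    return VoxelVolume(out.astype(np.float32), spacing=labels.spacing,
                       origin=labels.origin, vertical_axis=labels.vertical_axis)


# ---------------------------------------------------------------------------
# Serial-section simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SectionTransform:
    """Ground-truth deformation of one simulated physical section.

    Stored as the pull-back map ``W`` from deformed-section pixel
    coordinates to undeformed coordinates (both in pixels of the section
    frame): ``deformed(p) = original(W(p))`` with
    ``W(p) = A p + t + D(p)``, ``D`` a smooth displacement field.
    Registration of the deformed section back onto the undeformed one
    should recover ``W``.
    """

    matrix: np.ndarray                       # 2x2, acts on (row, col)
    translation: np.ndarray                  # (row, col) pixels
    displacement: np.ndarray | None = None   # (2, H, W) pixels, smooth part

    def map_points(self, points: np.ndarray) -> np.ndarray:
        """Apply ``W`` to an (N, 2) array of (row, col) pixel coordinates."""
        pts = np.asarray(points, dtype=float)
        out = pts @ self.matrix.T + self.translation
        if self.displacement is not None:
            for axis in range(2):
                out[:, axis] += ndimage.map_coordinates(
                    self.displacement[axis], pts.T, order=1, mode="nearest")
        return out

    def max_displacement(self, shape: tuple[int, int]) -> float:
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
        disp = self.map_points(pts) - pts
        return float(np.max(np.hypot(disp[:, 0], disp[:, 1])))


def apply_section_transform(image: np.ndarray, transform: SectionTransform,
                            order: int = 1) -> np.ndarray:
    """Warp a section by its ground-truth transform (pull-back sampling)."""
    shape = image.shape
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    src = transform.map_points(pts)
    coords = [src[:, 0].reshape(shape), src[:, 1].reshape(shape)]
    cval = 0.0
    return ndimage.map_coordinates(image, coords, order=order, mode="constant",
                                   cval=cval).astype(image.dtype, copy=False)


@dataclasses.dataclass
class SimulatedSectionStack:
    """Deformed serial sections plus their ground-truth transforms."""

    sections: list[np.ndarray]
    true_transforms: list[SectionTransform]
    section_indices: list[int]          # 1-based indices into the section series
    pixel_spacing: tuple[float, float]  # (row, col) µm
    thickness: float                    # µm


def _random_section_transform(rng: np.random.Generator, shape: tuple[int, int],
                              amplitude: float, pixel_spacing: tuple[float, float]
                              ) -> SectionTransform:
    """Draw an affine+smooth deformation, rescaled so the maximum landmark
    displacement over the section equals at most ``amplitude`` µm."""
    px = float(np.mean(pixel_spacing))
    amp_px = amplitude / px
    center = (np.asarray(shape, dtype=float) - 1) / 2.0
    theta = rng.uniform(-3, 3) * math.pi / 180.0
    scale = rng.uniform(0.97, 1.03, size=2)
    shear = rng.uniform(-0.03, 0.03)
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    A = rot @ np.diag(scale) @ np.array([[1.0, shear], [0.0, 1.0]])
    t_about_center = rng.uniform(-amp_px / 2, amp_px / 2, size=2)
    # affine around the section centre: W(p) = A (p - c) + c + t
    translation = center - A @ center + t_about_center

    # low-frequency displacement on a coarse grid, bicubically upsampled
    grid = rng.normal(0.0, 1.0, size=(2, 4, 4))
    disp = np.stack([ndimage.zoom(grid[a], (shape[0] / 4, shape[1] / 4), order=3)
                     for a in range(2)])
    disp = disp[:, :shape[0], :shape[1]]
    peak = np.max(np.hypot(disp[0], disp[1]))
    if peak > 0:
        disp *= (amp_px / 2) / peak

    tf = SectionTransform(A, translation, disp)
    # rescale the whole displacement (affine residual + smooth part) so the
    # max landmark displacement is bounded by the requested amplitude
    max_disp = tf.max_displacement(shape)
    if max_disp > amp_px and max_disp > 0:
        # W'(p) = p + s*(W(p) - p) stays affine+smooth and is exactly bounded
        s = amp_px / max_disp
        tf = SectionTransform(np.eye(2) + s * (A - np.eye(2)), s * translation, disp * s)
    return tf


def simulate_sections(volume: VoxelVolume, plan, deform_amplitude: float = 0.0,
                      seed: int = 0, interpolation_order: int = 1) -> SimulatedSectionStack:
    """Cut a volume into deformed serial sections following a section plan.

    Planes are extracted orthogonally to ``plan.section_normal`` at the
    plan's section thickness, then each section is warped by a random
    affine (rotation, anisotropic scale, shear, translation) plus a smooth
    low-frequency displacement whose total landmark displacement is
    bounded by ``deform_amplitude`` (µm).  The true per-section transforms
    are returned for registration-recovery experiments.
    ``deform_amplitude = 0`` yields plain plane extraction.
    """
    from .sectioning import collected_section_indices, extract_section

    indices = collected_section_indices(plan)
    if not indices:
        raise ValueError("section plan collects no sections within the volume")
    rng = np.random.default_rng(seed)
    sections: list[np.ndarray] = []
    transforms: list[SectionTransform] = []
    axes = [a for a in range(3) if a != plan.section_normal]
    pixel_spacing = (volume.spacing[axes[0]], volume.spacing[axes[1]])
    for s_idx in indices:
        img = extract_section(volume, plan, s_idx, order=interpolation_order)
        if deform_amplitude > 0:
            tf = _random_section_transform(rng, img.shape, deform_amplitude, pixel_spacing)
            img = apply_section_transform(img, tf, order=interpolation_order)
        else:
            tf = SectionTransform(np.eye(2), np.zeros(2), None)
        sections.append(img)
        transforms.append(tf)
    return SimulatedSectionStack(sections, transforms, list(indices), pixel_spacing,
                                 plan.section_thickness)
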