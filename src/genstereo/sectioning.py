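"""Virtual serial sectioning by systematic uniform random sampling (SURS).

A physical microtome run is modelled as a series of sections of fixed
thickness cut orthogonally to one volume axis.  Following standard SURS
practice, blocks of ``n_collected`` consecutive sections are kept and the
next ``n_skipped`` discarded, with a single uniform random start in the
first period; every block of collected sections is a *substack*.  Because
each section of the series is collected with probability
``n_collected / period``, weighting collected sections by
``period / n_collected`` yields unbiased Cavalieri volume estimates.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import LabelVolume, VoxelVolume, axis_index


@dataclasses.dataclass
class SectionPlan:
    """A SURS sectioning plan.

    ``random_start`` is the 1-based index of the first collected section
    and must lie in ``1..period`` with ``period = n_collected + n_skipped``.
    ``section_normal`` is the cutting axis; ``vertical_axis`` must be an
    in-plane axis (sections are cut parallel to the vertical axis).
    """

    total_sections: int
    section_thickness: float = 2.0
    n_collected: int = 20
    n_skipped: int = 50
    random_start: int = 1
    section_normal: int | str = 0
    vertical_axis: int | str = 1

    def __post_init__(self) -> None:
        self.section_normal = axis_index(self.section_normal)
        self.vertical_axis = axis_index(self.vertical_axis)
        if self.section_normal == self.vertical_axis:
            raise ValueError("section_normal must be perpendicular to vertical_axis")
        if self.total_sections < 0:
            raise ValueError("total_sections must be >= 0")
        if self.n_collected < 1 or self.n_skipped < 0:
            raise ValueError("need n_collected >= 1 and n_skipped >= 0")
        if self.section_thickness <= 0:
            raise ValueError("section_thickness must be positive")
        if not 1 <= self.random_start <= self.period:
            raise ValueError(f"random_start must lie in 1..{self.period}")

    @property
    def period(self) -> int:
        return self.n_collected + self.n_skipped

    @property
    def sampling_fraction(self) -> float:
        return self.n_collected / self.period

    def substack_starts(self) -> list[int]:
        """1-based indices of the first section of each substack."""
        return list(range(self.random_start, self.total_sections + 1, self.period))

    @property
    def n_substacks(self) -> int:
        return len(self.substack_starts())

    def substack_sections(self, substack_index: int) -> list[int]:
        """1-based section indices belonging to one substack (the last
        substack may be truncated by the end of the series)."""
        starts = self.substack_starts()
        if not 0 <= substack_index < len(starts):
            raise IndexError(f"substack index {substack_index} out of range "
                             f"(plan has {len(starts)} substacks)")
        s0 = starts[substack_index]
        return list(range(s0, min(s0 + self.n_collected, self.total_sections + 1)))

    def section_position_um(self, section_index: int) -> float:
        """Physical coordinate of a section's mid-plane along the normal
        axis, relative to the start of the series."""
        return (section_index - 1 + 0.5) * self.section_thickness

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["substack_starts"] = self.substack_starts()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SectionPlan":
        d = json.loads(text)
        d.pop("substack_starts", None)
        return cls(**d)


def make_plan(total_sections: int, section_thickness: float = 2.0,
              n_collected: int = 20, n_skipped: int = 50, seed: int = 0,
              section_normal: int | str = 0, vertical_axis: int | str = 1,
              random_start: int | None = None) -> SectionPlan:
    """Create a SURS plan, drawing the random start uniformly from
    ``1..period`` unless given explicitly.

    The collect/skip defaults (20 sections of 2 µm collected, 50 skipped)
    give a 140 µm period and a 2/7 sampled volume fraction.
    """
    if total_sections < 1:
        raise ValueError("total_sections must be >= 1")
    period = n_collected + n_skipped
    if random_start is None:
        rng = np.random.default_rng(seed)
        random_start = int(rng.integers(1, period + 1))
    return SectionPlan(total_sections, section_thickness, n_collected, n_skipped,
                       random_start, section_normal, vertical_axis)


def plan_for_volume(volume: VoxelVolume, section_thickness: float = 2.0,
                    n_collected: int = 20, n_skipped: int = 50, seed: int = 0,
                    section_normal: int | str = 0,
                    random_start: int | None = None) -> SectionPlan:
    """SURS plan covering the full extent of a volume along the normal axis."""
    normal = axis_index(section_normal)
    extent = volume.shape[normal] * volume.spacing[normal]
    total = int(np.floor(extent / section_thickness))
    return make_plan(total_sections=total, section_thickness=section_thickness,
                     n_collected=n_collected, n_skipped=n_skipped, seed=seed,
                     section_normal=normal, vertical_axis=volume.vertical_axis,
                     random_start=random_start)


def collected_section_indices(plan: SectionPlan) -> list[int]:
    """All 1-based collected section indices of the plan, in cutting order."""
    out: list[int] = []
    for i in range(plan.n_substacks):
        out.extend(plan.substack_sections(i))
    return out


def _inplane_axes(plan: SectionPlan) -> tuple[int, int]:
    """In-plane axes ordered (vertical first = image rows, other = columns)."""
    other = next(a for a in range(3) if a not in (plan.section_normal, plan.vertical_axis))
    return plan.vertical_axis, other


def extract_section(volume: VoxelVolume, plan: SectionPlan, section_index: int,
                    order: int | None = None) -> np.ndarray:
    """Resample one section plane from a volume.

    Returns a 2D array with the vertical axis as image rows.  Label
    volumes are sampled nearest-neighbour (no new label values), grayscale
    linearly; pass ``order`` to override.
    """
    if not 1 <= section_index <= plan.total_sections:
        raise ValueError(f"section index {section_index} outside 1..{plan.total_sections}")
    if order is None:
        order = 0 if isinstance(volume, LabelVolume) else 1
    normal = plan.section_normal
    ax_r, ax_c = _inplane_axes(plan)
    pos_um = plan.section_position_um(section_index)
    k = pos_um / volume.spacing[normal]  # continuous index along the normal
    k = min(max(k, 0.0), volume.shape[normal] - 1)
    nr, nc = volume.shape[ax_r], volume.shape[ax_c]
    rr, cc = np.meshgrid(np.arange(nr, dtype=float), np.arange(nc, dtype=float), indexing="ij")
    coords = [None, None, None]
    coords[normal] = np.full_like(rr, k)
    coords[ax_r] = rr
    coords[ax_c] = cc
    out = ndimage.map_coordinates(volume.data, coords, order=order, mode="nearest")
    return out


@dataclasses.dataclass
class Substack:
    """An ordered block of consecutive 2D sections treated as one thin 3D unit."""

    sections: np.ndarray                 # (n, rows, cols); rows = vertical axis
    pixel_spacing: tuple[float, float]   # (row, col) µm
    thickness: float                     # µm between sections
    depth_um: float                      # physical depth of the first section
    section_indices: list[int]           # 1-based source section indices
    inplane_origin: tuple[float, float] = (0.0, 0.0)  # physical (row, col) origin
    vertical_axis: int = 1

    @property
    def n_sections(self) -> int:
        return int(self.sections.shape[0])

    def to_volume(self) -> VoxelVolume:
        """View the substack as a thin 3D volume in the source physical frame
        (axis 0 = cutting direction)."""
        spacing = (self.thickness, *self.pixel_spacing)
        vol = VoxelVolume(np.ascontiguousarray(self.sections, dtype=np.float32),
                          spacing=spacing,
                          origin=(self.depth_um, *self.inplane_origin),
                          vertical_axis=1)
        return vol


def extract_substack(volume: VoxelVolume, plan: SectionPlan,
                     substack_index: int) -> Substack:
    """Extract one substack (all its collected sections) from a volume."""
    indices = plan.substack_sections(substack_index)
    sections = np.stack([extract_section(volume, plan, i) for i in indices])
    ax_r, ax_c = _inplane_axes(plan)
    return Substack(sections,
                    (volume.spacing[ax_r], volume.spacing[ax_c]),
                    plan.section_thickness,
                    volume.origin[plan.section_normal] + plan.section_position_um(indices[0]),
                    indices,
                    inplane_origin=(volume.origin[ax_r], volume.origin[ax_c]))


def project_substack(stack: Substack | np.ndarray, mode: str = "min") -> np.ndarray:
    """Reduce a substack to a single 2D image across its sections.

    ``min`` is the default: with dark stain on a bright background the
    minimum projection accumulates stained structure across the substack
    depth, which is how nearly-contained vessels become visible.
    """
    data = stack.sections if isinstance(stack, Substack) else np.asarray(stack)
    if data.ndim != 3 or data.shape[0] == 0:
        raise ValueError("expected a non-empty (n, rows, cols) section stack")
    reducers = {"min": np.min, "max": np.max, "mean": np.mean}
    if mode not in reducers:
        raise ValueError(f"unknown projection mode {mode!r}; choose from {sorted(reducers)}")
    return reducers[mode](data, axis=0)


def cavalieri_volume(plan: SectionPlan, section_areas_um2: Sequence[float]) -> float:
    """Cavalieri volume estimate (mm³) from the areas of collected sections.

    Each collected section stands for ``period / n_collected`` sections of
    the series, so
    ``V = (period / n_collected) * thickness * sum(areas)``.
    With exhaustive collection (``n_skipped = 0``) this reduces to the
    exact section-wise sum.
    """
    areas = np.asarray(list(section_areas_um2), dtype=float)
    if areas.size == 0:
        raise ValueError("no section areas supplied")
    weight = plan.period / plan.n_collected
    return float(weight * plan.section_thickness * areas.sum() / 1e9)
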