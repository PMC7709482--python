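"""Core image containers used throughout the package.

Volumes are stored as numpy arrays indexed ``[z][y][x]`` together with the
physical metadata needed for design-based stereology: isotropic or
anisotropic spacing in micrometres, a physical origin, and the identity of
the *vertical* axis.  The vertical axis is the anatomical reference
direction for vertical-section stereology (sections are cut parallel to
it and surface probes must be cycloids with their minor axis parallel
to it).

Conventions
-----------
* Indices are 0-based and voxel-centred: ``physical = origin + index * spacing``.
* ``spacing`` and ``origin`` are ordered ``(z, y, x)`` to match the array
  index order; SimpleITK uses the reverse order and the conversion
  helpers below take care of that.
* Grayscale data live in :class:`VoxelVolume`, integer class/label maps in
  :class:`LabelVolume`.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import SimpleITK as sitk

AXIS_NAMES = ("z", "y", "x")


def axis_index(axis: int | str) -> int:
    """Normalise an axis given as index or name ('z'/'y'/'x') to an index."""
    if isinstance(axis, str):
        try:
            return AXIS_NAMES.index(axis.lower())
        except ValueError:
            raise ValueError(f"unknown axis name {axis!r}; expected one of {AXIS_NAMES}")
    axis = int(axis)
    if axis not in (0, 1, 2):
        raise ValueError(f"axis index out of range: {axis}")
    return axis


def _as_triplet(value, name: str) -> tuple[float, float, float]:
    if np.isscalar(value):
        value = (float(value),) * 3
    value = tuple(float(v) for v in value)
    if len(value) != 3:
        raise ValueError(f"{name} must be a scalar or length-3 sequence, got {value!r}")
    return value


@dataclasses.dataclass
class VoxelVolume:
    """A 3D grayscale image with physical metadata.

    Parameters
    ----------
    data:
        Scalar intensities indexed ``[z][y][x]``.
    spacing:
        Voxel spacing in µm per axis ``(z, y, x)``; a scalar means
        isotropic spacing.  Default 7.0 µm, a typical whole-organ µCT
        voxel size.
    origin:
        Physical coordinate (µm) of voxel ``(0, 0, 0)``.
    vertical_axis:
        Index (or name) of the vertical anatomical axis.  Default ``y``.
    """

    data: np.ndarray
    spacing: Sequence[float] | float = 7.0
    origin: Sequence[float] | float = 0.0
    vertical_axis: int | str = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        self.spacing = _as_triplet(self.spacing, "spacing")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive on all axes, got {self.spacing}")
        self.origin = _as_triplet(self.origin, "origin")
        self.vertical_axis = axis_index(self.vertical_axis)

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    def physical(self, index) -> np.ndarray:
        """Physical coordinate (µm) of a (possibly fractional) index."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def index_of(self, point) -> np.ndarray:
        """Continuous index of a physical point (µm)."""
        return (np.asarray(point, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def extent_um(self) -> tuple[float, float, float]:
        """Physical edge lengths of the sampled domain (µm)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    # -- SimpleITK bridge -------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(self.data)
        img.SetSpacing(tuple(self.spacing[::-1]))
        img.SetOrigin(tuple(self.origin[::-1]))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, vertical_axis: int | str = 1) -> "VoxelVolume":
        data = sitk.GetArrayFromImage(img)
        spacing = tuple(img.GetSpacing()[::-1])
        origin = tuple(img.GetOrigin()[::-1])
        return cls(data, spacing=spacing, origin=origin, vertical_axis=vertical_axis)

    def with_data(self, data: np.ndarray) -> "VoxelVolume":
        """Same metadata, new voxel data."""
        return type(self)(data, spacing=self.spacing, origin=self.origin,
                          vertical_axis=self.vertical_axis)


class LabelVolume(VoxelVolume):
    """Integer class or label map sharing :class:`VoxelVolume` metadata."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            if np.issubdtype(self.data.dtype, np.bool_):
                self.data = self.data.astype(np.uint8)
            else:
                raise ValueError(f"label data must be integer, got dtype {self.data.dtype}")

    def label_counts(self) -> dict[int, int]:
        values, counts = np.unique(self.data, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}


# Compartment codes of rasterised phantoms and transported segmentations.
PARENCHYMA = 0
LUMEN = 1
WALL = 2

# Anatomical classes produced by segment joining.
CLS_BACKGROUND = 0
CLS_ARTERY = 1
CLS_VEIN = 2
CLS_AIRWAY = 3
CLASS_NAMES = {"background": CLS_BACKGROUND, "artery": CLS_ARTERY,
               "vein": CLS_VEIN, "airway": CLS_AIRWAY}

# Display convention for generations 1..5 (used by the CLI / plots).
GENERATION_COLORS = {1: "red", 2: "green", 3: "blue", 4: "yellow", 5: "cyan"}
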