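"""Volume and section I/O: NRRD, MetaImage and TIFF stacks.

NRRD and MetaImage carry spacing/origin in their headers and round-trip
losslessly (SimpleITK backend); the vertical-axis declaration travels in
a custom header key.  TIFF stacks store in-plane resolution and the
slice spacing in ImageJ-style metadata; a TIFF without usable spacing
metadata must be read with an explicit ``spacing`` argument.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile

from .core import AXIS_NAMES, LabelVolume, VoxelVolume

VERTICAL_AXIS_KEY = "genstereo_vertical_axis"
_SITK_EXT = {".nrrd", ".nhdr", ".mha", ".mhd"}
_TIFF_EXT = {".tif", ".tiff"}


def write_volume(volume: VoxelVolume, path: str | Path) -> None:
    """Write a volume; format chosen by extension (.nrrd/.nhdr/.mha/.mhd/.tif)."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext in _SITK_EXT:
        img = volume.to_sitk()
        img.SetMetaData(VERTICAL_AXIS_KEY, AXIS_NAMES[volume.vertical_axis])
        sitk.WriteImage(img, str(path))
    elif ext in _TIFF_EXT:
        sz, sy, sx = volume.spacing
        meta = {"spacing": sz, "unit": "um",
                VERTICAL_AXIS_KEY: AXIS_NAMES[volume.vertical_axis]}
        data = volume.data
        if data.dtype == np.int32:  # ImageJ TIFF has no int32 pixel type
            data = data.astype(np.float32) if np.abs(data).max() > 65535 else data.astype(np.uint16)
        tifffile.imwrite(path, data, imagej=True,
                         resolution=(1.0 / sx * 1e4, 1.0 / sy * 1e4),
                         metadata=meta)
    else:
        raise ValueError(f"unsupported volume format {ext!r} "
                         f"(supported: {sorted(_SITK_EXT | _TIFF_EXT)})")


def read_volume(path: str | Path, labels: bool | None = None,
                spacing=None, vertical_axis: int | str | None = None
                ) -> VoxelVolume | LabelVolume:
    """Read a volume; returns a :class:`LabelVolume` for integer data.

    ``labels`` forces the container type; ``spacing`` overrides (and for
    spacing-less TIFFs supplies) the voxel size in µm.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext in _SITK_EXT:
        img = sitk.ReadImage(str(path))
        va = vertical_axis
        if va is None:
            va = img.GetMetaData(VERTICAL_AXIS_KEY) if img.HasMetaDataKey(VERTICAL_AXIS_KEY) else 1
        vol = VoxelVolume.from_sitk(img, vertical_axis=va)
        if spacing is not None:
            vol = VoxelVolume(vol.data, spacing=spacing, origin=vol.origin, vertical_axis=va)
    elif ext in _TIFF_EXT:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            if data.ndim == 2:
                data = data[None]
            meta = tf.imagej_metadata or {}
            va = vertical_axis
            if va is None:
                va = meta.get(VERTICAL_AXIS_KEY, 1)
            if spacing is None:
                sz = meta.get("spacing")
                page = tf.pages[0]
                res = page.tags.get("XResolution")
                if sz is None or res is None:
                    raise ValueError(
                        f"{path} carries no spacing metadata; pass spacing=... explicitly")
                xres = res.value[0] / res.value[1]
                yres_tag = page.tags.get("YResolution")
                yres = yres_tag.value[0] / yres_tag.value[1] if yres_tag else xres
                spacing = (float(sz), 1e4 / yres, 1e4 / xres)
        vol = VoxelVolume(data, spacing=spacing, vertical_axis=va)
    else:
        raise ValueError(f"unsupported volume format {ext!r}")
    if labels is None:
        labels = np.issubdtype(vol.data.dtype, np.integer)
    if labels:
        data = vol.data
        if not np.issubdtype(data.dtype, np.integer):
            data = np.rint(data).astype(np.int32)
        return LabelVolume(data, spacing=vol.spacing, origin=vol.origin,
                           vertical_axis=vol.vertical_axis)
    return vol


def write_section_stack(sections, path: str | Path, pixel_spacing=(7.0, 7.0),
                        thickness: float = 2.0, depths_um=None) -> None:
    """Write 2D sections as a multi-page TIFF with per-page depth tags."""
    path = Path(path)
    arr = np.stack([np.asarray(s) for s in sections])
    meta = {"spacing": thickness, "unit": "um"}
    if depths_um is not None:
        meta["genstereo_depths_um"] = json.dumps([float(d) for d in depths_um])
    tifffile.imwrite(path, arr.astype(np.float32), imagej=True,
                     resolution=(1e4 / pixel_spacing[1], 1e4 / pixel_spacing[0]),
                     metadata=meta)


def read_section_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF section stack; returns (array, metadata)."""
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = dict(tf.imagej_metadata or {})
    if "genstereo_depths_um" in meta:
        meta["depths_um"] = json.loads(meta.pop("genstereo_depths_um"))
    return arr, meta
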