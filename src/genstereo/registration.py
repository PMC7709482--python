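"""Section-stack and volume-to-substack registration.

Registration follows the standard two-stage scheme for histological
material: an affine transform optimising translation, rotation, scale and
shear, followed by a B-spline free-form deformation correcting the local
distortions that physical sectioning introduces.  Transforms are
expressed, as is conventional for resampling, as maps from *fixed*-image
(reference) coordinates to *moving*-image coordinates; chains compose
affine first, then B-spline.

The 3D reference volume is registered *to* each substack (not the other
way around) so that every section of a substack has a matching resampled
volume slice from a single flat plane; registering substacks onto the
volume would mix material from different physical sections into one
output slice.

The optimizer backend is SimpleITK's registration framework behind a thin
interface; transforms serialise to JSON so runs are reproducible, and the
area-change factor of every deformable transform (summary of the Jacobian
determinant of the displacement) is reported because deformable mappings
change the extent of structures and hence bias downstream measurements.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
import SimpleITK as sitk

from .core import LabelVolume, VoxelVolume
from .sectioning import Substack


class RegistrationError(RuntimeError):
    """Optimizer divergence or an undefined similarity metric."""


# ---------------------------------------------------------------------------
# Transform chain
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TransformChain:
    """An affine transform optionally followed by a B-spline deformation.

    Maps fixed-image physical coordinates to moving-image physical
    coordinates (the direction a resampler needs).  The affine part must
    stay invertible.
    """

    dimension: int
    affine_matrix: np.ndarray
    affine_translation: np.ndarray
    affine_center: np.ndarray
    bspline: sitk.BSplineTransform | None = None

    def __post_init__(self) -> None:
        self.affine_matrix = np.asarray(self.affine_matrix, dtype=float).reshape(
            self.dimension, self.dimension)
        self.affine_translation = np.asarray(self.affine_translation, dtype=float)
        self.affine_center = np.asarray(self.affine_center, dtype=float)
        if abs(np.linalg.det(self.affine_matrix)) < 1e-12:
            raise ValueError("affine part of a transform chain must be invertible")

    # -- construction ------------------------------------------------------
    @classmethod
    def identity(cls, dimension: int) -> "TransformChain":
        return cls(dimension, np.eye(dimension), np.zeros(dimension), np.zeros(dimension))

    @classmethod
    def from_sitk_affine(cls, tf: sitk.Transform,
                         bspline: sitk.BSplineTransform | None = None) -> "TransformChain":
        dim = tf.GetDimension()
        affine = sitk.AffineTransform(tf) if not isinstance(tf, sitk.AffineTransform) else tf
        m = np.asarray(affine.GetMatrix()).reshape(dim, dim)
        return cls(dim, m, np.asarray(affine.GetTranslation()),
                   np.asarray(affine.GetCenter()), bspline)

    def as_sitk(self) -> sitk.Transform:
        aff = sitk.AffineTransform(self.dimension)
        aff.SetMatrix(self.affine_matrix.ravel())
        aff.SetTranslation(self.affine_translation)
        aff.SetCenter(self.affine_center)
        if self.bspline is None:
            return aff
        comp = sitk.CompositeTransform(self.dimension)
        comp.AddTransform(aff)
        comp.AddTransform(self.bspline)
        return comp

    # -- application -------------------------------------------------------
    def map_points(self, points: np.ndarray) -> np.ndarray:
        """Apply the chain to an (n, dim) array of physical points
        (coordinates ordered like sitk: x, y[, z])."""
        tf = self.as_sitk()
        pts = np.asarray(points, dtype=float)
        return np.array([tf.TransformPoint(tuple(p)) for p in pts])

    def compose(self, outer: "TransformChain") -> sitk.CompositeTransform:
        """``outer ∘ self`` as a composite (applied self-first by sitk)."""
        comp = sitk.CompositeTransform(self.dimension)
        comp.AddTransform(outer.as_sitk())
        comp.AddTransform(self.as_sitk())
        return comp

    # -- serialisation -----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "dimension": self.dimension,
            "affine": {
                "matrix": self.affine_matrix.tolist(),
                "translation": self.affine_translation.tolist(),
                "center": self.affine_center.tolist(),
            },
        }
        if self.bspline is not None:
            payload["bspline"] = {
                "fixed_parameters": list(self.bspline.GetFixedParameters()),
                "parameters": list(self.bspline.GetParameters()),
                "order": self.bspline.GetOrder(),
            }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "TransformChain":
        d = json.loads(text)
        bspline = None
        if "bspline" in d:
            bspline = sitk.BSplineTransform(d["dimension"], d["bspline"]["order"])
            bspline.SetFixedParameters(d["bspline"]["fixed_parameters"])
            bspline.SetParameters(d["bspline"]["parameters"])
        return cls(d["dimension"], np.array(d["affine"]["matrix"]),
                   np.array(d["affine"]["translation"]),
                   np.array(d["affine"]["center"]), bspline)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _to_sitk_2d(image: np.ndarray, spacing: tuple[float, float]) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(image, dtype=np.float32))
    img.SetSpacing((float(spacing[1]), float(spacing[0])))  # sitk is (x, y)
    return img


def _metric_for(name: str, reg: sitk.ImageRegistrationMethod) -> None:
    name = name.lower()
    if name in ("mi", "mattes", "mutual_information"):
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    elif name in ("meansquares", "mse"):
        reg.SetMetricAsMeanSquares()
    elif name in ("correlation", "ncc"):
        reg.SetMetricAsCorrelation()
    else:
        raise ValueError(f"unknown metric {name!r}")


def _run_registration(fixed: sitk.Image, moving: sitk.Image, initial: sitk.Transform,
                      metric: str, levels: int, iterations: int,
                      learning_rate: float = 1.0, sampling: float | None = None
                      ) -> sitk.Transform:
    reg = sitk.ImageRegistrationMethod()
    _metric_for(metric, reg)
    if sampling is not None:
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(sampling, 12345)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=learning_rate, minStep=1e-5,
        numberOfIterations=iterations, relaxationFactor=0.6)
    reg.SetOptimizerScalesFromPhysicalShift()
    shrink = [2 ** (levels - 1 - i) for i in range(levels)]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel([max(s - 1, 0) for s in shrink])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.SetInitialTransform(initial, inPlace=True)
    try:
        return reg.Execute(fixed, moving)
    except RuntimeError as err:  # pragma: no cover - backend failure surface
        raise RegistrationError(str(err)) from err


def _metric_value(fixed: sitk.Image, moving: sitk.Image, tf: sitk.Transform,
                  metric: str) -> float:
    reg = sitk.ImageRegistrationMethod()
    _metric_for(metric, reg)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetInitialTransform(tf, inPlace=False)
    return float(reg.MetricEvaluate(fixed, moving))


def _bspline_stage(fixed: sitk.Image, moving: sitk.Image, affine: sitk.Transform,
                   grid_spacing_px: float, metric: str,
                   iterations: int) -> sitk.BSplineTransform:
    mesh = [max(int(round(sz / grid_spacing_px)), 1) for sz in fixed.GetSize()]
    bspline = sitk.BSplineTransformInitializer(fixed, mesh)
    reg = sitk.ImageRegistrationMethod()
    _metric_for(metric, reg)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetMovingInitialTransform(affine)
    reg.SetInitialTransform(bspline, inPlace=True)
    reg.SetOptimizerAsLBFGSB(gradientConvergenceTolerance=1e-7,
                             numberOfIterations=iterations)
    reg.SetShrinkFactorsPerLevel([2, 1])
    reg.SetSmoothingSigmasPerLevel([1, 0])
    try:
        reg.Execute(fixed, moving)
    except RuntimeError as err:  # pragma: no cover
        raise RegistrationError(str(err)) from err
    return bspline


# ---------------------------------------------------------------------------
# Pairwise 2D stack registration
# ---------------------------------------------------------------------------

def register_pairwise_2d(stack: Substack | Sequence[np.ndarray],
                         pixel_spacing: tuple[float, float] | None = None,
                         metric: str = "meansquares", do_bspline: bool = False,
                         bspline_grid_px: float = 32.0, levels: int = 3,
                         iterations: int = 200) -> list[TransformChain]:
    """Align consecutive sections of a stack onto the first section's frame.

    For each consecutive pair, section ``n`` is the fixed image and
    section ``n+1`` the moving one; the resulting per-pair transforms are
    chained so entry ``k`` maps section-1 frame coordinates to section
    ``k+1`` coordinates (entry 0 is the identity for section 1).  The
    similarity metric must not end worse than it started, otherwise a
    :class:`RegistrationError` with diagnostics is raised.
    """
    if isinstance(stack, Substack):
        sections = [stack.sections[i] for i in range(stack.n_sections)]
        pixel_spacing = stack.pixel_spacing
    else:
        sections = list(stack)
        if pixel_spacing is None:
            pixel_spacing = (1.0, 1.0)
    if len(sections) < 2:
        raise ValueError("need at least two sections to register a stack")

    chains: list[TransformChain] = [TransformChain.identity(2)]
    accumulated: sitk.Transform | None = None
    for n in range(len(sections) - 1):
        fixed = _to_sitk_2d(sections[n], pixel_spacing)
        moving = _to_sitk_2d(sections[n + 1], pixel_spacing)
        init = sitk.CenteredTransformInitializer(
            fixed, moving, sitk.AffineTransform(2),
            sitk.CenteredTransformInitializerFilter.GEOMETRY)
        before = _metric_value(fixed, moving, init, metric)
        affine = _run_registration(fixed, moving, sitk.AffineTransform(init),
                                   metric, levels, iterations)
        after = _metric_value(fixed, moving, affine, metric)
        if after > before + 1e-9:
            raise RegistrationError(
                f"pairwise registration diverged at pair {n}->{n + 1}: "
                f"metric {before:.6g} -> {after:.6g}")
        bspline = None
        if do_bspline:
            bspline = _bspline_stage(fixed, moving, affine, bspline_grid_px,
                                     metric, iterations=50)
        pair = TransformChain.from_sitk_affine(affine, bspline)
        # chain into section-1 frame: frame1 -> section n -> section n+1
        if accumulated is None:
            accumulated = pair.as_sitk()
        else:
            comp = sitk.CompositeTransform(2)
            comp.AddTransform(accumulated)
            comp.AddTransform(pair.as_sitk())
            # sitk composites apply the *last added* transform first; we want
            # points to go frame1 -> ... -> n, then n -> n+1
            accumulated = comp
        chains.append(pair)
    return chains


def resample_2d(image: np.ndarray, chain: TransformChain,
                pixel_spacing: tuple[float, float],
                interpolation: str = "linear",
                reference_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Resample a 2D image through a chain (fixed frame -> image frame)."""
    img = _to_sitk_2d(image, pixel_spacing)
    ref_shape = reference_shape or image.shape
    ref = sitk.Image(int(ref_shape[1]), int(ref_shape[0]), sitk.sitkFloat32)
    ref.SetSpacing((float(pixel_spacing[1]), float(pixel_spacing[0])))
    interp = sitk.sitkNearestNeighbor if interpolation == "nearest" else sitk.sitkLinear
    out = sitk.Resample(img, ref, chain.as_sitk(), interp, 0.0)
    return sitk.GetArrayFromImage(out)


# ---------------------------------------------------------------------------
# 3D volume-to-substack registration
# ---------------------------------------------------------------------------

def register_volume_to_substack(volume: VoxelVolume, stack: Substack | VoxelVolume,
                                metric: str = "mi", do_bspline: bool = False,
                                bspline_grid_vox: float = 16.0, levels: int = 3,
                                iterations: int = 150) -> TransformChain:
    """Register the 3D reference volume to one substack.

    The substack is the fixed image, so the returned chain maps substack
    coordinates into volume coordinates and resampling the volume (or any
    label map defined on it) through the chain yields one matching slice
    per physical section.  Raises :class:`RegistrationError` when the
    fields of view do not overlap enough for the metric to be defined or
    when the optimizer diverges.
    """
    sub_vol = stack.to_volume() if isinstance(stack, Substack) else stack
    fixed = sub_vol.to_sitk()
    moving = volume.to_sitk()
    fixed = sitk.Cast(fixed, sitk.sitkFloat32)
    moving = sitk.Cast(moving, sitk.sitkFloat32)
    init = sitk.CenteredTransformInitializer(
        fixed, moving, sitk.AffineTransform(3),
        sitk.CenteredTransformInitializerFilter.GEOMETRY)
    try:
        before = _metric_value(fixed, moving, init, metric)
    except RuntimeError as err:
        raise RegistrationError(f"similarity metric undefined (insufficient overlap?): {err}")
    affine = _run_registration(fixed, moving, sitk.AffineTransform(init), metric,
                               levels, iterations, sampling=0.2)
    after = _metric_value(fixed, moving, affine, metric)
    if after > before + 1e-9:
        raise RegistrationError(f"volume registration diverged: metric {before:.6g} -> {after:.6g}")
    bspline = None
    if do_bspline:
        bspline = _bspline_stage(fixed, moving, affine, bspline_grid_vox, metric,
                                 iterations=30)
    return TransformChain.from_sitk_affine(affine, bspline)


def apply_transform(image: VoxelVolume | LabelVolume, chain: TransformChain,
                    reference: VoxelVolume, interpolation: str | None = None
                    ) -> VoxelVolume | LabelVolume:
    """Resample an image through a chain onto a reference grid.

    Label images always use nearest-neighbour interpolation (no label
    value may be invented); grayscale defaults to linear.  Out-of-domain
    voxels become background (0).
    """
    if chain.dimension != 3:
        raise ValueError("apply_transform expects a 3D chain; use resample_2d for sections")
    is_labels = isinstance(image, LabelVolume)
    if is_labels and interpolation == "linear":
        raise ValueError("label images must be resampled with nearest-neighbour interpolation")
    if interpolation is None:
        interpolation = "nearest" if is_labels else "linear"
    interp = sitk.sitkNearestNeighbor if interpolation == "nearest" else sitk.sitkLinear
    moving = image.to_sitk()
    ref = reference.to_sitk()
    out = sitk.Resample(sitk.Cast(moving, sitk.sitkFloat32) if not is_labels else moving,
                        ref, chain.as_sitk(), interp, 0)
    arr = sitk.GetArrayFromImage(out)
    if is_labels:
        return LabelVolume(arr.astype(image.data.dtype), spacing=reference.spacing,
                           origin=reference.origin, vertical_axis=reference.vertical_axis)
    return VoxelVolume(arr, spacing=reference.spacing, origin=reference.origin,
                       vertical_axis=reference.vertical_axis)


def jacobian_summary(chain: TransformChain, reference: VoxelVolume | None = None,
                     shape: tuple[int, ...] | None = None,
                     spacing: tuple[float, ...] | None = None) -> dict[str, float]:
    """Area/volume-change factor summary of a chain's deformation.

    Returns min/mean/max of the Jacobian determinant of the mapping over
    the reference grid.  For a pure affine chain this is a single number
    (the matrix determinant); deformable chains vary locally — the spread
    quantifies how much the deformation rescales structures.
    """
    det_affine = float(np.linalg.det(chain.affine_matrix))
    if chain.bspline is None:
        return {"min": det_affine, "mean": det_affine, "max": det_affine}
    if reference is not None:
        ref = reference.to_sitk()
    else:
        dim = chain.dimension
        shape = shape or (32,) * dim
        spacing = spacing or (1.0,) * dim
        ref = sitk.Image(*[int(s) for s in shape[::-1]],
                         sitk.sitkFloat32)
        ref.SetSpacing(tuple(float(s) for s in spacing[::-1]))
    field = sitk.TransformToDisplacementField(
        chain.as_sitk(), sitk.sitkVectorFloat64, ref.GetSize(), ref.GetOrigin(),
        ref.GetSpacing(), ref.GetDirection())
    jac = sitk.GetArrayFromImage(sitk.DisplacementFieldJacobianDeterminant(field))
    return {"min": float(jac.min()), "mean": float(jac.mean()), "max": float(jac.max())}
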