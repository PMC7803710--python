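"""Grid-aware volume and mask containers plus the spatial primitives shared by
every pipeline stage: resampling, rigid registration, binary morphology,
connected components and overlap/surface metrics.

Conventions
-----------
* Voxel arrays are indexed ``[i, j, k]`` (0-based), the fastest-varying index
  ``i`` running along the first physical axis.
* World coordinates are LPS millimetres (the DICOM convention); a grid maps a
  voxel index to the physical position of its *centre* via
  ``origin + direction @ (spacing * index)``.
* A :class:`RigidTransform` maps a point in the *target* (fixed) physical
  space to the corresponding point in the *source* (moving) space — the same
  convention ITK resampling and registration use, so a transform returned by
  :func:`register_rigid` plugs straight into :func:`resample`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

log = logging.getLogger(__name__)

MODALITIES = ("ZTE", "BB", "FIESTA_C", "DERIVED")


class GeometryError(ValueError):
    """Raised when grids are invalid or incompatible."""


class PipelineError(RuntimeError):
    """Raised when a pipeline stage cannot produce a valid result."""


# --------------------------------------------------------------------------- #
# grids and containers
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class Grid:
    """Regular 3D sampling grid with physical geometry."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        d = np.asarray(self.direction, dtype=float).reshape(3, 3)
        object.__setattr__(self, "direction", d)
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise GeometryError(f"invalid shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.allclose(d @ d.T, np.eye(3), atol=1e-6):
            raise GeometryError("direction matrix is not orthonormal within 1e-6")

    def index_to_physical(self, index) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(index, dtype=float))
        pts = np.asarray(self.origin) + (idx * np.asarray(self.spacing)) @ self.direction.T
        return pts if np.asarray(index).ndim > 1 else pts[0]

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical size of the field of view (voxel centres span + one voxel)."""
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def physical_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box (LPS) of all voxel centres."""
        corners = np.array([[i * (s - 1) for i, s in zip(c, self.shape)]
                            for c in np.ndindex(2, 2, 2)], dtype=float)
        pts = self.index_to_physical(corners)
        return pts.min(axis=0), pts.max(axis=0)

    def close_to(self, other: "Grid", tol: float = 1e-4) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing, atol=tol)
                and np.allclose(self.origin, other.origin, atol=tol)
                and np.allclose(self.direction, other.direction, atol=1e-6))

    def __eq__(self, other):
        return isinstance(other, Grid) and self.close_to(other, tol=1e-9)

    def __hash__(self):
        return hash((self.shape, self.spacing, self.origin))


@dataclass
class ImageVolume:
    """A 3D scalar field on a regular grid with a modality tag."""

    voxels: np.ndarray
    grid: Grid
    modality: str = "DERIVED"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise GeometryError("voxels must be a 3D array")
        if tuple(self.voxels.shape) != self.grid.shape:
            raise GeometryError(
                f"voxel shape {self.voxels.shape} != grid shape {self.grid.shape}")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if np.issubdtype(self.voxels.dtype, np.floating) and not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels contain NaN/Inf")

    @property
    def spacing(self):
        return self.grid.spacing

    def with_voxels(self, voxels, modality=None) -> "ImageVolume":
        return ImageVolume(voxels, self.grid, modality or self.modality)


@dataclass
class BinaryMask:
    """Boolean field sharing an :class:`ImageVolume`'s grid."""

    voxels: np.ndarray
    grid: Grid

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels).astype(bool)
        if tuple(self.voxels.shape) != self.grid.shape:
            raise GeometryError(
                f"mask shape {self.voxels.shape} != grid shape {self.grid.shape}")

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        _require_same_grid(self, other)
        return BinaryMask(self.voxels & other.voxels, self.grid)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        _require_same_grid(self, other)
        return BinaryMask(self.voxels | other.voxels, self.grid)

    def __invert__(self) -> "BinaryMask":
        return BinaryMask(~self.voxels, self.grid)


def _require_same_grid(a, b):
    if not a.grid.close_to(b.grid):
        raise GeometryError("operands are not defined on the same grid")


# --------------------------------------------------------------------------- #
# SimpleITK bridge
# --------------------------------------------------------------------------- #

def to_sitk(obj) -> sitk.Image:
    """Convert an ImageVolume/BinaryMask to a SimpleITK image (LPS geometry)."""
    if isinstance(obj, BinaryMask):
        arr = obj.voxels.astype(np.uint8)
    else:
        arr = np.asarray(obj.voxels, dtype=np.float32)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in obj.grid.spacing))
    img.SetOrigin(tuple(float(o) for o in obj.grid.origin))
    img.SetDirection(tuple(obj.grid.direction.flatten()))
    return img


def grid_from_sitk(img: sitk.Image) -> Grid:
    return Grid(shape=tuple(img.GetSize()),
                spacing=tuple(img.GetSpacing()),
                origin=tuple(img.GetOrigin()),
                direction=np.asarray(img.GetDirection()).reshape(3, 3))


def volume_from_sitk(img: sitk.Image, modality: str = "DERIVED") -> ImageVolume:
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return ImageVolume(arr, grid_from_sitk(img), modality)


def mask_from_sitk(img: sitk.Image) -> BinaryMask:
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return BinaryMask(arr > 0, grid_from_sitk(img))


# --------------------------------------------------------------------------- #
# rigid transforms
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class RigidTransform:
    """6-parameter rigid map between physical spaces.

    ``rotation_deg`` are ITK Euler angles (about x, y, z, in degrees) applied
    about ``center_mm``; the map is ``y = R (x - c) + c + t``.
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        for name in ("rotation_deg", "translation_mm", "center_mm"):
            object.__setattr__(self, name, tuple(float(v) for v in getattr(self, name)))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def to_sitk(self) -> sitk.Euler3DTransform:
        t = sitk.Euler3DTransform()
        t.SetCenter(self.center_mm)
        t.SetRotation(*np.deg2rad(self.rotation_deg))
        t.SetTranslation(self.translation_mm)
        return t

    @classmethod
    def from_sitk(cls, t: sitk.Euler3DTransform) -> "RigidTransform":
        return cls(rotation_deg=tuple(np.rad2deg([t.GetAngleX(), t.GetAngleY(), t.GetAngleZ()])),
                   translation_mm=tuple(t.GetTranslation()),
                   center_mm=tuple(t.GetCenter()))

    def matrix_offset(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (R, b) such that y = R x + b."""
        t = self.to_sitk()
        r = np.asarray(t.GetMatrix()).reshape(3, 3)
        c = np.asarray(self.center_mm)
        b = np.asarray(self.translation_mm) + c - r @ c
        return r, b

    def apply(self, points) -> np.ndarray:
        r, b = self.matrix_offset()
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ r.T + b
        return out if np.asarray(points).ndim > 1 else out[0]

    def inverse(self) -> "RigidTransform":
        r, b = self.matrix_offset()
        return _from_matrix_offset(r.T, -r.T @ b)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the map ``x -> self(other(x))``."""
        r1, b1 = self.matrix_offset()
        r2, b2 = other.matrix_offset()
        return _from_matrix_offset(r1 @ r2, r1 @ b2 + b1)

    @property
    def is_identity(self) -> bool:
        return (np.allclose(self.rotation_deg, 0, atol=1e-12)
                and np.allclose(self.translation_mm, 0, atol=1e-12))


def _from_matrix_offset(r: np.ndarray, b: np.ndarray) -> RigidTransform:
    t = sitk.Euler3DTransform()
    t.SetCenter((0.0, 0.0, 0.0))
    t.SetMatrix(tuple(np.asarray(r, dtype=float).flatten()), 1e-8)
    t.SetTranslation(tuple(np.asarray(b, dtype=float)))
    return RigidTransform.from_sitk(t)


# --------------------------------------------------------------------------- #
# resampling
# --------------------------------------------------------------------------- #

_INTERP = {"linear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor}


def resample(source: ImageVolume, target_grid: Grid,
             transform: RigidTransform | None = None,
             interpolation: str = "linear", fill: float = 0.0) -> ImageVolume:
    """Resample ``source`` onto ``target_grid``.

    ``transform`` maps target physical points to source physical points
    (identity when omitted). Regions sampling outside the source map to
    ``fill``.
    """
    if interpolation not in _INTERP:
        raise ValueError(f"interpolation must be one of {sorted(_INTERP)}")
    if interpolation == "nearest":
        vals = np.unique(source.voxels.ravel()[:: max(1, source.voxels.size // 4096)])
        if not np.all(np.isin(vals, (0, 1))):
            warnings.warn("nearest-neighbour interpolation requested for "
                          "non-mask intensities", stacklevel=2)
    t = (transform or RigidTransform.identity()).to_sitk()
    out = sitk.Resample(to_sitk(source), target_grid.shape, t,
                        _INTERP[interpolation],
                        tuple(float(o) for o in target_grid.origin),
                        tuple(float(s) for s in target_grid.spacing),
                        tuple(target_grid.direction.flatten()),
                        float(fill), sitk.sitkFloat32)
    res = volume_from_sitk(out, source.modality)
    return ImageVolume(res.voxels, target_grid, source.modality)


def resample_mask(mask: BinaryMask, target_grid: Grid,
                  transform: RigidTransform | None = None) -> BinaryMask:
    """Nearest-neighbour transfer of a binary mask onto another grid."""
    vol = ImageVolume(mask.voxels.astype(np.float32), mask.grid, "DERIVED")
    out = resample(vol, target_grid, transform, interpolation="nearest", fill=0.0)
    return BinaryMask(out.voxels > 0.5, target_grid)


# --------------------------------------------------------------------------- #
# rigid registration
# --------------------------------------------------------------------------- #

def register_rigid(moving: ImageVolume, fixed: ImageVolume,
                   seed: int = 12345) -> RigidTransform:
    """Mutual-information rigid registration of ``moving`` onto ``fixed``.

    Mattes mutual information is used because the two inputs generally have
    different contrasts (ZTE vs black-bone). Initialised at centre-of-mass
    (moments) alignment; deterministic for a fixed ``seed``. If the optimised
    transform does not improve the similarity over the initialisation, the
    initial transform is returned with a logged warning.

    The returned transform maps fixed-space points into moving space, ready
    for :func:`resample`.
    """
    f = sitk.Cast(to_sitk(fixed), sitk.sitkFloat32)
    m = sitk.Cast(to_sitk(moving), sitk.sitkFloat32)
    if float(np.ptp(fixed.voxels)) == 0 or float(np.ptp(moving.voxels)) == 0:
        raise PipelineError("registration requires non-constant volumes")

    initial = sitk.CenteredTransformInitializer(
        f, m, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.MOMENTS)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    reg.SetMetricSamplingStrategy(reg.REGULAR)
    reg.SetMetricSamplingPercentage(0.10, int(seed) % (2 ** 31 - 1) or 1)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=150,
        relaxationFactor=0.6, gradientMagnitudeTolerance=1e-6)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(sitk.Euler3DTransform(initial), inPlace=False)

    final = reg.Execute(f, m).Downcast()
    if isinstance(final, sitk.CompositeTransform):
        final = final.GetNthTransform(0).Downcast()

    def _metric(transform):
        ev = sitk.ImageRegistrationMethod()
        ev.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
        ev.SetMetricSamplingStrategy(ev.REGULAR)
        ev.SetMetricSamplingPercentage(0.10, int(seed) % (2 ** 31 - 1) or 1)
        ev.SetInterpolator(sitk.sitkLinear)
        ev.SetInitialTransform(transform, inPlace=False)
        return ev.MetricEvaluate(f, m)

    initial_metric = _metric(sitk.Euler3DTransform(initial))
    final_metric = _metric(sitk.Euler3DTransform(final))
    if final_metric > initial_metric:  # Mattes MI in ITK: lower is better
        log.warning("registration did not improve similarity "
                    "(%.4f -> %.4f); returning centre-of-mass initialisation",
                    initial_metric, final_metric)
        return RigidTransform.from_sitk(sitk.Euler3DTransform(initial))
    return RigidTransform.from_sitk(sitk.Euler3DTransform(final))


# --------------------------------------------------------------------------- #
# metrics
# --------------------------------------------------------------------------- #

def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); 1.0 when both masks are empty."""
    _require_same_grid(a, b)
    na, nb = a.count, b.count
    if na == 0 and nb == 0:
        return 1.0
    inter = int((a.voxels & b.voxels).sum())
    return 2.0 * inter / (na + nb)


def precision_recall(pred: BinaryMask, truth: BinaryMask) -> tuple[float, float]:
    _require_same_grid(pred, truth)
    tp = int((pred.voxels & truth.voxels).sum())
    p = tp / pred.count if pred.count else 0.0
    r = tp / truth.count if truth.count else 0.0
    return p, r


def _boundary(mask: np.ndarray) -> np.ndarray:
    er = ndimage.binary_erosion(mask, ndimage.generate_binary_structure(3, 1),
                                border_value=0)
    return mask & ~er


def mean_abs_surface_distance(a: BinaryMask, b: BinaryMask) -> float:
    """Symmetric mean absolute distance (mm) between mask boundaries."""
    _require_same_grid(a, b)
    if a.count == 0 or b.count == 0:
        if a.count == b.count:
            return 0.0
        raise PipelineError("surface distance undefined for an empty mask")
    sa, sb = _boundary(a.voxels), _boundary(b.voxels)
    spacing = a.grid.spacing
    d_to_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    d_to_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    dists = np.concatenate([d_to_b[sa], d_to_a[sb]])
    return float(dists.mean())


# --------------------------------------------------------------------------- #
# connected components and morphology
# --------------------------------------------------------------------------- #

_STRUCTS = {6: ndimage.generate_binary_structure(3, 1),
            26: ndimage.generate_binary_structure(3, 3)}


def largest_component(mask: BinaryMask, connectivity: int = 26) -> BinaryMask:
    """Keep only the largest connected component.

    Ties are broken deterministically by the lowest linear index of a
    component's first voxel (C order).
    """
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 6 or 26")
    if mask.count == 0:
        warnings.warn("largest_component called on an empty mask", stacklevel=2)
        return BinaryMask(mask.voxels.copy(), mask.grid)
    labels, n = ndimage.label(mask.voxels, structure=_STRUCTS[connectivity])
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best_size = sizes.max()
    # scipy labels components in raster order, so among equal-size components
    # the smallest label is the one whose first voxel has the lowest linear
    # index.
    best = int(np.flatnonzero(sizes == best_size)[0])
    return BinaryMask(labels == best, mask.grid)


def remove_small_components(mask: BinaryMask, min_voxels: int,
                            connectivity: int = 26) -> BinaryMask:
    """Drop connected components smaller than ``min_voxels``."""
    if mask.count == 0 or min_voxels <= 1:
        return BinaryMask(mask.voxels.copy(), mask.grid)
    labels, n = ndimage.label(mask.voxels, structure=_STRUCTS[connectivity])
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_voxels
    keep[0] = False
    return BinaryMask(keep[labels], mask.grid)


def morphology(mask: BinaryMask, op: str, radius_mm: float) -> BinaryMask:
    """Binary morphology with a *physical-space* ball structuring element.

    The ball respects anisotropic spacing (a 2 mm radius spans different voxel
    extents along each axis); implemented via exact Euclidean distance
    transforms, which is equivalent to a structuring-element sweep with
    ``B = {offset : ||offset * spacing|| <= radius}``.
    """
    ops = ("erode", "dilate", "close", "open", "fill_holes")
    if op not in ops:
        raise ValueError(f"op must be one of {ops}")
    if radius_mm < 0:
        raise ValueError("radius_mm must be >= 0")
    v = mask.voxels
    spacing = mask.grid.spacing

    if op == "fill_holes":
        return BinaryMask(ndimage.binary_fill_holes(v), mask.grid)
    if radius_mm == 0:
        return BinaryMask(v.copy(), mask.grid)
    if radius_mm < min(spacing) / 2.0:
        warnings.warn(f"structuring radius {radius_mm} mm is below half the "
                      "smallest voxel spacing; morphology is the identity",
                      stacklevel=2)
        return BinaryMask(v.copy(), mask.grid)

    def _erode(x):
        if not x.any():
            return x.copy()
        d = ndimage.distance_transform_edt(x, sampling=spacing)
        return d > radius_mm

    def _dilate(x):
        if x.all():
            return x.copy()
        d = ndimage.distance_transform_edt(~x, sampling=spacing)
        return x | (d <= radius_mm)

    if op == "erode":
        out = _erode(v)
    elif op == "dilate":
        out = _dilate(v)
    elif op == "close":
        out = _erode(_dilate(v))
    else:  # open
        out = _dilate(_erode(v))
    return BinaryMask(out, mask.grid)
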