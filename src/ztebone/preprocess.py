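"""Shared front half of both segmentation pipelines: denoising, intensity
normalisation, head-mask generation, N4 bias-field correction, skin removal
and render-window rescaling.

All free parameters live in :class:`PipelineConfig`, which round-trips through
YAML/JSON so a run is fully described by one small file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import yaml
from skimage.filters import threshold_otsu

from .core import (BinaryMask, Grid, ImageVolume, PipelineError, largest_component,
                   morphology, to_sitk, volume_from_sitk)

log = logging.getLogger(__name__)

#: reference value the interior median is scaled to by normalise_intensity
SOFT_TISSUE_REFERENCE = 1000.0

#: output ceiling of rescale_for_render (int16-positive range, DICOM friendly)
RENDER_MAX = 32767.0


@dataclass
class PipelineConfig:
    """Every threshold, radius and flag the segmentation pipelines expose.

    Thresholds on the black-bone / FIESTA-C side are expressed as fractions of
    the soft-tissue reference (interior median after normalisation = 1000);
    ZTE bone thresholds are in negative-log units of the same normalised
    intensity, where soft tissue sits near 0 and air far above 1.
    """

    denoise_method: str = "curvature_flow"      # gaussian | curvature_flow | none
    denoise_strength: float = 8.0               # iterations (curvature_flow) or 10x sigma mm (gaussian)
    headmask_threshold_method: str = "otsu"     # otsu | fixed
    headmask_threshold_value: float = 0.0       # used when method == fixed
    headmask_close_radius_mm: float = 2.0
    skin_thickness_mm: float = 3.0
    zte_bone_low: float = 0.15                  # -ln(I/1000) lower bound for bone
    zte_bone_high: float = 1.5                  # -ln(I/1000) upper bound (air above)
    zte_open_radius_mm: float = 0.5
    zte_air_margin_mm: float = 2.0              # exclusion margin around detected air
    # midpoint between the signal-void class (bone/air, residual signal ~5% of
    # the reference) and soft tissue, so the threshold crossing coincides with
    # the geometric boundary for partial-volume voxels
    bb_bone_threshold: float = 0.525            # fraction of soft-tissue reference
    search_dilation_mm: float = 3.0
    min_component_voxels: int = 100
    registration_enabled: bool = False
    render_window: tuple[float, float] = (0.0, 1200.0)
    seed: int = 0

    def __post_init__(self):
        self.render_window = tuple(float(v) for v in self.render_window)
        for name in ("headmask_close_radius_mm", "skin_thickness_mm",
                     "zte_open_radius_mm", "search_dilation_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.zte_bone_low < self.zte_bone_high:
            raise ValueError("zte_bone_low must be < zte_bone_high")
        if not self.render_window[0] < self.render_window[1]:
            raise ValueError("render_window must be ordered (low, high)")
        if self.denoise_method not in ("gaussian", "curvature_flow", "none"):
            raise ValueError(f"unknown denoise_method {self.denoise_method!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["render_window"] = list(self.render_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2) if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=True))
        path.write_text(text)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        path = Path(path)
        d = (json.loads(path.read_text()) if path.suffix == ".json"
             else yaml.safe_load(path.read_text()))
        return cls.from_dict(d)


@dataclass
class BiasField:
    """Smooth, strictly positive multiplicative intensity field."""

    values: np.ndarray
    grid: Grid

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if tuple(self.values.shape) != self.grid.shape:
            raise ValueError("bias field shape does not match its grid")
        if not np.all(np.isfinite(self.values)) or self.values.min() <= 0:
            raise ValueError("bias field must be finite and strictly positive")

    def log(self) -> np.ndarray:
        return np.log(self.values)


# --------------------------------------------------------------------------- #
# denoising
# --------------------------------------------------------------------------- #

def denoise(volume: ImageVolume, config: PipelineConfig) -> ImageVolume:
    """Edge-preserving (curvature flow) or Gaussian denoising.

    ``denoise_strength`` counts iterations for curvature flow and maps to a
    Gaussian sigma of ``strength / 10`` mm for the Gaussian method. Method
    ``none`` is the bit-exact identity.
    """
    if config.denoise_method == "none":
        return volume.with_voxels(volume.voxels.copy())
    img = sitk.Cast(to_sitk(volume), sitk.sitkFloat32)
    if config.denoise_method == "gaussian":
        sigma = max(config.denoise_strength / 10.0, 1e-3)
        out = sitk.SmoothingRecursiveGaussian(img, sigma)
    else:
        # run the flow in index space: the explicit scheme's stable time step
        # scales with voxel size, so unit spacing keeps 0.0625 stable on any
        # grid and the smoothing extent is ~1 voxel regardless of resolution
        spacing, origin = img.GetSpacing(), img.GetOrigin()
        img.SetSpacing((1.0, 1.0, 1.0))
        img.SetOrigin((0.0, 0.0, 0.0))
        out = sitk.CurvatureFlow(img, timeStep=0.0625,
                                 numberOfIterations=int(round(config.denoise_strength)))
        out.SetSpacing(spacing)
        out.SetOrigin(origin)
    res = volume_from_sitk(out, volume.modality)
    return ImageVolume(res.voxels, volume.grid, volume.modality)


# --------------------------------------------------------------------------- #
# head mask
# --------------------------------------------------------------------------- #

def head_mask(volume: ImageVolume, config: PipelineConfig) -> BinaryMask:
    """Binary head region: threshold, morphological close, hole filling,
    largest connected component.

    Holes are filled *before* the component selection so that a dark skull
    shell (black-bone contrast) cannot split scalp from brain: the shell and
    any internal cavity are enclosed background and get filled.
    """
    v = volume.voxels
    if config.headmask_threshold_method == "fixed":
        thr = config.headmask_threshold_value
    else:
        if float(np.ptp(v)) == 0:
            raise PipelineError("no head found: constant volume")
        thr = float(threshold_otsu(v.astype(np.float32)))
    fg = BinaryMask(v > thr, volume.grid)
    if fg.count == 0:
        raise PipelineError("no head found: empty threshold result")
    if config.headmask_close_radius_mm > 0:
        fg = morphology(fg, "close", config.headmask_close_radius_mm)
    fg = morphology(fg, "fill_holes", 0.0)
    fg = largest_component(fg, connectivity=26)
    fg = morphology(fg, "fill_holes", 0.0)
    if fg.count < config.min_component_voxels:
        raise PipelineError("no head found: largest component below "
                            f"min_component_voxels ({fg.count} voxels)")
    if fg.count > 0.9 * fg.voxels.size:
        # a head is always surrounded by background air in the FOV; a mask
        # filling the volume means the threshold latched onto noise
        raise PipelineError("no head found: foreground fills the field of view")
    return fg


# --------------------------------------------------------------------------- #
# N4 bias correction
# --------------------------------------------------------------------------- #

def estimate_and_correct_bias(volume: ImageVolume, mask: BinaryMask,
                              config: PipelineConfig,
                              shrink: int = 4) -> tuple[ImageVolume, BiasField]:
    """N4 estimation and removal of a smooth multiplicative bias field.

    The field is estimated on a shrunk copy (speed), reconstructed at full
    resolution, normalised to zero log-mean inside the mask (the overall scale
    is not identifiable and belongs to intensity normalisation), clipped to
    the sanity range [0.2, 5], and divided out everywhere.
    """
    if mask.count == 0:
        raise PipelineError("bias correction requires a nonempty mask")
    vox = volume.voxels
    if float(np.abs(vox[mask.voxels]).max()) == 0:
        raise PipelineError("bias correction: masked region is all zero")

    img = sitk.Cast(to_sitk(volume), sitk.sitkFloat32) + 1e-3
    msk = to_sitk(mask)
    shrink = max(1, int(shrink))
    small = sitk.Shrink(img, [shrink] * 3)
    small_mask = sitk.Shrink(msk, [shrink] * 3)

    n4 = sitk.N4BiasFieldCorrectionImageFilter()
    n4.SetMaximumNumberOfIterations([50, 50, 50])
    n4.Execute(small, small_mask)
    log_field = sitk.GetArrayFromImage(
        n4.GetLogBiasFieldAsImage(img)).transpose(2, 1, 0).astype(np.float64)

    log_field -= float(log_field[mask.voxels].mean())
    fld = np.clip(np.exp(log_field), 0.2, 5.0)
    corrected = (vox / fld).astype(np.float32)
    return (ImageVolume(corrected, volume.grid, volume.modality),
            BiasField(fld, volume.grid))


# --------------------------------------------------------------------------- #
# skin removal, normalisation, render rescale
# --------------------------------------------------------------------------- #

def remove_skin(head: BinaryMask, config: PipelineConfig) -> BinaryMask:
    """Erode the head mask inward by ``skin_thickness_mm`` (physical space)."""
    if config.skin_thickness_mm == 0:
        return BinaryMask(head.voxels.copy(), head.grid)
    out = morphology(head, "erode", config.skin_thickness_mm)
    if out.count == 0:
        raise PipelineError("skin thickness exceeds head radius")
    return out


def normalise_intensity(volume: ImageVolume,
                        interior: BinaryMask) -> tuple[ImageVolume, float]:
    """Scale intensities so the interior median equals the soft-tissue
    reference (1000). Pure scaling, no offset; returns (volume, scale)."""
    if interior.count == 0:
        raise PipelineError("normalisation requires a nonempty interior mask")
    med = float(np.median(volume.voxels[interior.voxels]))
    if med <= 0:
        raise PipelineError(f"interior median must be positive, got {med}")
    scale = SOFT_TISSUE_REFERENCE / med
    out = (volume.voxels * scale).astype(np.float32)
    return ImageVolume(out, volume.grid, volume.modality), scale


def rescale_for_render(volume: ImageVolume, config: PipelineConfig) -> ImageVolume:
    """Window to ``render_window`` and map affinely onto [0, 32767].

    Monotone inside the window (relative contrast survives for end-user
    rendering); values outside clamp to the range ends.
    """
    low, high = config.render_window
    if not low < high:
        raise PipelineError("degenerate render window")
    v = np.clip(volume.voxels, low, high)
    out = ((v - low) / (high - low) * RENDER_MAX).astype(np.float32)
    return ImageVolume(out, volume.grid, volume.modality)
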