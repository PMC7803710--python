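"""Craniofacial bone segmentation.

Two fully automated algorithms:

* **BB-only** — segments a single black-bone (or FIESTA-C) volume. Because
  cortical bone and air are both signal voids in these contrasts, dark-voxel
  candidates inside the skin-removed head *conflate bone with internal air* —
  a known, deliberate limitation of the single-contrast route.
* **ZTE-driven** — a low-resolution ZTE volume, in which bone carries
  intermediate signal between dark air and bright soft tissue, is segmented
  first; its bone mask is transferred to the high-resolution grid and dilated
  to form a *search region*. High-resolution dark-voxel candidates are
  accepted as bone only inside that region: ZTE decides *where* bone is, the
  high-resolution contrast decides *exactly which voxels* are bone. Internal
  air and dark non-bony tissue (tendons, muscle attachments) fall outside the
  search region and are rejected.

Both return a :class:`SegmentationResult` whose render volume preserves
(inverted) intensity information inside the bone mask, so an end user can
still window/adjust the 3D rendering instead of being stuck with a hard
binary surface.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (BinaryMask, ImageVolume, PipelineError, RigidTransform,
                   morphology, register_rigid, remove_small_components,
                   resample_mask)
from .preprocess import (SOFT_TISSUE_REFERENCE, RENDER_MAX, BiasField,
                         PipelineConfig, denoise, estimate_and_correct_bias,
                         head_mask, normalise_intensity, remove_skin,
                         rescale_for_render)

log = logging.getLogger(__name__)

BB_ONLY = "BB_ONLY"
ZTE_DRIVEN = "ZTE_DRIVEN"


@dataclass
class SegmentationResult:
    """Final bone mask plus the intensity-preserving render volume."""

    bone_mask: BinaryMask
    render_volume: ImageVolume
    provenance: str                      # BB_ONLY | ZTE_DRIVEN
    config: PipelineConfig
    transform: RigidTransform | None = None
    intermediates: dict = field(default_factory=dict)


@dataclass
class _Preprocessed:
    norm: ImageVolume        # denoised, bias-corrected, interior median = 1000
    head: BinaryMask
    interior: BinaryMask     # head with the skin shell eroded away
    bias: BiasField
    scale: float


def preprocess_volume(volume: ImageVolume, config: PipelineConfig) -> _Preprocessed:
    """Denoise, head-mask, normalise, N4-correct and re-normalise a volume.

    The head mask doubles as the normalisation interior; normalisation is
    repeated after N4 so that downstream thresholds (fractions of the
    soft-tissue reference) always see an interior median of exactly 1000.
    """
    den = denoise(volume, config)
    head = head_mask(den, config)
    norm, scale = normalise_intensity(den, head)
    corrected, bias = estimate_and_correct_bias(norm, head, config)
    norm, scale2 = normalise_intensity(corrected, head)
    interior = remove_skin(head, config)
    return _Preprocessed(norm=norm, head=head, interior=interior,
                         bias=bias, scale=scale * scale2)


# --------------------------------------------------------------------------- #
# classification primitives
# --------------------------------------------------------------------------- #

def zte_bone_mask(zte: ImageVolume, config: PipelineConfig,
                  head: BinaryMask | None = None) -> BinaryMask:
    """Classify bone on a preprocessed ZTE volume.

    On normalised ZTE, soft tissue sits at the reference (negative log
    intensity ~0) and air far above it; bone is the intermediate band
    ``zte_bone_low <= -ln(I/1000) <= zte_bone_high``, restricted to the head
    mask, opened and cleaned of sub-``min_component_voxels`` specks.

    ZTE's defining ability is to identify air, and that is used directly:
    voxels darker than the bone band are air (internal or background), and a
    ``zte_air_margin_mm`` shell around them is excluded from the bone class.
    This removes the one-voxel partial-volume rim that every air interface
    (sinus, oropharynx, the outer skin surface) would otherwise contribute
    to the bone band; true bone abutting an air cavity is recovered
    downstream by the search-region dilation from its fully-bony
    neighbourhood. The margin should be at least the coarsest voxel spacing
    or the rim survives along that axis.
    """
    if head is None:
        head = head_mask(zte, config)
    med = float(np.median(zte.voxels[head.voxels]))
    if abs(med - SOFT_TISSUE_REFERENCE) > 0.1 * SOFT_TISSUE_REFERENCE:
        raise PipelineError(
            f"ZTE volume is not normalised (interior median {med:.0f}, "
            f"expected {SOFT_TISSUE_REFERENCE:.0f})")
    neglog = -np.log(np.clip(zte.voxels, 1e-3, None) / SOFT_TISSUE_REFERENCE)
    bone = (neglog >= config.zte_bone_low) & (neglog <= config.zte_bone_high)
    mask = BinaryMask(bone, zte.grid) & head
    air = BinaryMask(neglog > config.zte_bone_high, zte.grid)
    if config.zte_air_margin_mm > 0 and air.count:
        air_zone = morphology(air, "dilate", config.zte_air_margin_mm)
        mask = mask & ~air_zone
    if config.zte_open_radius_mm > 0 and mask.count:
        mask = morphology(mask, "open", config.zte_open_radius_mm)
    return remove_small_components(mask, config.min_component_voxels)


def bb_bone_candidates(highres: ImageVolume, interior: BinaryMask,
                       config: PipelineConfig) -> BinaryMask:
    """Dark-voxel bone candidates on a preprocessed BB/FIESTA-C volume.

    Everything below ``bb_bone_threshold`` x soft-tissue reference inside the
    skin-removed head is a candidate. By construction this *includes internal
    air* (sinuses, oropharynx), which is indistinguishable from bone in these
    contrasts — separating them is exactly what the ZTE-driven route adds.
    """
    if interior.count == 0:
        raise PipelineError("bone candidate search requires a nonempty interior")
    thr = config.bb_bone_threshold * SOFT_TISSUE_REFERENCE
    return BinaryMask(highres.voxels < thr, highres.grid) & interior


def make_render_volume(highres: ImageVolume, bone: BinaryMask,
                       config: PipelineConfig) -> ImageVolume:
    """Intensity-preserving render volume.

    Bone is dark in BB/FIESTA-C, so intensities are inverted (``32767 - v``)
    to render bright, then multiplied by the bone mask dilated by one voxel
    (a halo keeping the cortical boundary's partial-volume shading); all
    other voxels are zeroed. Tagged DERIVED.
    """
    if not highres.grid.close_to(bone.grid):
        raise PipelineError("render volume: intensity and mask grids differ")
    halo = ndimage.binary_dilation(
        bone.voxels, ndimage.generate_binary_structure(3, 3))
    out = (RENDER_MAX - highres.voxels) * halo
    return ImageVolume(out.astype(np.float32), highres.grid, "DERIVED")


# --------------------------------------------------------------------------- #
# pipelines
# --------------------------------------------------------------------------- #

def bb_only_pipeline(bb: ImageVolume, config: PipelineConfig | None = None) -> SegmentationResult:
    """Single-contrast pipeline: preprocess, dark-voxel classification,
    component cleanup, render volume."""
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    pre = preprocess_volume(bb, config)
    cand = bb_bone_candidates(pre.norm, pre.interior, config)
    bone = remove_small_components(cand, config.min_component_voxels)
    rescaled = rescale_for_render(pre.norm, config)
    render = make_render_volume(rescaled, bone, config)
    log.info("BB-only pipeline finished in %.1f s", time.perf_counter() - t0)
    return SegmentationResult(
        bone_mask=bone, render_volume=render, provenance=BB_ONLY,
        config=config, transform=None,
        intermediates={"head": pre.head, "interior": pre.interior,
                       "candidates": cand, "normalised": pre.norm,
                       "bias": pre.bias})


def _physical_overlap_fraction(a: ImageVolume, b: ImageVolume) -> float:
    (alo, ahi), (blo, bhi) = a.grid.physical_bounds(), b.grid.physical_bounds()
    lo, hi = np.maximum(alo, blo), np.minimum(ahi, bhi)
    if np.any(hi <= lo):
        return 0.0
    inter = float(np.prod(hi - lo))
    vol = min(float(np.prod(ahi - alo)), float(np.prod(bhi - blo)))
    return inter / vol if vol > 0 else 0.0


def zte_driven_pipeline(zte: ImageVolume, highres: ImageVolume,
                        config: PipelineConfig | None = None) -> SegmentationResult:
    """ZTE-driven pipeline: the ZTE bone mask, transferred to the
    high-resolution grid and dilated by ``search_dilation_mm``, constrains
    the dark-voxel classification of the high-resolution volume."""
    config = config or PipelineConfig()
    if highres.modality not in ("BB", "FIESTA_C"):
        raise PipelineError("high-resolution input must be BB or FIESTA_C, "
                            f"got {highres.modality}")
    if _physical_overlap_fraction(zte, highres) < 0.30:
        raise PipelineError("volumes do not cover the same anatomy "
                            "(< 30% physical overlap)")
    t0 = time.perf_counter()

    zpre = preprocess_volume(zte, config)
    zmask = zte_bone_mask(zpre.norm, config, head=zpre.head)

    hpre = preprocess_volume(highres, config)

    if config.registration_enabled:
        transform = register_rigid(moving=zpre.norm, fixed=hpre.norm,
                                   seed=config.seed + 12345)
    else:
        transform = RigidTransform.identity()

    search = resample_mask(zmask, highres.grid, transform)
    if config.search_dilation_mm > 0:
        search = morphology(search, "dilate", config.search_dilation_mm)

    cand = bb_bone_candidates(hpre.norm, hpre.interior, config)
    bone = remove_small_components(cand & search, config.min_component_voxels)
    rescaled = rescale_for_render(hpre.norm, config)
    render = make_render_volume(rescaled, bone, config)
    log.info("ZTE-driven pipeline finished in %.1f s", time.perf_counter() - t0)
    return SegmentationResult(
        bone_mask=bone, render_volume=render, provenance=ZTE_DRIVEN,
        config=config, transform=transform,
        intermediates={"zte_bone": zmask, "search": search,
                       "head": hpre.head, "interior": hpre.interior,
                       "candidates": cand, "normalised": hpre.norm,
                       "bias": hpre.bias})
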