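# Methods

## The problem

Rendering the craniofacial skeleton in 3D from MRI requires separating
cortical bone from everything else, and the two practical high-resolution
contrasts make that hard in complementary ways:

* **Black-bone (BB) gradient echo** (short TE/TR, low flip angle) returns
  minimal signal from cortical bone and flattens soft-tissue contrast. Bone
  is easy to find as a signal void — but **air is also a signal void**, so a
  single-contrast segmentation cannot distinguish the frontal sinus or
  oropharynx wall from bone, and dark non-bony tissue (tendons, dense muscle
  attachments, nasal cartilage) leaks into the bone class.
* **ZTE (zero echo time)** starts its readout immediately after the RF
  pulse and therefore captures short-T2* species: air is dark, cortical
  bone carries intermediate signal, soft tissue is bright. ZTE can tell bone
  from air — but practical ZTE resolution (~1 mm, anisotropic) is too
  coarse for crisp surface rendering.

The package implements two fully automated pipelines:

1. **BB-only**: denoise → head mask → intensity normalisation → N4 bias
   correction → skin removal → dark-voxel classification → component
   cleanup → intensity-preserving render volume.
2. **ZTE-driven**: the ZTE volume is preprocessed the same way and
   classified into bone; the resulting low-resolution bone mask is
   transferred to the high-resolution grid (BB or FIESTA-C) and dilated to
   form a **search region**; high-resolution dark-voxel candidates are
   accepted as bone only inside it. ZTE decides *where* bone is; the
   high-resolution contrast decides *exactly which voxels* are bone.
   Internal air and tendon-like confounders fall outside the search region
   and are rejected.

FIESTA-C (bSSFP; fluid very bright, bone/air dark) is handled by the same
ZTE-driven pipeline, since its bone/soft separation is also a dark-voxel
problem.

## Classification model

All thresholds operate on intensities normalised so that the median of the
head interior equals a fixed reference (1000); normalisation is a pure scale
(no offset) and is repeated after N4 so the reference holds exactly.

**ZTE bone band.** With soft tissue at the reference, the negative log
intensity `-ln(I/1000)` is ~0 for soft tissue, intermediate for bone, and
large for air. Bone is the band `[zte_bone_low, zte_bone_high]` (defaults
0.15 / 1.5). Voxels darker than the band are **air** — internal or
background — and a margin of `zte_air_margin_mm` (default 2.0 mm, at least
the coarsest ZTE voxel) around them is excluded from the bone class. This
exclusion is what makes "ZTE identifies air" operational: every air/soft
interface (cavity walls, the outer skin surface) otherwise contributes a
one-voxel partial-volume rim that lands inside the bone band, and once the
search region is dilated such rims would readmit entire cavity interiors.
The mask is then restricted to the head, opened (default radius 0.5 mm,
below one voxel so thin orbital bone survives; speck removal is delegated
to the component filter), and cleaned of components below
`min_component_voxels`.

**High-resolution dark-voxel candidates.** Voxels below
`bb_bone_threshold x 1000` inside the skin-removed head. The default 0.525
is the midpoint between the dark class (bone/air, residual signal ~5% of
the soft reference) and soft tissue, so the threshold crossing coincides
with the geometric tissue boundary for partial-volume voxels. By design
this candidate set **conflates bone with internal air** — resolving that is
the ZTE-driven pipeline's job.

**Search region.** The ZTE bone mask is transferred to the high-resolution
grid by nearest-neighbour resampling (optionally through a registered rigid
transform) and dilated by `search_dilation_mm` (default 3.0 mm ≈ 2x the
ZTE slice spacing) to absorb resampling quantisation and residual
misalignment. Final bone = candidates ∩ search region, keeping all
connected components of at least `min_component_voxels` (default 100) — the
facial skeleton is not guaranteed singly connected at mask resolution, so
only the largest component is *not* kept.

**Render volume.** Segmentation to a binary mask would destroy the
end-user's ability to refine the rendering, so the output preserves
intensity: the windowed, `[0, 32767]`-rescaled volume is inverted
(`32767 - v`, making dark bone render bright) and multiplied by the bone
mask dilated by one voxel (the halo keeps cortical partial-volume shading).
Everything outside is zero.

## Preprocessing choices

* **Denoising**: curvature flow (edge-preserving) by default. The flow runs
  in index space (unit spacing): the explicit scheme's stable time step
  scales with voxel size, and the standard 0.0625 step diverges at 0.4 mm
  FIESTA-C spacing if physical spacing is used; in index space the
  smoothing extent is ~1 voxel on any grid. The default strength
  (8 iterations) is the smallest that reduces noise in a homogeneous region
  by ≥ 25% while minimising partial-volume edge reshaping at the thin
  skull shell. A Gaussian (`sigma = strength/10` mm) and `none` are
  available.
* **Head mask**: Otsu threshold (scale-invariant), morphological closing
  (2 mm), hole filling, then largest component, then a second hole fill.
  Holes are filled *before* component selection so that a dark skull shell
  cannot split scalp from brain — on BB contrast the shell thresholds as
  background while scalp and brain threshold as foreground. A foreground
  covering > 90% of the field of view is rejected ("no head found"):
  a head is always surrounded by background air.
* **N4 bias correction**: estimated at 4x shrink, 3 fitting levels,
  50 iterations each; the log field is normalised to zero mean inside the
  head (the global scale is not identifiable and belongs to intensity
  normalisation), clipped to [0.2, 5], and divided out.
* **Skin removal**: physical-space erosion of the head mask by
  `skin_thickness_mm` (default 3.0 mm — below the phantom's 5 mm scalp, so
  no calvarial bone is eroded; exposed in the config for real data).
* **Morphology** throughout uses exact Euclidean-distance-transform ball
  operations with anisotropic sampling equal to the voxel spacing, i.e. a
  2 mm radius means different voxel extents on a 0.5 x 0.5 x 1.2 mm grid —
  equivalent to a structuring-element sweep with the physical ball.
* **Registration** (`registration_enabled`, default off): Mattes mutual
  information (the inputs have different contrasts), moments
  initialisation, regular-step gradient descent over a 3-level pyramid,
  deterministic sampling for a fixed seed. If optimisation fails to improve
  the similarity the centre-of-mass initialisation is returned with a
  warning. Off by default: header geometry alone aligns the volumes when
  the subject does not move, and registration is the documented remedy for
  when they do.

## The synthetic head phantom

No public dataset pairs ZTE with BB and FIESTA-C of the same head, so
validation uses a parametric digital phantom that poses each failure mode
the pipelines target, with exact ground truth:

* an ellipsoidal head (default semi-axes 28 x 35 x 31 mm, a ~40%-scale
  adult) with a 5 mm scalp layer and a closed 2.5 mm skull shell,
  optionally thinned to 1 mm at the orbit and vertex (sub-voxel at BB
  slice spacing);
* internal air cavities: a frontal sinus reaching into the skull's inner
  table (the air/bone interface) and an oropharynx deep in soft tissue;
* tendon/muscle confounders near the mandible and nose that are dark-ish
  in BB/FIESTA-C (near the bone threshold) but soft-tissue-bright in ZTE;
* per-modality intensities (soft = 1000): BB air/bone 50, ZTE bone 500,
  FIESTA-C fluid 2000 — the ZTE bone/soft ratio is a modelling choice, not
  a measured value, and is recorded in the phantom sidecar;
* a smooth multiplicative bias field, log-linear along one axis (default
  peak amplitude 0.2);
* Rician noise (magnitude of complex Gaussian, default sigma 50 = SNR 20
  against soft tissue), added on each acquisition grid *after* resampling
  so the measured noise level matches the configured one;
* acquisition grids with the clinical voxel spacings — ZTE
  0.9 x 0.9 x 1.6 mm, BB 0.5 x 0.5 x 1.2 mm, FIESTA-C 0.4 x 0.4 x 0.7 mm —
  over the phantom's field of view; matrix sizes therefore scale with the
  head (~136 x 164 x 62 for BB) rather than full clinical matrices, keeping
  a full two-pipeline validation under a minute on one CPU while preserving
  the resolution ratios the method's mechanism depends on;
* an optional rigid inter-acquisition motion applied to the ZTE volume
  (named spec "moved": 2 mm translation, ~1 degree rotation).

Labels are rasterised once on a 0.4 mm isotropic master grid (the finest
acquisition spacing, so no modality grid is under-resolved), and per-grid
truth masks are nearest-resampled from it. Generation is bit-identical for
a fixed spec and seed.

**What the phantom does not emulate**: real cranial geometry (sutures,
trabecular bone, marrow), k-space/sequence physics, motion artefacts other
than a single rigid displacement, spatially varying noise, and teeth —
passing tests show the pipelines' *mechanisms* work (air/bone separation,
confounder rejection, resolution inheritance, recovery of simulated bias
and motion), not that the defaults are clinically tuned.

## Numerical conventions and degenerate inputs

* Voxel indices are 0-based; world coordinates are LPS millimetres (DICOM).
* Intensities resample linearly, masks/labels nearest-neighbour.
* Dice of two empty masks is 1.0; the largest-component tie-break keeps the
  component whose first voxel has the lowest linear (C-order) index.
* A morphology radius below half the smallest voxel spacing is the
  identity (with a warning); erosion that annihilates the head mask, empty
  threshold results, non-positive normalisation medians, degenerate render
  windows, and < 30% physical overlap between paired volumes are hard
  errors.
* DICOM export writes 16-bit secondary-capture slices (modality "OT", so
  derived data never masquerades as an acquired MR series) with
  slope/intercept chosen to map the maximum to 32767; orientation metadata
  is never invented — a series without it is rejected.

## Known, deliberately reproduced limitations

* **Residual air rim**: internal air inside the dilated search region —
  where a sinus abuts bone — remains labelled bone. Sinus and oropharynx
  air are not specifically targeted; a characterisation test asserts the
  residual layer exists rather than hiding it.
* **Teeth/occlusal leakage** is not specially handled.
* The BB-only pipeline's air/bone conflation is asserted as designed
  behaviour (its false-positive rate on internal air is *expected* to be
  high); it exists as the baseline the ZTE-driven pipeline improves on.

## Problem sizes used in tests and the acceptance script

Full-scale runs use the default phantom (BB grid ~1.4M voxels, FIESTA-C
~3.7M); stage-level property tests use a reduced phantom (half-size head,
0.8 mm master grid) where only geometry matters. The acceptance script
regenerates every study condition at the given seed and recomputes all
reported quantities end to end; nothing is cached or hard-coded.
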