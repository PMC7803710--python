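"""Parametric digital head phantom with paired multi-contrast volumes and
ground truth.

The phantom is an ellipsoidal head with, from the outside in: a scalp/skin
layer, a closed skull shell of variable thickness (optionally thinned at the
orbit and vertex), and interior soft tissue. Internal air cavities (frontal
sinus abutting the skull's inner table, oropharynx), tendon/muscle confounder
structures and an optional bright-fluid cavity can be embedded. Labels are
rasterised once on an isotropic master grid; per-modality intensity volumes
are built from them, multiplied by a smooth log-linear bias field, resampled
to each acquisition grid (voxel spacings default to clinical ZTE / black-bone
/ FIESTA-C protocols) and corrupted with Rician noise. The ZTE acquisition
may additionally be displaced by a rigid inter-acquisition motion.

Per-modality contrast model (arbitrary units, soft tissue = 1000):

========== ======= ====== ====== ====== ========== =======
modality    bg air  bone   soft   skin  internal air fluid
========== ======= ====== ====== ====== ========== =======
BB             50     50   1000   1000       50       1000
ZTE            50    500   1000   1000       50       1000
FIESTA-C       50     50   1000   1000       50       2000
========== ======= ====== ====== ====== ========== =======

Bone and air are indistinguishable in BB and FIESTA-C (the single-contrast
failure mode); ZTE separates them. Tendon confounders are dark-ish in BB /
FIESTA-C (near the bone threshold) but soft-tissue-bright in ZTE, so the
ZTE-driven pipeline can reject them.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (BinaryMask, Grid, ImageVolume, RigidTransform, resample,
                   resample_mask)
from .preprocess import BiasField

log = logging.getLogger(__name__)

# label codes on the master grid
BACKGROUND, SKIN, SOFT, BONE, AIR_INTERNAL, CONFOUNDER, FLUID = range(7)

#: Clinical acquisition voxel spacings (mm) per modality.
DEFAULT_SPACINGS = {
    "zte": (0.9, 0.9, 1.6),
    "bb": (0.5, 0.5, 1.2),
    "fiesta": (0.4, 0.4, 0.7),
}

MODALITY_TAGS = {"zte": "ZTE", "bb": "BB", "fiesta": "FIESTA_C"}

_DEFAULT_INTENSITIES = {
    #            bg air  bone   soft   fluid
    "zte":    {"air": 50.0, "bone": 500.0, "soft": 1000.0, "fluid": 1000.0},
    "bb":     {"air": 50.0, "bone": 50.0, "soft": 1000.0, "fluid": 1000.0},
    "fiesta": {"air": 50.0, "bone": 50.0, "soft": 1000.0, "fluid": 2000.0},
}

_DEFAULT_CONFOUNDER_INTENSITY = {"zte": 1000.0, "bb": 250.0, "fiesta": 250.0}


class PhantomValidationError(ValueError):
    """Raised when a PhantomSpec violates its invariants; lists each breach."""


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid structure, positions/sizes in mm."""

    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]
    name: str = ""
    #: per-modality intensity, used for confounder structures only
    intensity: dict = field(default_factory=dict)

    def inside(self, x, y, z):
        cx, cy, cz = self.center_mm
        ax, ay, az = self.semiaxes_mm
        return (((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2
                + ((z - cz) / az) ** 2) <= 1.0


@dataclass(frozen=True)
class ThinPatch:
    """Angular patch of reduced skull thickness around a direction."""

    direction: tuple[float, float, float]
    half_angle_deg: float
    thickness_mm: float
    name: str = ""


@dataclass
class PhantomSpec:
    """Full parameterisation of the synthetic head (sizes in mm)."""

    head_semiaxes_mm: tuple[float, float, float] = (28.0, 35.0, 31.0)
    scalp_thickness_mm: float = 5.0
    skull_thickness_mm: float = 2.5
    thin_patches: tuple[ThinPatch, ...] = ()
    air_cavities: tuple[Ellipsoid, ...] = ()
    confounders: tuple[Ellipsoid, ...] = ()
    fluid_cavities: tuple[Ellipsoid, ...] = ()
    intensities: dict = field(default_factory=lambda: {
        m: dict(v) for m, v in _DEFAULT_INTENSITIES.items()})
    noise_sigma: float = 50.0
    bias_amplitude: float = 0.2          # peak log-amplitude of the bias field
    bias_axis: int = 2
    motion: RigidTransform = field(default_factory=RigidTransform.identity)
    grids: dict | None = None            # modality -> Grid; default from spacings
    master_spacing_mm: float = 0.4
    margin_mm: float = 6.0
    seed: int = 0
    name: str = "custom"

    # ------------------------------------------------------------------ #

    def fov_mm(self) -> np.ndarray:
        return 2 * (np.asarray(self.head_semiaxes_mm) + self.margin_mm)

    def _grid_for_spacing(self, spacing) -> Grid:
        spacing = np.asarray(spacing, dtype=float)
        shape = np.ceil(self.fov_mm() / spacing).astype(int)
        origin = -(shape - 1) * spacing / 2.0
        return Grid(shape=tuple(shape), spacing=tuple(spacing),
                    origin=tuple(origin))

    def master_grid(self) -> Grid:
        return self._grid_for_spacing([self.master_spacing_mm] * 3)

    def modality_grids(self) -> dict[str, Grid]:
        if self.grids is not None:
            return dict(self.grids)
        return {m: self._grid_for_spacing(s) for m, s in DEFAULT_SPACINGS.items()}

    def validate(self) -> None:
        breaches = []
        a = np.asarray(self.head_semiaxes_mm, dtype=float)
        if np.any(a <= 0):
            breaches.append(f"head semi-axes must be positive, got {tuple(a)}")
        if self.scalp_thickness_mm <= 0 or self.skull_thickness_mm <= 0:
            breaches.append("scalp and skull thickness must be positive")
        if self.scalp_thickness_mm + self.skull_thickness_mm >= min(a):
            breaches.append("scalp + skull thickness exceeds the smallest head semi-axis")
        inner = a - self.scalp_thickness_mm
        for kind, items in (("air cavity", self.air_cavities),
                            ("confounder", self.confounders),
                            ("fluid cavity", self.fluid_cavities)):
            for e in items:
                c = np.asarray(e.center_mm)
                s = np.asarray(e.semiaxes_mm)
                if np.any(s <= 0):
                    breaches.append(f"{kind} {e.name!r}: non-positive semi-axes")
                    continue
                # every axis-extreme point must stay strictly inside the head
                pts = c + np.vstack([np.diag(s), -np.diag(s)])
                q = ((pts / a) ** 2).sum(axis=1)
                if np.any(q >= 1.0):
                    breaches.append(f"{kind} {e.name!r} is not strictly inside the head")
                if kind != "air cavity":
                    q_in = ((pts / inner) ** 2).sum(axis=1)
                    if np.any(q_in >= 1.0):
                        breaches.append(f"{kind} {e.name!r} reaches into the skull/scalp")
        if self.noise_sigma < 0:
            breaches.append("noise_sigma must be >= 0")
        if self.master_spacing_mm <= 0:
            breaches.append("master_spacing_mm must be positive")
        if breaches:
            raise PhantomValidationError("; ".join(breaches))

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "head_semiaxes_mm": list(self.head_semiaxes_mm),
            "scalp_thickness_mm": self.scalp_thickness_mm,
            "skull_thickness_mm": self.skull_thickness_mm,
            "thin_patches": [dataclasses.asdict(p) for p in self.thin_patches],
            "air_cavities": [dataclasses.asdict(e) for e in self.air_cavities],
            "confounders": [dataclasses.asdict(e) for e in self.confounders],
            "fluid_cavities": [dataclasses.asdict(e) for e in self.fluid_cavities],
            "intensities": {m: dict(v) for m, v in self.intensities.items()},
            "noise_sigma": self.noise_sigma,
            "bias_amplitude": self.bias_amplitude,
            "bias_axis": self.bias_axis,
            "motion": {"rotation_deg": list(self.motion.rotation_deg),
                       "translation_mm": list(self.motion.translation_mm),
                       "center_mm": list(self.motion.center_mm)},
            "master_spacing_mm": self.master_spacing_mm,
            "margin_mm": self.margin_mm,
            "seed": self.seed,
        }
        if self.grids is not None:
            d["grids"] = {m: {"shape": list(g.shape), "spacing": list(g.spacing),
                              "origin": list(g.origin)}
                          for m, g in self.grids.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["head_semiaxes_mm"] = tuple(d.get("head_semiaxes_mm", (28.0, 35.0, 31.0)))
        d["thin_patches"] = tuple(
            ThinPatch(direction=tuple(p["direction"]),
                      half_angle_deg=p["half_angle_deg"],
                      thickness_mm=p["thickness_mm"], name=p.get("name", ""))
            for p in d.get("thin_patches", ()))
        for key in ("air_cavities", "confounders", "fluid_cavities"):
            d[key] = tuple(
                Ellipsoid(center_mm=tuple(e["center_mm"]),
                          semiaxes_mm=tuple(e["semiaxes_mm"]),
                          name=e.get("name", ""),
                          intensity=dict(e.get("intensity", {})))
                for e in d.get(key, ()))
        if "motion" in d:
            mo = d["motion"]
            d["motion"] = RigidTransform(rotation_deg=tuple(mo["rotation_deg"]),
                                         translation_mm=tuple(mo["translation_mm"]),
                                         center_mm=tuple(mo.get("center_mm", (0, 0, 0))))
        if d.get("grids"):
            d["grids"] = {m: Grid(shape=tuple(g["shape"]),
                                  spacing=tuple(g["spacing"]),
                                  origin=tuple(g["origin"]))
                          for m, g in d["grids"].items()}
        return cls(**d)


@dataclass
class PhantomSet:
    """Generated paired volumes with ground truth on every modality grid."""

    spec: PhantomSpec
    volumes: dict                       # modality -> ImageVolume
    truths: dict                        # modality -> {name -> BinaryMask}
    applied_bias: dict                  # modality -> BiasField
    applied_motion: RigidTransform

    @property
    def zte(self) -> ImageVolume:
        return self.volumes["zte"]

    @property
    def bb(self) -> ImageVolume:
        return self.volumes["bb"]

    @property
    def fiesta(self) -> ImageVolume:
        return self.volumes["fiesta"]

    def truth(self, modality: str, name: str) -> BinaryMask:
        return self.truths[modality][name]


# --------------------------------------------------------------------------- #
# rasterisation
# --------------------------------------------------------------------------- #

def _coordinate_axes(grid: Grid):
    xs = [o + np.arange(n, dtype=np.float32) * s
          for o, n, s in zip(grid.origin, grid.shape, grid.spacing)]
    return (xs[0][:, None, None], xs[1][None, :, None], xs[2][None, None, :])


def rasterise_labels(spec: PhantomSpec) -> tuple[np.ndarray, Grid]:
    """Rasterise the anatomical label volume on the isotropic master grid."""
    grid = spec.master_grid()
    x, y, z = _coordinate_axes(grid)
    a = np.asarray(spec.head_semiaxes_mm, dtype=np.float32)

    labels = np.zeros(grid.shape, dtype=np.uint8)
    q_head = (x / a[0]) ** 2 + (y / a[1]) ** 2 + (z / a[2]) ** 2
    head = q_head <= 1.0
    labels[head] = SKIN

    outer = a - spec.scalp_thickness_mm
    qo = (x / outer[0]) ** 2 + (y / outer[1]) ** 2 + (z / outer[2]) ** 2
    inside_outer = qo <= 1.0
    labels[inside_outer] = SOFT

    # depth below the outer skull surface, via the ellipsoid implicit function:
    # depth ~ (1 - r) / |grad r| with r = sqrt(qo), |grad r| = |grad qo| / (2 r)
    grad2 = ((x / outer[0] ** 2) ** 2 + (y / outer[1] ** 2) ** 2
             + (z / outer[2] ** 2) ** 2)
    r = np.sqrt(np.maximum(qo, 1e-12))
    depth = (1.0 - r) * r / np.sqrt(np.maximum(grad2, 1e-12))

    thickness = np.full(grid.shape, np.float32(spec.skull_thickness_mm))
    if spec.thin_patches:
        norm = np.sqrt(np.maximum(x ** 2 + y ** 2 + z ** 2, 1e-12))
        for patch in spec.thin_patches:
            d = np.asarray(patch.direction, dtype=np.float32)
            d = d / np.linalg.norm(d)
            cosang = (x * d[0] + y * d[1] + z * d[2]) / norm
            sel = cosang >= np.cos(np.deg2rad(patch.half_angle_deg))
            thickness[sel] = patch.thickness_mm
    # the surface-linearised depth is only meaningful near the shell; guard
    # r >= 0.5 so the degenerate gradient at the centre cannot mislabel it
    labels[inside_outer & (r >= 0.5) & (depth <= thickness)] = BONE

    for cav in spec.air_cavities:
        labels[cav.inside(x, y, z) & (labels == SOFT)] = AIR_INTERNAL
    for conf in spec.confounders:
        labels[conf.inside(x, y, z) & (labels == SOFT)] = CONFOUNDER
    for fl in spec.fluid_cavities:
        labels[fl.inside(x, y, z) & (labels == SOFT)] = FLUID
    return labels, grid


def _intensity_volume(labels: np.ndarray, grid: Grid, spec: PhantomSpec,
                      modality: str) -> np.ndarray:
    lev = spec.intensities[modality]
    lut = np.array([lev["air"],           # background
                    lev["soft"],          # skin
                    lev["soft"],          # soft tissue
                    lev["bone"],          # bone
                    lev["air"],           # internal air
                    lev["soft"],          # confounder placeholder, set below
                    lev["fluid"]], dtype=np.float32)
    vol = lut[labels]
    if spec.confounders:
        x, y, z = _coordinate_axes(grid)
        for conf in spec.confounders:
            val = conf.intensity.get(modality,
                                     _DEFAULT_CONFOUNDER_INTENSITY[modality])
            vol[conf.inside(x, y, z) & (labels == CONFOUNDER)] = val
    return vol


def _bias_field_values(grid: Grid, spec: PhantomSpec) -> np.ndarray:
    if spec.bias_amplitude == 0:
        return np.ones(grid.shape, dtype=np.float32)
    axes = _coordinate_axes(grid)
    u = axes[spec.bias_axis] / float(spec.head_semiaxes_mm[spec.bias_axis])
    u = np.clip(u, -1.5, 1.5)
    field = np.exp(np.float32(spec.bias_amplitude) * u)
    return np.broadcast_to(field, grid.shape).astype(np.float32)


_TRUTH_FROM_LABEL = {
    "bone": (BONE,),
    "air_internal": (AIR_INTERNAL,),
    "head": (SKIN, SOFT, BONE, AIR_INTERNAL, CONFOUNDER, FLUID),
    "skin": (SKIN,),
    "confounders": (CONFOUNDER,),
}


def generate_phantom(spec: PhantomSpec,
                     modalities: tuple[str, ...] | None = None) -> PhantomSet:
    """Generate the paired volumes and ground truth for ``spec``.

    ``modalities`` restricts generation (e.g. ``("bb",)``) — handy when only
    one contrast is needed; defaults to every grid the spec defines.
    Regeneration with the same spec and seed is bit-identical.
    """
    spec.validate()
    labels, master = rasterise_labels(spec)
    grids = spec.modality_grids()
    if modalities is not None:
        grids = {m: grids[m] for m in modalities}

    label_vol = ImageVolume(labels.astype(np.float32), master, "DERIVED")
    bias_master = _bias_field_values(master, spec)

    mod_ids = {"zte": 1, "bb": 2, "fiesta": 3}
    volumes, truths, biases = {}, {}, {}
    for modality, grid in grids.items():
        transform = spec.motion if (modality == "zte"
                                    and not spec.motion.is_identity) else None
        intensity = _intensity_volume(labels, master, spec, modality) * bias_master
        vol = resample(ImageVolume(intensity, master, "DERIVED"), grid,
                       transform, interpolation="linear",
                       fill=float(spec.intensities[modality]["air"]))
        if spec.noise_sigma > 0:
            rng = np.random.default_rng([spec.seed, mod_ids.get(modality, 9)])
            sigma = np.float32(spec.noise_sigma)
            real = vol.voxels + rng.normal(0.0, sigma, vol.voxels.shape).astype(np.float32)
            imag = rng.normal(0.0, sigma, vol.voxels.shape).astype(np.float32)
            vox = np.sqrt(real ** 2 + imag ** 2).astype(np.float32)
        else:
            vox = vol.voxels.astype(np.float32)
        volumes[modality] = ImageVolume(vox, grid, MODALITY_TAGS.get(modality, "DERIVED"))

        with warnings.catch_warnings():
            # label volumes are legitimately nearest-interpolated
            warnings.simplefilter("ignore")
            lab = resample(label_vol, grid, transform, interpolation="nearest",
                           fill=float(BACKGROUND))
        lab_arr = np.rint(lab.voxels).astype(np.uint8)
        truths[modality] = {
            name: BinaryMask(np.isin(lab_arr, codes), grid)
            for name, codes in _TRUTH_FROM_LABEL.items()}

        bias_vol = resample(ImageVolume(bias_master, master, "DERIVED"), grid,
                            transform, interpolation="linear", fill=1.0)
        biases[modality] = BiasField(np.clip(bias_vol.voxels, 1e-3, None), grid)

    return PhantomSet(spec=spec, volumes=volumes, truths=truths,
                      applied_bias=biases, applied_motion=spec.motion)


# --------------------------------------------------------------------------- #
# named study conditions
# --------------------------------------------------------------------------- #

def _sinus_cavities() -> tuple[Ellipsoid, ...]:
    return (
        # reaches into the skull's inner table so the cavity abuts bone
        Ellipsoid(center_mm=(0.0, 23.0, 4.0), semiaxes_mm=(5.0, 4.5, 4.0),
                  name="frontal_sinus"),
        Ellipsoid(center_mm=(0.0, 2.0, -10.0), semiaxes_mm=(8.0, 6.0, 7.0),
                  name="oropharynx"),
    )


def _tendon_confounders() -> tuple[Ellipsoid, ...]:
    return (
        Ellipsoid(center_mm=(8.0, 6.0, -9.0), semiaxes_mm=(5.0, 2.5, 2.5),
                  name="masseter_tendon"),
        Ellipsoid(center_mm=(0.0, 18.5, -5.0), semiaxes_mm=(3.0, 3.5, 2.5),
                  name="nasal_cartilage"),
    )


def default_specs() -> dict[str, PhantomSpec]:
    """Named study conditions covering every mechanism the pipelines target.

    * ``clean`` — noiseless, bias-free, no cavities/confounders: isolates
      geometry and resolution effects.
    * ``sinus`` — frontal sinus abutting the inner table plus an oropharynx:
      the air/bone-interface failure mode of single-contrast segmentation.
    * ``tendon`` — dark muscular/cartilaginous confounders near the mandible
      and nose.
    * ``thin_bone`` — orbital/vertex skull patches thinned to 1 mm
      (sub-voxel at black-bone z-spacing).
    * ``moved`` — 2 mm / 1 degree rigid motion between the ZTE and
      high-resolution acquisitions.
    """
    specs = {
        "clean": PhantomSpec(name="clean", noise_sigma=0.0, bias_amplitude=0.0),
        "sinus": PhantomSpec(name="sinus", air_cavities=_sinus_cavities()),
        "tendon": PhantomSpec(name="tendon", confounders=_tendon_confounders()),
        "thin_bone": PhantomSpec(
            name="thin_bone",
            thin_patches=(
                ThinPatch(direction=(0.0, 0.0, 1.0), half_angle_deg=20.0,
                          thickness_mm=1.0, name="vertex"),
                ThinPatch(direction=(0.0, 0.8, 0.4), half_angle_deg=14.0,
                          thickness_mm=1.0, name="orbit"),
            )),
        "moved": PhantomSpec(
            name="moved", air_cavities=_sinus_cavities(),
            motion=RigidTransform(rotation_deg=(0.7, -0.5, 0.4),
                                  translation_mm=(1.5, -1.0, 0.8))),
    }
    return specs
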