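"""Synthetic CT phantoms of a talus-like bone with known ground truth.

No patient scans ship with this package; instead this module generates
stylised tarsocrural phantoms that reproduce the features the downstream
densitometry pipeline measures:

* a bone made of two parallel half-capsule ridges (standing in for the medial
  and lateral trochlear ridges) on a block base, wrapped in a thin
  high-density subchondral plate shell over a lower-density trabecular
  interior;
* two physiological density peaks on the articular surface — one on the
  proximal part of the medial ridge, one on the distal part of the lateral
  ridge — modelled as Gaussian bumps added to the plate density;
* an optional osteochondrosis-like lesion on the medial ridge: a low-density
  spherical core surrounded by a sclerotic high-density rim;
* a globally denser contralateral joint (bilateral asymmetry);
* cylindrical calibration inserts of known mineral density embedded in the
  soft-tissue background, mimicking a quantitative-CT reference phantom;
* additive Gaussian HU noise.

Mineral densities are specified in mg hydroxyapatite per cm^3 (mg HA/cm^3)
and converted to Hounsfield Units through an affine map ``density = slope *
HU + intercept`` whose true parameters are recorded in the ground truth, so
calibration recovery can be verified exactly.

Anatomy is deliberately stylised: the downstream operators (thresholding,
ray casting, projection, quantization) are shape-agnostic, so fidelity to
real talar geometry buys nothing for validating them.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .volume import CTVolume, FormatError, read_volume, write_volume  # noqa: F401  (re-exported)

# ---------------------------------------------------------------------------
# study-condition constants (cohort Results the generator is calibrated to)
# ---------------------------------------------------------------------------

#: mean +/- SD lesion-core mineral density over affected joints, mg HA/cm^3
LESION_CORE_DENSITY = 612.6
LESION_CORE_BETWEEN_DOG_SD = 88.4
#: mean +/- SD trochlear-ridge plate density of the contralateral normal joint
CONTRALATERAL_PLATE_DENSITY = 780.7
CONTRALATERAL_PLATE_BETWEEN_DOG_SD = 39.8
#: default bilateral offset: the contralateral joint is globally denser
DEFAULT_CONTRALATERAL_OFFSET = 60.0
#: affected-joint plate base = contralateral minus the bilateral offset
AFFECTED_PLATE_DENSITY = CONTRALATERAL_PLATE_DENSITY - DEFAULT_CONTRALATERAL_OFFSET
#: number of dogs in the study cohort
COHORT_N_DOGS = 8

LABELS = {
    "background": 0,
    "trabecular": 1,
    "plate": 2,
    "lesion_core": 3,
    "lesion_rim": 4,
}
INSERT_LABEL_BASE = 10  # insert k gets label INSERT_LABEL_BASE + k


class PhantomConfigError(ValueError):
    """A phantom configuration violates its invariants."""


class GeometryError(ValueError):
    """Requested geometry is inconsistent (e.g. lesion off the ridge surface)."""


class CohortError(ValueError):
    """A cohort request is degenerate (e.g. fewer than 2 dogs)."""


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RidgeGeometry:
    """Two parallel half-capsule ridges on a block base.

    Ridge axes run dorsoplantar (y); each ridge is the upper half of a capsule
    (cylinder with a spherical cap at the dorsal end) of the given radius,
    sitting on the base block.  Separation is centre-to-centre mediolaterally.
    """

    radius_mm: float = 6.0
    separation_mm: float = 14.0
    length_mm: float = 24.0
    base_height_mm: float = 6.0
    base_z_mm: float = 8.0  # bottom of the base block; inserts live below

    def validate(self) -> None:
        for name in ("radius_mm", "separation_mm", "length_mm", "base_height_mm"):
            if getattr(self, name) <= 0:
                raise PhantomConfigError(f"ridge_geometry.{name} must be > 0")
        if self.separation_mm < self.radius_mm:
            raise PhantomConfigError("ridge separation must be >= ridge radius")


@dataclass(frozen=True)
class PeakSpec:
    """A physiological density peak: a Gaussian bump added to plate density.

    ``along_frac`` positions the peak centre along the ridge axis as a
    fraction of ridge length (0 = plantar/proximal end, 1 = dorsal end).
    """

    ridge: str  # "medial" | "lateral"
    along_frac: float
    amplitude: float = 200.0  # mg HA/cm^3 at the peak centre
    sigma_mm: float = 2.0

    def validate(self) -> None:
        if self.ridge not in ("medial", "lateral"):
            raise PhantomConfigError(f"peak ridge must be medial/lateral, got {self.ridge!r}")
        if not 0.0 <= self.along_frac <= 1.0:
            raise PhantomConfigError("peak along_frac must be in [0, 1]")
        if self.amplitude < 0 or self.sigma_mm <= 0:
            raise PhantomConfigError("peak amplitude must be >= 0 and sigma > 0")


@dataclass(frozen=True)
class LesionSpec:
    """Osteochondrosis-like focal defect on the medial ridge surface.

    A spherical low-density core centred on the articular surface, surrounded
    by a concentric sclerotic rim (rim density > core density).  The centre is
    derived from ``along_frac`` on the medial ridge apex; an explicit
    ``center_mm`` may be given instead and is validated to lie on the medial
    ridge surface.
    """

    along_frac: float = 0.3
    core_radius_mm: float = 4.0
    core_density: float = LESION_CORE_DENSITY
    rim_width_mm: float = 2.0
    rim_density: float = 1000.0
    center_mm: Optional[tuple[float, float, float]] = None

    def validate(self) -> None:
        if self.core_radius_mm <= 0 or self.rim_width_mm <= 0:
            raise PhantomConfigError("lesion core radius and rim width must be > 0")
        if self.core_density < 0:
            raise PhantomConfigError("lesion core density must be >= 0")
        if self.rim_density <= self.core_density:
            raise PhantomConfigError("lesion rim density must exceed core density")
        if not 0.0 <= self.along_frac <= 1.0:
            raise PhantomConfigError("lesion along_frac must be in [0, 1]")


@dataclass(frozen=True)
class InsertSpec:
    """A cylindrical calibration insert of known mineral density.

    The cylinder axis runs dorsoplantar (y); ``center_mm`` is the cylinder
    centre in volume mm coordinates.
    """

    density: float  # known mg HA/cm^3
    center_mm: tuple[float, float, float]
    radius_mm: float = 2.5
    height_mm: float = 10.0

    def validate(self) -> None:
        if self.density < 0:
            raise PhantomConfigError("insert density must be >= 0")
        if self.radius_mm <= 0 or self.height_mm <= 0:
            raise PhantomConfigError("insert radius and height must be > 0")


def default_peaks() -> tuple[PeakSpec, PeakSpec]:
    """Proximal-medial and distal-lateral physiological density peaks."""
    return (PeakSpec("medial", 0.3), PeakSpec("lateral", 0.8))


def default_inserts() -> tuple[InsertSpec, ...]:
    """Three-insert reference phantom: 0, 400 and 800 mg HA/cm^3."""
    return (
        InsertSpec(0.0, (8.0, 16.0, 3.5)),
        InsertSpec(400.0, (16.0, 16.0, 3.5)),
        InsertSpec(800.0, (24.0, 16.0, 3.5)),
    )


@dataclass(frozen=True)
class PhantomConfig:
    """Full specification of one synthetic joint volume."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)
    ridge_geometry: RidgeGeometry = field(default_factory=RidgeGeometry)
    plate_thickness_mm: float = 2.0
    plate_base_density: float = CONTRALATERAL_PLATE_DENSITY
    peaks: tuple[PeakSpec, ...] = field(default_factory=default_peaks)
    trabecular_density: float = 400.0
    background_hu: float = 40.0
    lesion: Optional[LesionSpec] = None
    inserts: tuple[InsertSpec, ...] = field(default_factory=default_inserts)
    noise_sd_hu: float = 15.0
    true_calibration: tuple[float, float] = (1.0, 0.0)  # density = slope*HU + intercept
    seed: int = 0

    def validate(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise PhantomConfigError(f"shape must be 3 positive ints, got {self.shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise PhantomConfigError(f"spacing_mm must be 3 positive floats, got {self.spacing_mm}")
        if self.plate_thickness_mm <= 0:
            raise PhantomConfigError("plate_thickness_mm must be > 0")
        for name in ("plate_base_density", "trabecular_density"):
            if getattr(self, name) < 0:
                raise PhantomConfigError(f"{name} must be >= 0")
        if self.noise_sd_hu < 0:
            raise PhantomConfigError("noise_sd_hu must be >= 0")
        slope, _ = self.true_calibration
        if slope <= 0:
            raise PhantomConfigError("true_calibration slope must be > 0")
        self.ridge_geometry.validate()
        for p in self.peaks:
            p.validate()
        if self.lesion is not None:
            self.lesion.validate()
        for ins in self.inserts:
            ins.validate()
        if len({ins.density for ins in self.inserts}) < 2:
            raise PhantomConfigError("insert_spec must contain >= 2 distinct densities")


@dataclass
class GroundTruth:
    """Per-voxel labels and generative scalars for one phantom volume."""

    label_volume: np.ndarray  # uint8, same shape as the HU volume
    true_plate_mean_density: float
    true_lesion_mean_density: Optional[float]
    true_calibration: tuple[float, float]
    insert_densities: tuple[float, ...] = ()

    def label_mask(self, name: str) -> np.ndarray:
        return self.label_volume == LABELS[name]


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _grids(config: PhantomConfig):
    """Voxel-centre mm coordinate grids (open/broadcast form)."""
    xs = (np.arange(config.shape[0]) + 0.5) * config.spacing_mm[0]
    ys = (np.arange(config.shape[1]) + 0.5) * config.spacing_mm[1]
    zs = (np.arange(config.shape[2]) + 0.5) * config.spacing_mm[2]
    return np.meshgrid(xs, ys, zs, indexing="ij", sparse=True)


def _ridge_axes(config: PhantomConfig):
    """Return (x_medial, x_lateral, y0, y_cap, z_top) of the ridge axes in mm.

    The medial ridge sits at smaller x.  Ridge axis segments run from y0
    (proximal/plantar flat end) to y_cap; the spherical cap closes the dorsal
    end so the full ridge length is length_mm.
    """
    g = config.ridge_geometry
    extent_x = config.shape[0] * config.spacing_mm[0]
    extent_y = config.shape[1] * config.spacing_mm[1]
    cx = extent_x / 2.0
    x_med = cx - g.separation_mm / 2.0
    x_lat = cx + g.separation_mm / 2.0
    y0 = (extent_y - g.length_mm) / 2.0
    y_cap = y0 + g.length_mm - g.radius_mm
    z_top = g.base_z_mm + g.base_height_mm
    return x_med, x_lat, y0, y_cap, z_top


def _half_capsule_mask(config: PhantomConfig, x_axis: float) -> np.ndarray:
    """Upper half of a capsule around the ridge axis segment at x = x_axis."""
    g = config.ridge_geometry
    X, Y, Z = _grids(config)
    _, _, y0, y_cap, z_top = _ridge_axes(config)
    yc = np.clip(Y, y0, y_cap)  # nearest point on the axis segment
    d2 = (X - x_axis) ** 2 + (Y - yc) ** 2 + (Z - z_top) ** 2
    return (d2 <= g.radius_mm ** 2) & (Z >= z_top) & (Y >= y0)


def _surface_point(config: PhantomConfig, ridge: str, along_frac: float):
    """mm coordinates of a point on a ridge's articular (apex) surface."""
    g = config.ridge_geometry
    x_med, x_lat, y0, y_cap, z_top = _ridge_axes(config)
    x = x_med if ridge == "medial" else x_lat
    y = y0 + along_frac * g.length_mm
    if y <= y_cap:
        z = z_top + g.radius_mm
    else:  # on the dorsal spherical cap
        dy = y - y_cap
        if dy > g.radius_mm:
            raise GeometryError("point beyond the dorsal end of the ridge")
        z = z_top + float(np.sqrt(g.radius_mm ** 2 - dy ** 2))
    return (x, y, z)


def _lesion_center(config: PhantomConfig) -> tuple[float, float, float]:
    lesion = config.lesion
    assert lesion is not None
    if lesion.center_mm is None:
        return _surface_point(config, "medial", lesion.along_frac)
    # explicit centre: must lie on the medial ridge surface (within a voxel)
    g = config.ridge_geometry
    x_med, _, y0, y_cap, z_top = _ridge_axes(config)
    x, y, z = lesion.center_mm
    yc = min(max(y, y0), y_cap)
    dist_to_axis = float(np.sqrt((x - x_med) ** 2 + (y - yc) ** 2 + (z - z_top) ** 2))
    tol = max(config.spacing_mm)
    if not (abs(dist_to_axis - g.radius_mm) <= tol and z >= z_top and y >= y0):
        raise GeometryError(
            f"lesion center {lesion.center_mm} is not on the medial ridge surface "
            f"(distance to ridge axis {dist_to_axis:.2f} mm, radius {g.radius_mm} mm)")
    return (x, y, z)


def _insert_mask(config_shape, spacing, insert: InsertSpec) -> np.ndarray:
    xs = (np.arange(config_shape[0]) + 0.5) * spacing[0]
    ys = (np.arange(config_shape[1]) + 0.5) * spacing[1]
    zs = (np.arange(config_shape[2]) + 0.5) * spacing[2]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij", sparse=True)
    cx, cy, cz = insert.center_mm
    radial = (X - cx) ** 2 + (Z - cz) ** 2 <= insert.radius_mm ** 2
    axial = np.abs(Y - cy) <= insert.height_mm / 2.0
    return radial & axial


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_volume(config: PhantomConfig) -> tuple[CTVolume, GroundTruth]:
    """Generate one phantom CT volume and its voxel-exact ground truth.

    The noiseless HU field is the exact affine inverse of the mineral-density
    field under ``config.true_calibration``; Gaussian noise of
    ``config.noise_sd_hu`` HU is then added.  Deterministic given
    ``config.seed``.
    """
    from scipy import ndimage

    config.validate()
    spacing = config.spacing_mm
    g = config.ridge_geometry

    x_med, x_lat, _, _, z_top = _ridge_axes(config)
    extent = tuple(n * s for n, s in zip(config.shape, spacing))
    if z_top + g.radius_mm >= extent[2]:
        raise GeometryError("ridges do not fit inside the volume along z")
    if x_med - g.radius_mm < 0 or x_lat + g.radius_mm > extent[0]:
        raise GeometryError("ridges do not fit inside the volume along x")

    X, Y, Z = _grids(config)

    # --- bone geometry: base block + two half-capsule ridges ----------------
    base_half_width = g.separation_mm / 2.0 + g.radius_mm
    cx = extent[0] / 2.0
    _, _, y0, _, _ = _ridge_axes(config)
    base = ((np.abs(X - cx) <= base_half_width)
            & (Y >= y0) & (Y <= y0 + g.length_mm)
            & (Z >= g.base_z_mm) & (Z < z_top))
    bone = base | _half_capsule_mask(config, x_med) | _half_capsule_mask(config, x_lat)
    if not bone.any():
        raise GeometryError("bone geometry produced an empty mask")

    labels = np.zeros(config.shape, dtype=np.uint8)
    labels[bone] = LABELS["trabecular"]

    # subchondral plate: bone shell within plate_thickness_mm of background
    depth_to_surface = ndimage.distance_transform_edt(bone, sampling=spacing)
    plate = bone & (depth_to_surface <= config.plate_thickness_mm)
    labels[plate] = LABELS["plate"]

    # --- density field -------------------------------------------------------
    slope, intercept = config.true_calibration
    background_density = slope * config.background_hu + intercept
    density = np.full(config.shape, background_density, dtype=np.float64)
    density[bone] = config.trabecular_density
    density[plate] = config.plate_base_density

    for peak in config.peaks:
        px, py, pz = _surface_point(config, peak.ridge, peak.along_frac)
        d2 = (X - px) ** 2 + (Y - py) ** 2 + (Z - pz) ** 2
        density[plate] += peak.amplitude * np.exp(
            -d2 / (2.0 * peak.sigma_mm ** 2))[plate]

    true_lesion_mean = None
    if config.lesion is not None:
        lx, ly, lz = _lesion_center(config)
        d2 = (X - lx) ** 2 + (Y - ly) ** 2 + (Z - lz) ** 2
        core = bone & (d2 <= config.lesion.core_radius_mm ** 2)
        rim_outer = config.lesion.core_radius_mm + config.lesion.rim_width_mm
        rim = bone & ~core & (d2 <= rim_outer ** 2)
        if not core.any():
            raise GeometryError("lesion core contains no bone voxels")
        labels[core] = LABELS["lesion_core"]
        labels[rim] = LABELS["lesion_rim"]
        density[core] = config.lesion.core_density
        density[rim] = config.lesion.rim_density
        true_lesion_mean = float(density[core].mean())

    # --- calibration inserts -------------------------------------------------
    for k, insert in enumerate(config.inserts):
        m = _insert_mask(config.shape, spacing, insert)
        if (m & bone).any():
            raise GeometryError(f"insert {k} overlaps the bone")
        if not m.any():
            raise GeometryError(f"insert {k} lies outside the volume grid")
        labels[m] = INSERT_LABEL_BASE + k
        density[m] = insert.density

    true_plate_mean = float(density[labels == LABELS["plate"]].mean())

    # --- density -> HU, plus noise ------------------------------------------
    hu = (density - intercept) / slope
    if config.noise_sd_hu > 0:
        rng = np.random.default_rng(config.seed)
        hu = hu + rng.normal(0.0, config.noise_sd_hu, size=config.shape)

    vol = CTVolume(hu=hu, spacing=spacing)
    gt = GroundTruth(
        label_volume=labels,
        true_plate_mean_density=true_plate_mean,
        true_lesion_mean_density=true_lesion_mean,
        true_calibration=config.true_calibration,
        insert_densities=tuple(i.density for i in config.inserts),
    )
    return vol, gt


def affected_config(**overrides) -> PhantomConfig:
    """Default affected-joint configuration: medial-ridge lesion, lower base density."""
    cfg = PhantomConfig(plate_base_density=AFFECTED_PLATE_DENSITY, lesion=LesionSpec())
    return replace(cfg, **overrides) if overrides else cfg


def generate_bilateral_pair(
    config: Optional[PhantomConfig] = None,
    contralateral_offset: float = DEFAULT_CONTRALATERAL_OFFSET,
) -> tuple[tuple[CTVolume, GroundTruth], tuple[CTVolume, GroundTruth]]:
    """Generate an (affected, contralateral) joint pair.

    The affected volume carries the lesion of ``config``; the contralateral
    volume has no lesion and its plate base density raised by
    ``contralateral_offset`` (the compensatory-loading asymmetry: the
    contralateral normal joint is globally denser).  The two sides use
    distinct noise substreams derived from ``config.seed``.
    """
    if contralateral_offset < 0:
        raise PhantomConfigError("contralateral_offset must be >= 0")
    if config is None:
        config = affected_config()
    seed_aff, seed_con = _substream_seeds(config.seed, "bilateral")
    affected = replace(config, seed=seed_aff)
    contra = replace(
        config,
        lesion=None,
        plate_base_density=config.plate_base_density + contralateral_offset,
        seed=seed_con,
    )
    return generate_volume(affected), generate_volume(contra)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortRecord:
    dog_id: str
    side: str  # "left" | "right"
    affected: bool
    timepoint: int
    key: str  # volume reference (dict key, or file stem once written)


@dataclass
class CohortManifest:
    """Records of all joints in a cohort: one affected side per dog, both
    sides present at every timepoint (the study design is unilateral)."""

    records: list[CohortRecord]

    def validate(self) -> None:
        if not self.records:
            raise CohortError("empty cohort manifest")
        df = self.to_frame()
        for (dog, tp), grp in df.groupby(["dog_id", "timepoint"]):
            if sorted(grp["side"]) != ["left", "right"]:
                raise CohortError(f"dog {dog} timepoint {tp}: both sides must be present")
            if int(grp["affected"].sum()) != 1:
                raise CohortError(f"dog {dog} timepoint {tp}: exactly one affected side required")
        affected_sides = df[df["affected"]].groupby("dog_id")["side"].nunique()
        if (affected_sides != 1).any():
            raise CohortError("a dog's affected side must be consistent across timepoints")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    def to_csv(self, path: str | os.PathLike) -> None:
        df = self.to_frame().rename(columns={"key": "path"})
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "CohortManifest":
        df = pd.read_csv(path)
        recs = [
            CohortRecord(str(r.dog_id), str(r.side), bool(r.affected),
                         int(r.timepoint), str(r.path))
            for r in df.itertuples()
        ]
        return cls(records=recs)


def _substream_seeds(master_seed: int, *tokens) -> np.ndarray:
    """Stable per-entity substream seeds: master seed + CRC32 of a string key.

    Keyed hashing (rather than sequential draws) keeps every volume's noise
    stream invariant under reordering or subsetting of the cohort.
    """
    key = ":".join(str(t) for t in tokens)
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(key.encode())])
    return ss.generate_state(2) % (2 ** 31)


def generate_cohort(
    n_dogs: int = COHORT_N_DOGS,
    config_template: Optional[PhantomConfig] = None,
    plate_between_sd: float = CONTRALATERAL_PLATE_BETWEEN_DOG_SD,
    lesion_between_sd: float = LESION_CORE_BETWEEN_DOG_SD,
    contralateral_offset: float = DEFAULT_CONTRALATERAL_OFFSET,
    n_timepoints: int = 1,
    seed: int = 0,
) -> tuple[CohortManifest, dict[str, tuple[CTVolume, GroundTruth]]]:
    """Generate a unilateral-disease cohort with between-dog density variation.

    Per dog, the contralateral plate base density is drawn from
    Normal(contralateral default, ``plate_between_sd``), the affected plate
    base is that value minus ``contralateral_offset``, and the lesion core
    density from Normal(core default, ``lesion_between_sd``) (clipped to stay
    below the rim density).  The affected side (left/right) is randomised per
    dog.  All draws and noise streams are keyed substreams of ``seed``, so the
    cohort is reproducible and stable under reordering.

    At follow-up timepoints (t >= 1) the contralateral joint gains density and
    the lesion core-rim contrast shrinks, emulating the longitudinal pattern
    after treatment.
    """
    if n_dogs < 2:
        raise CohortError("a paired cohort needs at least 2 dogs")
    if n_timepoints < 1:
        raise CohortError("n_timepoints must be >= 1")
    template = config_template if config_template is not None else affected_config()
    if template.lesion is None:
        template = replace(template, lesion=LesionSpec())

    # longitudinal defaults (mg HA/cm^3 per follow-up step)
    contra_gain, core_gain, rim_loss = 30.0, 40.0, 40.0

    records: list[CohortRecord] = []
    volumes: dict[str, tuple[CTVolume, GroundTruth]] = {}
    for i in range(n_dogs):
        dog = f"dog{i + 1:02d}"
        pseed = _substream_seeds(seed, "params", dog)
        prng = np.random.default_rng(pseed[0])
        contra_base = float(prng.normal(CONTRALATERAL_PLATE_DENSITY, plate_between_sd))
        contra_base = max(contra_base, 0.0)
        affected_base = max(contra_base - contralateral_offset, 0.0)
        core = float(prng.normal(LESION_CORE_DENSITY, lesion_between_sd))
        affected_side = "left" if prng.random() < 0.5 else "right"

        for tp in range(n_timepoints):
            core_tp = core + core_gain * tp
            rim_tp = template.lesion.rim_density - rim_loss * tp
            core_tp = float(np.clip(core_tp, 0.0, rim_tp - 50.0))
            lesion = replace(template.lesion, core_density=core_tp, rim_density=rim_tp)
            for side in ("left", "right"):
                affected = side == affected_side
                vseed = _substream_seeds(seed, "vol", dog, side, tp)[0]
                if affected:
                    cfg = replace(template, plate_base_density=affected_base,
                                  lesion=lesion, seed=int(vseed))
                else:
                    cfg = replace(template, lesion=None,
                                  plate_base_density=contra_base + contra_gain * tp,
                                  seed=int(vseed))
                key = f"{dog}_{side}_t{tp}"
                volumes[key] = generate_volume(cfg)
                records.append(CohortRecord(dog, side, affected, tp, key))

    manifest = CohortManifest(records=records)
    manifest.validate()
    return manifest, volumes


# ---------------------------------------------------------------------------
# ground-truth sidecar I/O
# ---------------------------------------------------------------------------

def write_ground_truth(gt: GroundTruth, volume_path: str | os.PathLike) -> tuple[str, str]:
    """Write the JSON sidecar (+ label volume as NIfTI) next to a volume file."""
    base, _ = os.path.splitext(os.fspath(volume_path))
    label_path = base + "_labels.nii"
    json_path = base + "_truth.json"
    write_volume(CTVolume(hu=gt.label_volume.astype(np.int16),
                          spacing=(1.0, 1.0, 1.0),
                          description="ground-truth labels"), label_path)
    payload = {
        "true_plate_mean_density": gt.true_plate_mean_density,
        "true_lesion_mean_density": gt.true_lesion_mean_density,
        "true_calibration": list(gt.true_calibration),
        "insert_densities": list(gt.insert_densities),
        "label_volume": os.path.basename(label_path),
        "labels": LABELS,
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return json_path, label_path


def read_ground_truth(json_path: str | os.PathLike) -> GroundTruth:
    json_path = os.fspath(json_path)
    with open(json_path) as fh:
        payload = json.load(fh)
    label_path = os.path.join(os.path.dirname(json_path), payload["label_volume"])
    labels = read_volume(label_path).hu.astype(np.uint8)
    return GroundTruth(
        label_volume=labels,
        true_plate_mean_density=payload["true_plate_mean_density"],
        true_lesion_mean_density=payload["true_lesion_mean_density"],
        true_calibration=tuple(payload["true_calibration"]),
        insert_densities=tuple(payload["insert_densities"]),
    )
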