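"""Bone segmentation, articular-surface ray casting and plate extraction.

The bone of interest is isolated by a fixed HU threshold (default 200 HU,
the floor of the densitogram display window) followed by largest
26-connected component selection and closing of small holes.  For each view
the articular surface is found by ray casting: along every projection ray
the first bone voxel defines the surface, and the subchondral bone plate is
the set of bone voxels within the projection depth (default 1.5 mm, the
plate thickness) of that surface voxel, measured along the ray.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.morphology import remove_small_holes

from .volume import CTVolume

DEFAULT_THRESHOLD_HU = 200.0
DEFAULT_DEPTH_MM = 1.5
MAX_HOLE_VOXELS = 3


class EmptySegmentationError(ValueError):
    """No voxel reached the segmentation threshold."""


class ParameterError(ValueError):
    pass


class ViewMismatchError(ValueError):
    """Inputs were produced under different views."""


@dataclass(frozen=True)
class ViewSpec:
    """An axis-aligned projection view.

    ``axis`` is the volume axis the rays travel along and ``direction`` the
    travel direction (+1 = increasing index, -1 = decreasing).  Rays enter
    from outside the bone, so the *first* bone voxel met is the articular
    surface.  The two standard views:

    * ``proximal``: rays along -z — looking down at the proximal articular
      surface of the trochlear ridges;
    * ``dorsal``: the proximal view rotated backward by 90 degrees about the
      mediolateral (x) axis — rays along -y onto the dorsal aspect.
    """

    name: str
    axis: int
    direction: int

    def __post_init__(self) -> None:
        if self.axis not in (0, 1, 2) or self.direction not in (-1, 1):
            raise ParameterError(f"invalid view {self}")

    @property
    def plane_axes(self) -> tuple[int, int]:
        """The two in-plane (image) axes, in volume-axis order."""
        return tuple(a for a in range(3) if a != self.axis)


PROXIMAL = ViewSpec("proximal", axis=2, direction=-1)
DORSAL = ViewSpec("dorsal", axis=1, direction=-1)
STANDARD_VIEWS = (PROXIMAL, DORSAL)


def get_view(name: str) -> ViewSpec:
    for v in STANDARD_VIEWS:
        if v.name == name:
            return v
    raise ParameterError(f"unknown view {name!r}; expected one of "
                         f"{[v.name for v in STANDARD_VIEWS]}")


@dataclass
class BoneMask:
    """Binary voxel mask of the segmented bone (single connected component)."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    threshold_hu: float

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class SurfaceMap:
    """Per-ray articular surface for one view.

    ``first_index`` holds, for each in-plane pixel, the ray-order index (0 at
    the ray entry face) of the first bone voxel; -1 where the ray misses the
    bone.  ``footprint`` is the joint-surface mask (rays that hit bone).
    """

    view: ViewSpec
    first_index: np.ndarray  # int, 2D
    footprint: np.ndarray  # bool, 2D
    n_along: int  # number of voxels along the ray axis


@dataclass
class PlateMask:
    """Subchondral plate voxels for one view (subset of the bone mask)."""

    mask: np.ndarray  # bool, 3D, volume frame
    surface: SurfaceMap
    depth_mm: float
    view: ViewSpec


def _to_ray_frame(arr: np.ndarray, view: ViewSpec) -> np.ndarray:
    """Reorder an array so the ray axis is last and index 0 is the entry face."""
    moved = np.moveaxis(arr, view.axis, -1)
    if view.direction < 0:
        moved = moved[..., ::-1]
    return moved


def _from_ray_frame(arr: np.ndarray, view: ViewSpec) -> np.ndarray:
    if view.direction < 0:
        arr = arr[..., ::-1]
    return np.moveaxis(arr, -1, view.axis)


def segment_bone(volume: CTVolume,
                 threshold_hu: float = DEFAULT_THRESHOLD_HU) -> BoneMask:
    """Threshold + largest 26-connected component + small-hole closing.

    Holes of up to 3 voxels inside the component are filled.  Component-size
    ties break to the lowest label index (deterministic).
    """
    supra = volume.hu >= threshold_hu
    if not supra.any():
        raise EmptySegmentationError(
            f"no voxel >= {threshold_hu} HU; cannot segment bone")
    labels, n = ndimage.label(supra, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 1:
        comp = supra
    else:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        comp = labels == int(np.argmax(counts))  # argmax -> lowest label on tie
    comp = remove_small_holes(comp, max_size=MAX_HOLE_VOXELS)
    return BoneMask(mask=comp, spacing=volume.spacing, threshold_hu=float(threshold_hu))


def find_articular_surface(bone: BoneMask, view: ViewSpec) -> SurfaceMap:
    """Ray-cast the first bone voxel per projection ray.

    Rays that miss the bone are marked absent; the set of hit rays is the
    joint-surface footprint used by the densitogram.
    """
    if not bone.mask.any():
        raise EmptySegmentationError("empty bone mask")
    m = _to_ray_frame(bone.mask, view)
    footprint = m.any(axis=-1)
    first = m.argmax(axis=-1).astype(np.int64)
    first[~footprint] = -1
    return SurfaceMap(view=view, first_index=first, footprint=footprint,
                      n_along=m.shape[-1])


def extract_plate(bone: BoneMask, surface: SurfaceMap,
                  depth_mm: float = DEFAULT_DEPTH_MM) -> PlateMask:
    """Bone voxels within ``depth_mm`` along-ray of each ray's surface voxel.

    Depth is measured from the surface voxel centre in mm along the ray axis
    and is inclusive: with 0.3 mm sampling a 1.5 mm depth keeps the surface
    sample plus 5 samples beyond it.
    """
    if depth_mm <= 0:
        raise ParameterError(f"depth_mm must be > 0, got {depth_mm}")
    view = surface.view
    step = bone.spacing[view.axis]
    n_extra = int(np.floor(depth_mm / step + 1e-9))
    m = _to_ray_frame(bone.mask, view)
    idx = np.arange(m.shape[-1])
    first = surface.first_index[..., None]
    within = (idx >= first) & (idx <= first + n_extra) & surface.footprint[..., None]
    plate_ray = m & within
    return PlateMask(mask=_from_ray_frame(plate_ray, view), surface=surface,
                     depth_mm=float(depth_mm), view=view)
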