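"""Densitograms: surface projection, quantization, false colour, density maxima.

The subchondral plate is collapsed onto the articular surface by a maximum
intensity projection (MIP): for every surface pixel the densitogram value is
the maximum HU among the plate voxels on its ray; the per-ray arithmetic
mean is kept alongside.  For quantification the display window (200-1200 HU)
is rescaled to 8 bits (256 levels), evenly split into eight bins of 32
levels each; a *density maximum* is any surface area falling in the two
highest bins, and its size relative to the whole joint surface is the
maximum area ratio

    MAR = pixels of the density maximum / pixels of the total joint surface.

For between-individual comparison a 30 x 30 unit grid is stretched over the
joint-surface bounding box and maxima are reported by their grid
coordinates.  The false-colour rendering divides the window into ten 100 HU
classes coloured, in descending density order: black, dark red, light red,
orange, yellow, dark green, light green, dark blue, light blue, white.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .segmentation import PlateMask, ViewSpec, ViewMismatchError
from .volume import CTVolume

DEFAULT_WINDOW = (200.0, 1200.0)
N_EIGHTBIT = 256
N_BINS = 8
LEVELS_PER_BIN = N_EIGHTBIT // N_BINS  # 32
N_COLOR_CLASSES = 10
GRID_N = 30

#: colour classes in *ascending* density order (class 0 = lowest 100 HU).
#: Descending order is black, dark red, light red, orange, yellow,
#: dark green, light green, dark blue, light blue, white.
COLOR_NAMES = (
    "white", "light blue", "dark blue", "light green", "dark green",
    "yellow", "orange", "light red", "dark red", "black",
)
COLOR_RGB = (
    (255, 255, 255),
    (130, 190, 255),
    (0, 0, 160),
    (130, 230, 130),
    (0, 130, 0),
    (255, 255, 0),
    (255, 160, 0),
    (255, 110, 110),
    (170, 0, 0),
    (0, 0, 0),
)
BACKGROUND_RGB = (190, 190, 190)


class DomainError(ValueError):
    pass


class WindowError(ValueError):
    pass


@dataclass
class Densitogram:
    """Per-view 2D projection of the subchondral plate.

    ``max_map``/``mean_map`` are defined exactly on ``surface_mask``; values
    off the surface are NaN.  ``pixel_spacing`` is the in-plane voxel size
    (mm) of the two image axes.
    """

    view: ViewSpec
    max_map: np.ndarray
    mean_map: np.ndarray
    surface_mask: np.ndarray
    pixel_spacing: tuple[float, float]


@dataclass
class QuantizedMap:
    """8-bit / 8-bin / 10-colour-class quantization of a densitogram MIP."""

    eightbit_map: np.ndarray  # int16, -1 off surface, else 0..255
    bin_map: np.ndarray  # int16, -1 off surface, else 0..7
    color_map: np.ndarray  # int16, -1 off surface, else 0..9
    window: tuple[float, float]
    surface_mask: np.ndarray


@dataclass
class MaximumRegion:
    label: int
    n_pixels: int
    centroid: tuple[float, float]
    grid_xy: tuple[int, int]


@dataclass
class DensityMaximumSummary:
    """Surface pixels in the two highest density bins, their connected
    regions, grid coordinates of region centroids, and the pooled MAR."""

    maximum_pixels: np.ndarray  # bool, 2D
    regions: list[MaximumRegion]
    mar: float

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def grid_coords(self) -> list[tuple[int, int]]:
        return [r.grid_xy for r in self.regions]


def project(volume: CTVolume, plate: PlateMask, view: ViewSpec) -> Densitogram:
    """Maximum-intensity and mean projection of the plate onto the surface.

    For each surface pixel the value set is the HU of the plate voxels on its
    ray; ``max_map`` is their maximum, ``mean_map`` their arithmetic mean.
    """
    if view.name != plate.view.name or view.axis != plate.view.axis \
            or view.direction != plate.view.direction:
        raise ViewMismatchError(
            f"plate was extracted for view {plate.view.name!r}, "
            f"projection requested for {view.name!r}")
    from .segmentation import _to_ray_frame

    hu = _to_ray_frame(np.asarray(volume.hu, dtype=np.float64), view)
    pm = _to_ray_frame(plate.mask, view)
    counts = pm.sum(axis=-1)
    surface = counts > 0
    neg_inf = np.where(pm, hu, -np.inf)
    with np.errstate(invalid="ignore"):
        max_map = neg_inf.max(axis=-1)
        mean_map = np.where(surface, np.where(pm, hu, 0.0).sum(axis=-1)
                            / np.maximum(counts, 1), np.nan)
    max_map = np.where(surface, max_map, np.nan)
    sp = volume.spacing
    pixel_spacing = tuple(sp[a] for a in view.plane_axes)
    return Densitogram(view=view, max_map=max_map, mean_map=mean_map,
                       surface_mask=surface, pixel_spacing=pixel_spacing)


def quantize(d: Densitogram,
             window: tuple[float, float] = DEFAULT_WINDOW) -> QuantizedMap:
    """Quantize the MIP map to 8-bit levels, 8 bins and 10 colour classes.

    eightbit = round(255 * clip((HU - low) / (high - low), 0, 1)), with
    rounding half away from zero; bin = eightbit // 32 (level 255 stays in
    bin 7); colour class = which of the ten equal HU intervals of the window
    the raw HU falls in (values outside the window clip to the end classes).
    """
    low, high = float(window[0]), float(window[1])
    if not low < high:
        raise WindowError(f"degenerate window {window}")
    hu = d.max_map
    frac = np.clip((hu - low) / (high - low), 0.0, 1.0)
    eightbit = np.floor(255.0 * frac + 0.5)  # round half away from zero (frac >= 0)
    bins = np.minimum(eightbit // LEVELS_PER_BIN, N_BINS - 1)
    class_width = (high - low) / N_COLOR_CLASSES
    clipped = np.clip(hu, low, np.nextafter(high, low))
    color = np.floor((clipped - low) / class_width)

    def _fill(arr):
        out = np.where(d.surface_mask, arr, -1)
        return out.astype(np.int16)

    return QuantizedMap(eightbit_map=_fill(eightbit), bin_map=_fill(bins),
                        color_map=_fill(color), window=(low, high),
                        surface_mask=d.surface_mask)


def colorize(q: QuantizedMap, isodensity_contours: bool = False) -> np.ndarray:
    """Render the colour-class map as an RGB uint8 image.

    The highest 100 HU class renders black, the lowest white; off-surface
    pixels are neutral grey.  With ``isodensity_contours`` the boundaries
    between colour classes are drawn in mid grey (lines of equal density).
    """
    lut = np.array((BACKGROUND_RGB,) + COLOR_RGB, dtype=np.uint8)
    img = lut[q.color_map + 1]
    if isodensity_contours:
        cm = q.color_map
        edge = np.zeros_like(q.surface_mask)
        edge[:-1, :] |= (cm[:-1, :] != cm[1:, :]) & q.surface_mask[:-1, :] & q.surface_mask[1:, :]
        edge[:, :-1] |= (cm[:, :-1] != cm[:, 1:]) & q.surface_mask[:, :-1] & q.surface_mask[:, 1:]
        img[edge] = (100, 100, 100)
    return img


def grid_coordinates(surface_mask: np.ndarray,
                     point: Sequence[float],
                     n: int = GRID_N,
                     require_on_surface: bool = True) -> tuple[int, int]:
    """Map a surface pixel to 1-based coordinates on the standard n x n grid.

    The grid is stretched over the tight bounding box of the joint surface so
    the whole surface fits inside; per axis the cell is
    ``1 + floor(n * (coord - bbox_min) / bbox_extent)``, clipped to ``n``.
    """
    if not np.any(surface_mask):
        raise DomainError("empty surface mask")
    pt = tuple(float(c) for c in point)
    if require_on_surface:
        i, j = int(round(pt[0])), int(round(pt[1]))
        inside = (0 <= i < surface_mask.shape[0] and 0 <= j < surface_mask.shape[1]
                  and surface_mask[i, j])
        if not inside:
            raise DomainError(f"point {point} is not on the joint surface")
    rows, cols = np.nonzero(surface_mask)
    coords = []
    for c, lo, hi in ((pt[0], rows.min(), rows.max()), (pt[1], cols.min(), cols.max())):
        extent = hi - lo + 1  # bbox extent in pixels
        cell = 1 + int(np.floor(n * (c - lo) / extent))
        coords.append(int(np.clip(cell, 1, n)))
    return tuple(coords)


def compute_mar(maximum_pixels: np.ndarray, surface_mask: np.ndarray) -> float:
    """MAR = |density-maximum pixels| / |joint-surface pixels| (exact ratio)."""
    n_surf = int(np.count_nonzero(surface_mask))
    if n_surf == 0:
        raise DomainError("empty surface mask: MAR undefined")
    n_max = int(np.count_nonzero(maximum_pixels & surface_mask))
    return n_max / n_surf


def locate_density_maxima(q: QuantizedMap,
                          surface_mask: Optional[np.ndarray] = None,
                          grid_n: int = GRID_N) -> DensityMaximumSummary:
    """Find density maxima: surface pixels in the two highest bins (6 and 7).

    Maxima are split into 8-connected regions; each region reports its pixel
    count, centroid and centroid grid coordinates.  An empty maximum set is
    valid (MAR 0, no regions).
    """
    surface = q.surface_mask if surface_mask is None else surface_mask
    if not np.any(surface):
        raise DomainError("empty surface mask")
    maximum = surface & (q.bin_map >= N_BINS - 2)
    labels, n = ndimage.label(maximum, structure=np.ones((3, 3), dtype=bool))
    regions: list[MaximumRegion] = []
    if n:
        centroids = ndimage.center_of_mass(maximum, labels, range(1, n + 1))
        sizes = ndimage.sum_labels(maximum, labels, range(1, n + 1))
        for lab, (cy, cx), size in zip(range(1, n + 1), centroids, sizes):
            grid = grid_coordinates(surface, (cy, cx), n=grid_n,
                                    require_on_surface=False)
            regions.append(MaximumRegion(label=lab, n_pixels=int(size),
                                         centroid=(float(cy), float(cx)),
                                         grid_xy=grid))
    return DensityMaximumSummary(maximum_pixels=maximum, regions=regions,
                                 mar=compute_mar(maximum, surface))
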