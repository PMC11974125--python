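"""HU -> mineral density calibration from a reference phantom.

CT attenuation (HU) is converted to hydroxyapatite-equivalent mineral density
(mg HA/cm^3) through an affine map fitted by ordinary least squares to the
known-density inserts of a calibration phantom scanned with the joint:

    density = slope * HU + intercept

Insert ROIs are eroded by one voxel before averaging so partial-volume voxels
at the insert boundary do not bias the fit.  With exactly two inserts the fit
is exact; with more, residual RMS quantifies phantom/scan linearity.
Calibration is per-scan.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from .volume import CTVolume

log = logging.getLogger(__name__)


class UnderdeterminedError(ValueError):
    """Fewer than two distinct insert HU values: the affine map cannot be fit."""


class InsertExtractionError(ValueError):
    """An insert ROI lies outside the volume or is empty after erosion."""


@dataclass(frozen=True)
class CalibrationModel:
    """Affine HU -> mg HA/cm^3 map.

    ``slope`` must be positive: attenuation increases with mineral density,
    so the map is strictly increasing in HU.
    """

    slope: float  # mg HA/cm^3 per HU
    intercept: float  # mg HA/cm^3
    residual_rms: float = 0.0
    n_inserts: int = 2

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"calibration slope must be > 0, got {self.slope}")
        if self.n_inserts < 2:
            raise ValueError("a calibration model needs >= 2 inserts")
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be >= 0")

    def __call__(self, hu):
        return hu_to_density(self, hu)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump({"slope": self.slope, "intercept": self.intercept,
                       "residual_rms": self.residual_rms,
                       "n_inserts": self.n_inserts}, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "CalibrationModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def extract_insert_means(volume: CTVolume, inserts: Sequence) -> list[tuple[float, float]]:
    """Sample mean HU inside each calibration insert.

    ``inserts`` is a sequence of :class:`~ctoam.synthetic_data.InsertSpec`
    (known density, cylinder centre/radius/height in mm).  Each insert ROI is
    eroded by one voxel to drop partial-volume edge voxels.

    Returns ``[(known_density, mean_hu), ...]`` in input order.
    """
    from .synthetic_data import _insert_mask  # cylinder rasterisation

    extent = volume.extent_mm()
    pairs: list[tuple[float, float]] = []
    for k, ins in enumerate(inserts):
        cx, cy, cz = ins.center_mm
        if not (ins.radius_mm <= cx <= extent[0] - ins.radius_mm
                and ins.height_mm / 2 <= cy <= extent[1] - ins.height_mm / 2
                and ins.radius_mm <= cz <= extent[2] - ins.radius_mm):
            raise InsertExtractionError(
                f"insert {k} (density {ins.density}) extends outside the volume")
        roi = _insert_mask(volume.shape, volume.spacing, ins)
        roi = ndimage.binary_erosion(roi, iterations=1)
        if not roi.any():
            raise InsertExtractionError(
                f"insert {k} (density {ins.density}) is empty after 1-voxel erosion")
        pairs.append((float(ins.density), float(volume.hu[roi].mean())))
    return pairs


def fit_calibration(pairs: Sequence[tuple[float, float]]) -> CalibrationModel:
    """Ordinary least-squares fit of density = slope * HU + intercept.

    ``pairs`` are ``(known_density, mean_hu)`` tuples from
    :func:`extract_insert_means`.  Raises :class:`UnderdeterminedError` for
    fewer than two pairs or coincident HU values.
    """
    if len(pairs) < 2:
        raise UnderdeterminedError("calibration needs >= 2 (density, HU) pairs")
    density = np.asarray([p[0] for p in pairs], dtype=np.float64)
    hu = np.asarray([p[1] for p in pairs], dtype=np.float64)
    if np.ptp(hu) == 0:
        raise UnderdeterminedError("all insert HU values are identical; slope undefined")
    if len(pairs) == 2:
        # exact two-point solution (linregress is equivalent; this avoids its
        # degenerate-stderr warnings for n = 2)
        slope = (density[1] - density[0]) / (hu[1] - hu[0])
        intercept = density[0] - slope * hu[0]
        residual_rms = 0.0
    else:
        res = stats.linregress(hu, density)
        slope, intercept = float(res.slope), float(res.intercept)
        residual_rms = float(np.sqrt(np.mean((slope * hu + intercept - density) ** 2)))
    if slope <= 0:
        raise UnderdeterminedError(
            f"fitted calibration slope {slope:.4g} is not positive; "
            "check insert specification/ROIs")
    return CalibrationModel(slope=float(slope), intercept=float(intercept),
                            residual_rms=residual_rms, n_inserts=len(pairs))


def hu_to_density(model: CalibrationModel, hu):
    """Apply the affine calibration elementwise; masks and shapes are preserved.

    Accepts scalars, ndarrays and masked arrays.  Negative calibrated
    densities (air / soft tissue under the map) are numerically permitted but
    logged at debug level.
    """
    out = model.slope * np.ma.asanyarray(hu) + model.intercept if np.ma.isMaskedArray(hu) \
        else model.slope * np.asanyarray(hu) + model.intercept
    if np.ndim(out) == 0 and not np.ma.isMaskedArray(out):
        out = float(out)
        if out < 0:
            log.debug("calibrated density %.1f mg HA/cm^3 is negative", out)
        return out
    valid = out.compressed() if np.ma.isMaskedArray(out) else out
    if valid.size and (valid < 0).any():
        log.debug("%d calibrated densities are negative (air/soft tissue)",
                  int((valid < 0).sum()))
    return out
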