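"""CT volume container and on-disk interchange.

The package works on a single in-memory representation: a 3D array of
Hounsfield Units plus per-axis voxel spacing in millimetres.  Axis order is
fixed throughout the package as

    axis 0 = x = mediolateral
    axis 1 = y = dorsoplantar
    axis 2 = z = proximodistal

and recorded in the NIfTI header ``descrip`` field on write.  NIfTI-1 is the
primary interchange format (int16 HU); DICOM series are read-only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import nibabel as nib

AXIS_DESCRIPTION = "axes: x=mediolateral y=dorsoplantar z=proximodistal; HU"


class FormatError(ValueError):
    """A volume file could not be parsed; the message names the offending field."""


@dataclass
class CTVolume:
    """A 3D CT scan in Hounsfield Units.

    Parameters
    ----------
    hu : ndarray, shape (nx, ny, nz)
        Voxel intensities in Hounsfield Units.  Float arrays are allowed in
        memory (noiseless synthetic volumes are exact floats); on disk HU are
        stored as int16.
    spacing : tuple of 3 floats
        Voxel size in mm per axis.  Voxel *centres* sit at
        ``(index + 0.5) * spacing`` in the volume's mm coordinate frame.
    """

    hu: np.ndarray
    spacing: tuple[float, float, float]
    description: str = field(default=AXIS_DESCRIPTION)

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu)
        if self.hu.ndim != 3:
            raise FormatError(f"CTVolume.hu must be 3D, got ndim={self.hu.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"CTVolume.spacing must be 3 positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape

    def extent_mm(self) -> tuple[float, float, float]:
        """Physical edge lengths of the volume in mm."""
        return tuple(n * s for n, s in zip(self.hu.shape, self.spacing))

    def voxel_centers(self, axis: int) -> np.ndarray:
        """mm coordinates of voxel centres along one axis."""
        n, s = self.hu.shape[axis], self.spacing[axis]
        return (np.arange(n) + 0.5) * s


def write_volume(volume: CTVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1 with int16 HU and spacing in the header.

    HU values are rounded to the nearest integer; a volume that already holds
    integral HU round-trips exactly.
    """
    data = np.rint(volume.hu).astype(np.int16)
    affine = np.diag([*volume.spacing, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(volume.spacing)
    img.header["descrip"] = volume.description.encode()[:79]
    nib.save(img, os.fspath(path))


def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read a NIfTI volume written by :func:`write_volume` (or compatible)."""
    path = os.fspath(path)
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises a zoo of types on bad files
        raise FormatError(f"could not read NIfTI volume from {path!r}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path!r}: expected a 3D image, header reports ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise FormatError(f"{path!r}: non-positive voxel spacing in header pixdim: {zooms}")
    descrip = bytes(img.header["descrip"]).split(b"\x00", 1)[0].decode(errors="replace")
    return CTVolume(hu=data, spacing=tuple(float(z) for z in zooms),
                    description=descrip or AXIS_DESCRIPTION)


def read_dicom_series(directory: str | os.PathLike) -> CTVolume:
    """Read an axial DICOM series into a CTVolume (HU via RescaleSlope/Intercept).

    Slices are sorted by ImagePositionPatient along the slice axis (falling
    back to InstanceNumber) and stacked on axis 2; in-plane rows/cols map to
    axes 1/0 so that the package's (x, y, z) axis convention is preserved for
    a standard axial acquisition.
    """
    import pydicom

    directory = os.fspath(directory)
    files = sorted(
        os.path.join(directory, f) for f in os.listdir(directory)
        if not f.startswith(".")
    )
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"no DICOM images with PixelData found in {directory!r}")

    def sort_key(ds):
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None and len(ipp) == 3:
            return float(ipp[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=sort_key)
    first = slices[0]
    try:
        px, py = (float(v) for v in first.PixelSpacing)
    except Exception as exc:
        raise FormatError(f"{directory!r}: missing or malformed PixelSpacing") from exc
    if len(slices) > 1:
        dz = abs(sort_key(slices[1]) - sort_key(slices[0])) or float(
            getattr(first, "SliceThickness", 1.0))
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    stack = []
    for ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = ds.pixel_array.astype(np.float64) * slope + inter
        # pixel_array is (row, col) = (y, x); transpose to (x, y)
        stack.append(arr.T)
    hu = np.stack(stack, axis=2)
    return CTVolume(hu=hu, spacing=(px, py, dz))
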