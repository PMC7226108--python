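"""Volumetric image and mask I/O.

Volumes and masks are held as plain 3-D NumPy arrays indexed ``(x, y, z)``
(0-based) with physical voxel spacing in millimetres.  NIfTI is the on-disk
format, read and written through nibabel; a JSON provenance sidecar records
the source path and grid metadata next to every file this module writes.

Physical distances are always derived from the stored spacing; voxel indices
are never treated as millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import EmptyROIError, FormatError, GridMismatchError, ValidationError

__all__ = [
    "Volume3D",
    "ROIMask",
    "ROIVoxelSet",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "extract_roi",
    "resample_isotropic",
]


@dataclass
class Volume3D:
    """A 3-D scalar image with physical grid metadata.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Scalar intensities (e.g. ADC in mm^2/s).
    spacing : tuple of float
        Voxel size ``(sx, sy, sz)`` in mm; all components must be positive.
    origin : tuple of float
        Physical coordinates of voxel ``(0, 0, 0)``.
    axcodes : tuple of str
        Anatomical orientation codes of the three axes.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axcodes: tuple[str, str, str] = ("R", "A", "S")

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError(
                f"volume must be rank 3, got rank {self.voxels.ndim}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        n_bad = int(np.size(self.voxels) - np.isfinite(self.voxels).sum())
        if n_bad:
            raise ValidationError(f"volume contains {n_bad} non-finite voxel(s)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class ROIMask:
    """Binary tumour mask sharing the grid of its companion :class:`Volume3D`.

    Stored as uint8; any strictly positive value is foreground.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise ValidationError(f"mask must be rank 3, got rank {arr.ndim}")
        self.voxels = (arr > 0).astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())


@dataclass
class ROIVoxelSet:
    """Intensities and integer coordinates of the voxels inside a mask."""

    values: np.ndarray
    coordinates: np.ndarray  # (n, 3) int array of (i, j, k)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=int)
        if len(self.values) != len(self.coordinates):
            raise ValidationError("values and coordinates must have equal length")

    def __len__(self) -> int:
        return len(self.values)


def _affine_from(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def _sidecar(path: Path, payload: dict) -> None:
    side = path.with_name(path.name.split(".")[0] + ".provenance.json")
    side.write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_volume(path) -> Volume3D:
    """Load a NIfTI volume, validating rank, spacing and finiteness.

    Raises
    ------
    FormatError
        If the file is missing, truncated or not a supported format.
    ValidationError
        If the array is not rank 3 or contains NaN/Inf voxels.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except ValidationError:
        raise
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read {path} as a volumetric image: {exc}") from exc
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    try:
        codes = tuple(nib.orientations.aff2axcodes(img.affine))
    except Exception:
        codes = ("R", "A", "S")
    return Volume3D(voxels=data, spacing=tuple(zooms), origin=origin, axcodes=codes)


def write_volume(vol: Volume3D, path) -> Path:
    """Write a volume as NIfTI plus a JSON provenance sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float64),
                          _affine_from(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    _sidecar(path, {"path": str(path), "shape": list(vol.shape),
                    "spacing_mm": list(vol.spacing), "origin": list(vol.origin)})
    return path


def read_mask(path) -> ROIMask:
    """Load a NIfTI mask; any value > 0 becomes foreground."""
    vol = read_volume(path)
    return ROIMask(voxels=vol.voxels, spacing=vol.spacing, origin=vol.origin)


def write_mask(mask: ROIMask, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8),
                          _affine_from(mask.spacing, mask.origin))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
    _sidecar(path, {"path": str(path), "shape": list(mask.shape),
                    "spacing_mm": list(mask.spacing), "origin": list(mask.origin)})
    return path


def extract_roi(vol: Volume3D, mask: ROIMask) -> ROIVoxelSet:
    """Collect the masked voxels in deterministic i-major (C) order.

    Raises
    ------
    GridMismatchError
        If volume and mask differ in shape or spacing.
    EmptyROIError
        If the mask has no foreground voxel.
    """
    if vol.shape != mask.shape:
        raise GridMismatchError(
            f"volume shape {vol.shape} != mask shape {mask.shape}"
        )
    if not np.allclose(vol.spacing, mask.spacing, atol=1e-6):
        raise GridMismatchError(
            f"volume spacing {vol.spacing} != mask spacing {mask.spacing}"
        )
    coords = np.argwhere(mask.voxels > 0)  # C-order: i-major
    if len(coords) == 0:
        raise EmptyROIError("mask contains no foreground voxels")
    values = vol.voxels[coords[:, 0], coords[:, 1], coords[:, 2]]
    return ROIVoxelSet(values=values, coordinates=coords, spacing=vol.spacing)


def resample_isotropic(vol: Volume3D, mask: ROIMask | None = None,
                       target_mm: float = 1.0):
    """Optional isotropic resampling (off by default in the pipeline).

    Linear interpolation for the image, nearest-neighbour for the mask, so
    the mask stays binary.  Returns ``vol`` or ``(vol, mask)`` resampled.
    """
    zoom = tuple(s / target_mm for s in vol.spacing)
    new_vox = ndimage.zoom(vol.voxels, zoom, order=1, mode="nearest")
    out_vol = Volume3D(new_vox, spacing=(target_mm,) * 3, origin=vol.origin,
                       axcodes=vol.axcodes)
    if mask is None:
        return out_vol
    new_mask = ndimage.zoom(mask.voxels, zoom, order=0, mode="nearest")
    # nearest-neighbour zoom may round shapes differently; crop/pad to match
    new_mask = new_mask[tuple(slice(0, n) for n in out_vol.shape)]
    pad = [(0, a - b) for a, b in zip(out_vol.shape, new_mask.shape)]
    if any(p[1] for p in pad):
        new_mask = np.pad(new_mask, pad)
    out_mask = ROIMask(new_mask, spacing=(target_mm,) * 3, origin=mask.origin)
    return out_vol, out_mask
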