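"""CT and label volumes with NIfTI-1 persistence.

Arrays are kept in ``(z, y, x)`` axis order with per-axis voxel spacing in
millimetres; every volume/area conversion in the package goes through the
product of spacings so anisotropic voxels are handled uniformly.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "CTVolume",
    "LabelVolume",
    "LABEL_SCHEME",
    "LOBE_LABELS",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "VolumeFormatError",
]

HU_MIN = -1100.0
HU_MAX = 3100.0

#: Integer label scheme shared by phantoms and all downstream analysis.
LABEL_SCHEME = {
    "background": 0,
    "RUL": 1,
    "RML": 2,
    "RLL": 3,
    "LUL": 4,
    "LLL": 5,
    "airway_lumen": 6,
    "airway_wall": 7,
    "nodule": 8,
}

#: Lobe labels: right upper/middle/lower, left upper/lower.
LOBE_LABELS = (1, 2, 3, 4, 5)


class VolumeFormatError(ValueError):
    """Raised when a volume file violates the expected format."""


def _check_spacing(spacing_mm: Sequence[float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing_mm must be 3 positive values, got {spacing_mm!r}")
    return spacing


@dataclasses.dataclass
class CTVolume:
    """A 3-D grid of CT attenuation values in Hounsfield units.

    Parameters
    ----------
    values
        HU array of shape ``(nz, ny, nx)``. Air is ~ -1000 HU, water 0 HU.
    spacing_mm
        Voxel edge lengths ``(dz, dy, dx)`` in mm.
    origin_mm
        Physical position of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise VolumeFormatError(
                f"expected 3-D volume, got shape {self.values.shape}"
            )
        self.spacing_mm = _check_spacing(self.spacing_mm)
        self.origin_mm = tuple(float(v) for v in self.origin_mm)
        lo, hi = float(self.values.min()), float(self.values.max())
        if lo < HU_MIN or hi > HU_MAX:
            raise VolumeFormatError(
                f"HU values outside [{HU_MIN:g}, {HU_MAX:g}]: range [{lo:g}, {hi:g}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclasses.dataclass
class LabelVolume:
    """Integer label map co-registered with a :class:`CTVolume`."""

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise VolumeFormatError(
                f"expected 3-D label volume, got shape {self.labels.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.array_equal(rounded, self.labels):
                raise VolumeFormatError("labels must be integer-valued")
            self.labels = rounded.astype(np.int16)
        self.spacing_mm = _check_spacing(self.spacing_mm)
        known = set(LABEL_SCHEME.values())
        present = set(np.unique(self.labels).tolist())
        unknown = present - known
        if unknown:
            raise VolumeFormatError(f"labels outside declared scheme: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def mask(self, *label_ids: int) -> np.ndarray:
        """Boolean mask of voxels carrying any of ``label_ids``."""
        return np.isin(self.labels, label_ids)

    def lung_mask(self) -> np.ndarray:
        return self.mask(*LOBE_LABELS)


def _affine(spacing_zyx: Sequence[float], origin_zyx: Sequence[float]) -> np.ndarray:
    # nibabel stores (x, y, z); we store (z, y, x) and transpose on IO
    aff = np.diag(list(spacing_zyx[::-1]) + [1.0])
    aff[:3, 3] = list(origin_zyx[::-1])
    return aff


def _load_3d(path: str | os.PathLike) -> tuple[np.ndarray, tuple, tuple]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise VolumeFormatError(f"unreadable NIfTI header in {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeFormatError(
            f"expected 3-D volume in {path}, got {data.ndim}-D image"
        )
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    # normalize (x, y, z) -> (z, y, x)
    return data.T, tuple(float(z) for z in zooms[::-1]), origin[::-1]


def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read a 3-D NIfTI-1 CT volume; axes normalized to ``(z, y, x)``."""
    data, spacing, origin = _load_3d(path)
    return CTVolume(values=data, spacing_mm=spacing, origin_mm=origin)


def write_volume(volume: CTVolume, path: str | os.PathLike) -> None:
    """Write a CT volume as NIfTI-1, as int16 when values are integral."""
    vals = volume.values
    if np.issubdtype(vals.dtype, np.integer) or np.array_equal(np.rint(vals), vals):
        vals = vals.astype(np.int16)
    else:
        vals = vals.astype(np.float32)
    img = nib.Nifti1Image(vals.T, _affine(volume.spacing_mm, volume.origin_mm))
    img.header.set_zooms(volume.spacing_mm[::-1])
    nib.save(img, str(path))


def read_labels(path: str | os.PathLike) -> LabelVolume:
    """Read a co-registered integer label volume (lobes/airways/nodule)."""
    data, spacing, _ = _load_3d(path)
    return LabelVolume(labels=data, spacing_mm=spacing)


def write_labels(labels: LabelVolume, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(
        labels.labels.T.astype(np.int16), _affine(labels.spacing_mm, (0, 0, 0))
    )
    img.header.set_zooms(labels.spacing_mm[::-1])
    nib.save(img, str(path))
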