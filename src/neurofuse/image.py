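"""Core image containers and file I/O.

Every stage of the pipeline transforms :class:`VolumeImage` objects — scalar
grids (2D slices or 3D volumes) carrying a voxel spacing and a modality tag —
and produces or consumes congruent binary :class:`BrainMask` grids.  3D
volumes are read and written as NIfTI through nibabel; 2D slices as 8/16-bit
grayscale PNG through imageio.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class Modality(enum.Enum):
    MRI = "MRI"
    PET = "PET"
    OTHER = "OTHER"


class NeurofuseError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(NeurofuseError, ValueError):
    pass


class DegenerateInputError(NeurofuseError, ValueError):
    pass


class ShapeMismatchError(NeurofuseError, ValueError):
    pass


class StrippingFailedError(NeurofuseError, RuntimeError):
    pass


@dataclass
class VolumeImage:
    """A scalar intensity grid with physical spacing and a modality tag.

    Parameters
    ----------
    data
        2D ``(H, W)`` or 3D ``(H, W, D)`` array of finite intensities.
    spacing
        Physical size of one voxel in mm (isotropic scalar), default 1.0.
    modality
        One of :class:`Modality`; free-text strings are coerced.
    """

    data: np.ndarray
    spacing: float = 1.0
    modality: Modality = Modality.OTHER

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim not in (2, 3) or self.data.size == 0:
            raise InvalidParameterError(
                f"image grid must be non-empty 2D or 3D, got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise InvalidParameterError("image contains non-finite values")
        if not self.spacing > 0:
            raise InvalidParameterError(f"spacing must be > 0, got {self.spacing}")
        if isinstance(self.modality, str):
            self.modality = Modality(self.modality.upper())

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def with_data(self, data: np.ndarray) -> "VolumeImage":
        """Copy of this image carrying new intensities (same spacing/modality)."""
        return VolumeImage(np.asarray(data, dtype=np.float64),
                           spacing=self.spacing, modality=self.modality)


@dataclass
class BrainMask:
    """Binary grid congruent with its source image; 1 = brain voxel."""

    data: np.ndarray = field(default_factory=lambda: np.zeros((1, 1)))

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise InvalidParameterError("mask values must be exactly 0 or 1")
        self.data = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def as_bool(self) -> np.ndarray:
        return self.data.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def _require_congruent(*grids: np.ndarray) -> None:
    shapes = {g.shape for g in grids}
    if len(shapes) > 1:
        raise ShapeMismatchError(f"incongruent grid shapes: {sorted(shapes)}")


def load_image(path: str | Path, modality: Modality | str = Modality.OTHER) -> VolumeImage:
    """Read a NIfTI (.nii/.nii.gz) volume or grayscale PNG slice."""
    path = Path(path)
    if path.suffix == ".png":
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path), dtype=np.float64)
        if arr.ndim == 3:  # collapse accidental RGB
            arr = arr.mean(axis=-1)
        return VolumeImage(arr, modality=modality)
    import nibabel as nib

    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    arr = np.asarray(img.get_fdata(), dtype=np.float64)
    arr = np.squeeze(arr)
    return VolumeImage(arr, spacing=float(zooms[0]), modality=modality)


def save_image(img: VolumeImage | BrainMask, path: str | Path) -> Path:
    """Write NIfTI for 3D grids, PNG (16-bit for images, 8-bit for masks) for 2D."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    is_mask = isinstance(img, BrainMask)
    data = img.data
    if path.suffix == ".png":
        import imageio.v3 as iio

        if is_mask:
            iio.imwrite(path, (data * 255).astype(np.uint8))
        else:
            lo, hi = float(data.min()), float(data.max())
            scaled = np.zeros_like(data) if hi == lo else (data - lo) / (hi - lo)
            iio.imwrite(path, np.round(scaled * 65535).astype(np.uint16))
        return path
    import nibabel as nib

    spacing = 1.0 if is_mask else img.spacing
    affine = np.diag([spacing] * data.ndim + [1.0] * (4 - data.ndim))
    out = data.astype(np.uint8) if is_mask else data.astype(np.float32)
    nib.save(nib.Nifti1Image(out, affine), str(path))
    return path
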