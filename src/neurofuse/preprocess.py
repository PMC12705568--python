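"""Image-quality preprocessing: Gaussian smoothing, skull stripping, Z-score.

The smoothing kernel is the Gaussian probability density sampled at integer
voxel offsets and renormalized to unit sum, applied separably along each
spatial axis with edge replication at the boundary.  Skull stripping isolates
the brain as the largest bright connected component (Otsu threshold →
morphological closing → largest component → hole filling).  Z-score
normalization maps in-mask intensities to zero mean and unit population
variance so that structural and functional channels inform downstream fusion
on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import closing, disk, ball

from .image import (
    BrainMask,
    DegenerateInputError,
    InvalidParameterError,
    StrippingFailedError,
    VolumeImage,
    _require_congruent,
)


@dataclass
class GaussianFilterConfig:
    """Discrete Gaussian kernel: standard deviation ``sigma`` (voxels) and
    half-width ``radius`` (defaults to ceil(3*sigma), <0.3% truncated mass)."""

    sigma: float = 1.0
    radius: int | None = None

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise InvalidParameterError(f"sigma must be > 0, got {self.sigma}")
        if self.radius is None:
            self.radius = int(ceil(3 * self.sigma))
        if self.radius < 1:
            raise InvalidParameterError(f"radius must be >= 1, got {self.radius}")


def gaussian_kernel(cfg: GaussianFilterConfig) -> np.ndarray:
    """Separable 1D Gaussian weights at offsets -radius..+radius, unit sum.

    The weights are the normal pdf ``exp(-x^2 / (2 sigma^2)) / (sigma sqrt(2 pi))``
    evaluated at integer offsets about a zero-mean center, then renormalized so
    a constant image passes through the filter unchanged.
    """
    offsets = np.arange(-cfg.radius, cfg.radius + 1, dtype=np.float64)
    pdf = np.exp(-(offsets**2) / (2.0 * cfg.sigma**2)) / (cfg.sigma * np.sqrt(2 * np.pi))
    return pdf / pdf.sum()


def gaussian_smooth(img: VolumeImage, cfg: GaussianFilterConfig) -> VolumeImage:
    """Separable Gaussian convolution along every spatial axis.

    Boundaries use edge replication (scipy 'nearest'), avoiding the dark halo
    zero padding would create at the brain edge.  Output shape equals input
    shape; a normalized kernel means unit DC gain.
    """
    kernel = gaussian_kernel(cfg)
    out = img.data
    for axis in range(out.ndim):
        out = ndimage.convolve1d(out, kernel, axis=axis, mode="nearest")
    return img.with_data(out)


def skull_strip(img: VolumeImage) -> tuple[VolumeImage, BrainMask]:
    """Remove non-brain voxels (scalp, skull, background).

    Otsu-thresholds the foreground, closes small gaps (radius-2 structuring
    element), keeps the largest connected component, and fills interior holes
    (the dark CSF core must stay inside the brain).  Returns the masked image
    and the binary mask.

    Raises
    ------
    StrippingFailedError
        If no foreground voxel survives thresholding (e.g. an all-zero image).
    """
    data = img.data
    if np.ptp(data) == 0:
        raise StrippingFailedError(
            f"skull stripping failed: constant {img.modality.value} image has no foreground"
        )
    thr = threshold_otsu(data)
    fg = data > thr
    if not fg.any():
        raise StrippingFailedError(
            f"skull stripping failed: empty foreground for {img.modality.value} image"
        )
    selem = disk(2) if data.ndim == 2 else ball(2)
    fg = closing(fg, selem)
    labels = label(fg)
    if labels.max() == 0:
        raise StrippingFailedError(
            f"skull stripping failed: no connected component in {img.modality.value} image"
        )
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    fg = labels == int(np.argmax(sizes))
    fg = ndimage.binary_fill_holes(fg)
    mask = BrainMask(fg.astype(np.uint8))
    return img.with_data(np.where(fg, data, 0.0)), mask


def zscore_normalize(img: VolumeImage, mask: BrainMask | None = None) -> VolumeImage:
    """Zero-mean, unit-variance intensity normalization.

    The mean and *population* standard deviation are computed over in-mask
    voxels (all voxels if ``mask`` is None); in-mask voxels are replaced by
    their standard scores and out-of-mask voxels are set to 0.

    Raises
    ------
    DegenerateInputError
        If the in-mask intensities have zero variance (constant image, or a
        single in-mask voxel): a scale cannot be defined.
    """
    data = img.data
    if mask is None:
        sel = np.ones(data.shape, dtype=bool)
    else:
        _require_congruent(data, mask.data)
        sel = mask.as_bool()
    vals = data[sel]
    if vals.size == 0:
        raise DegenerateInputError("empty mask: no voxels to normalize")
    mu = vals.mean()
    sd = vals.std()  # population (ddof=0): unit variance exactly at any n
    if sd == 0:
        raise DegenerateInputError(
            "zero in-mask variance: constant image cannot be Z-score normalized"
        )
    out = np.zeros_like(data)
    out[sel] = (vals - mu) / sd
    return img.with_data(out)
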