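"""Mask-coding fusion of the structural and functional channels.

The structural (MRI) channel is the anatomical reference and is never
modified; the functional (PET) channel is modulated by gray-matter
information before the two are stacked:

* ``simple_concat`` — stack the raw channels (no modulation);
* ``mask_code_fuse`` — hard masking, PET ⊙ binary GM mask;
* ``soft_fuse`` — PET ⊙ gm_prob**alpha, a one-parameter family whose
  alpha = 0 endpoint is plain concatenation and whose alpha = 1 default is
  soft GM modulation (binary gm_prob reproduces hard masking exactly).

Channel order is fixed: channel 0 = MRI, channel 1 = PET.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .image import BrainMask, InvalidParameterError, VolumeImage, _require_congruent


class FusionKind(enum.Enum):
    CONCAT = "concat"
    MASK_HARD = "mask_hard"
    MASK_SOFT = "mask_soft"


@dataclass
class FusedInput:
    """Spatial grid x 2 channels (0 = MRI, 1 = modulated PET) plus provenance."""

    data: np.ndarray  # (..., 2)
    provenance: FusionKind
    alpha: float | None = None

    def __post_init__(self) -> None:
        if self.data.shape[-1] != 2:
            raise InvalidParameterError("fused input must have exactly 2 channels")
        if not np.all(np.isfinite(self.data)):
            raise InvalidParameterError("fused input contains non-finite values")

    @property
    def mri(self) -> np.ndarray:
        return self.data[..., 0]

    @property
    def pet(self) -> np.ndarray:
        return self.data[..., 1]

    def save(self, path: str | Path) -> Path:
        """Write channels as a stacked .npy with a JSON provenance sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.save(path.with_suffix(".npy"), self.data)
        sidecar = {"provenance": self.provenance.value, "alpha": self.alpha}
        path.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True))
        return path.with_suffix(".npy")


def _stack(mri: np.ndarray, pet_mod: np.ndarray, kind: FusionKind,
           alpha: float | None = None) -> FusedInput:
    return FusedInput(np.stack([mri, pet_mod], axis=-1), kind, alpha)


def simple_concat(mri: VolumeImage, pet: VolumeImage) -> FusedInput:
    """Direct two-channel stack of the raw modalities."""
    _require_congruent(mri.data, pet.data)
    return _stack(mri.data, pet.data, FusionKind.CONCAT)


def mask_code_fuse(mri: VolumeImage, pet: VolumeImage, mask: BrainMask) -> FusedInput:
    """Hard mask coding: PET gated voxel-wise by the binary GM mask."""
    _require_congruent(mri.data, pet.data, mask.data)
    return _stack(mri.data, pet.data * mask.data, FusionKind.MASK_HARD)


def soft_fuse(mri: VolumeImage, pet: VolumeImage, gm_prob: np.ndarray,
              alpha: float = 1.0) -> FusedInput:
    """Soft mask coding: PET modulated by the GM probability map to power alpha."""
    if alpha < 0:
        raise InvalidParameterError(f"alpha must be >= 0, got {alpha}")
    gm_prob = np.asarray(gm_prob, dtype=np.float64)
    _require_congruent(mri.data, pet.data, gm_prob)
    if gm_prob.min() < 0 or gm_prob.max() > 1:
        raise InvalidParameterError("gm_prob must lie in [0, 1]")
    return _stack(mri.data, pet.data * gm_prob**alpha, FusionKind.MASK_SOFT, alpha)
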