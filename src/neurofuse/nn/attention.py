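"""Spatial multimodal attention (SMAtt).

A parameter-free attention block: the concatenated two-modality feature map
``W_cat`` (spatial grid x 2H channels) is reweighted voxel-wise by the
elementwise product of its channel-wise average pool (CAP) and channel-wise
max pool (CMP),

    W_catx = W_cat ⊗ CAP(W_cat) ⊗ CMP(W_cat),

with the single-channel attention maps broadcast across channels; the
weighted map is then split into its two modality halves (first H channels =
structural branch, last H = functional branch, matching the concatenation
order) and the halves are averaged into the fused map ``W_fused`` with H
channels.  If an attention map is degenerate (non-finite), the block falls
back to the identity, keeping the raw features.

All operations accept a single map ``(G, X, C)`` or a batch ``(N, G, X, C)``.
"""

from __future__ import annotations

import numpy as np

from ..image import InvalidParameterError
from .engine import DTYPE, Layer


def channel_avg_pool(fmap: np.ndarray) -> np.ndarray:
    """CAP: per-location mean over channels; output keeps a trailing axis of 1."""
    fmap = np.asarray(fmap)
    return fmap.mean(axis=-1, keepdims=True)


def channel_max_pool(fmap: np.ndarray) -> np.ndarray:
    """CMP: per-location maximum over channels; output keeps a trailing axis of 1."""
    fmap = np.asarray(fmap)
    return fmap.max(axis=-1, keepdims=True)


def smatt(w_cat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Apply spatial multimodal attention to a concatenated feature map.

    Returns ``(W_catx, W_fused)``: the attention-weighted map (same shape as
    the input) and the fused map with half the channels.

    Raises
    ------
    InvalidParameterError
        If the channel count is odd (the map cannot be split into halves).
    """
    w_cat = np.asarray(w_cat, dtype=DTYPE)
    c = w_cat.shape[-1]
    if c % 2 != 0:
        raise InvalidParameterError(f"channel count must be even to split halves, got {c}")
    cap = channel_avg_pool(w_cat)
    cmp_ = channel_max_pool(w_cat)
    if not (np.all(np.isfinite(cap)) and np.all(np.isfinite(cmp_))):
        w_catx = w_cat.copy()  # attention failed: retain raw features
    else:
        w_catx = w_cat * cap * cmp_
    h = c // 2
    w_fused = 0.5 * (w_catx[..., :h] + w_catx[..., h:])
    return w_catx, w_fused


class SMAttLayer(Layer):
    """SMAtt as a trainable-graph node with an exact backward pass.

    The block has no parameters, but gradients flow through both the feature
    map and the pooled attention maps (mean: uniform 1/C share; max: routed
    to the arg-max channel, first occurrence on ties).
    """

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        c = x.shape[-1]
        if c % 2 != 0:
            raise InvalidParameterError(f"channel count must be even, got {c}")
        self._x = x
        self._a = channel_avg_pool(x)
        self._arg = x.argmax(axis=-1)
        self._m = np.take_along_axis(x, self._arg[..., None], axis=-1)
        self._identity = not (np.all(np.isfinite(self._a)) and np.all(np.isfinite(self._m)))
        wx = x.copy() if self._identity else x * self._a * self._m
        h = c // 2
        return 0.5 * (wx[..., :h] + wx[..., h:])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dwx = 0.5 * np.concatenate([dy, dy], axis=-1)
        if self._identity:
            return dwx
        x, a, m = self._x, self._a, self._m
        c = x.shape[-1]
        dx = dwx * a * m
        da = (dwx * x * m).sum(axis=-1, keepdims=True)
        dm = (dwx * x * a).sum(axis=-1, keepdims=True)
        dx += da / c
        np.put_along_axis(
            dx, self._arg[..., None],
            np.take_along_axis(dx, self._arg[..., None], axis=-1) + dm, axis=-1)
        return dx
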