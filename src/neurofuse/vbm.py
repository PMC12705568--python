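"""Desk-scale voxel-based morphometry.

Voxel-based morphometry (VBM) compares tissue composition across subjects
voxel by voxel: every brain is mapped into a common stereotactic space
(affine spatial normalization), intensities are decomposed into gray matter /
white matter / CSF probability maps, the gray-matter maps are smoothed, and a
general linear model contrasts subject groups at every voxel to produce a
t-statistic map.  A binary gray-matter mask thresholded from the probability
maps gates the functional channel downstream.

This implementation is deliberately desk-scale: affine-only normalization by
normalized cross-correlation search (no nonlinear warps or atlases) and a
three-component intensity mixture for segmentation (no tissue priors).
Tissue labels follow T1-like contrast — ascending mean intensity is read as
CSF < GM < WM; the convention is configurable via ``tissue_order``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.mixture import GaussianMixture

from .image import (
    BrainMask,
    DegenerateInputError,
    InvalidParameterError,
    VolumeImage,
    _require_congruent,
)
from .preprocess import GaussianFilterConfig, gaussian_smooth

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass
class TissueMaps:
    """Per-voxel posterior probabilities of the three tissue classes.

    In-brain voxels satisfy gm + wm + csf = 1; out-of-mask voxels are (0,0,0).
    """

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray

    def __post_init__(self) -> None:
        _require_congruent(self.gm, self.wm, self.csf)
        for name in ("gm", "wm", "csf"):
            arr = getattr(self, name)
            if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
                raise InvalidParameterError(f"{name} probabilities outside [0, 1]")


@dataclass
class StatMap:
    """Voxel-wise t statistics with their degrees of freedom."""

    t_values: np.ndarray
    df: int


@dataclass
class AffineTransform:
    """Homogeneous (d+1)x(d+1) transform from subject to template coordinates."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        d = m.shape[0] - 1
        if m.shape != (d + 1, d + 1) or not np.allclose(m[-1], np.eye(d + 1)[-1]):
            raise InvalidParameterError("matrix must be homogeneous with last row [0..0 1]")
        if abs(np.linalg.det(m[:d, :d])) < 1e-12:
            raise InvalidParameterError("transform is not invertible")
        self.matrix = m

    @property
    def ndim(self) -> int:
        return self.matrix.shape[0] - 1

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:-1, -1].copy()

    @property
    def scale(self) -> float:
        d = self.ndim
        return float(np.linalg.det(self.matrix[:d, :d]) ** (1.0 / d))


@dataclass
class RegistrationConfig:
    """Search envelope for affine spatial normalization.

    max_translation in voxels, max_rotation in degrees, max_log_scale as
    |ln s|; coordinate-descent refinement halves the step sizes
    ``n_refinements`` times starting from ``initial_steps``
    (translation vox, rotation deg, log-scale).
    """

    max_translation: float = 8.0
    max_rotation: float = 10.0
    max_log_scale: float = 0.12
    coarse_translation_step: float = 2.0
    initial_steps: tuple[float, float, float] = (2.0, 2.0, 0.04)
    n_refinements: int = 5
    smooth_sigma: float = 1.0


def _rotation_matrix(angles_deg: np.ndarray, d: int) -> np.ndarray:
    if d == 2:
        th = np.deg2rad(angles_deg[0])
        c, s = np.cos(th), np.sin(th)
        return np.array([[c, -s], [s, c]])
    rx, ry, rz = np.deg2rad(angles_deg)
    cx, sx, cy, sy, cz, sz = np.cos(rx), np.sin(rx), np.cos(ry), np.sin(ry), np.cos(rz), np.sin(rz)
    mx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    my = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    mz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return mx @ my @ mz


def _params_to_affine(params: np.ndarray, d: int, center: np.ndarray) -> AffineTransform:
    """(translations, angles, log-scale) → subject→template homogeneous matrix.

    x_tpl = s * R * (x_sub - center) + center + t  (rotation/scale about the
    grid center so translation stays interpretable).
    """
    n_ang = 1 if d == 2 else 3
    t = params[:d]
    ang = params[d:d + n_ang]
    s = np.exp(params[d + n_ang])
    a = s * _rotation_matrix(ang, d)
    m = np.eye(d + 1)
    m[:d, :d] = a
    m[:d, -1] = center - a @ center + t
    return AffineTransform(m)


def resample(img: VolumeImage, transform: AffineTransform,
             out_shape: tuple[int, ...]) -> VolumeImage:
    """Linearly resample ``img`` onto a template grid under ``transform``.

    ``transform`` maps subject to template coordinates, so the template grid
    is pulled back through its inverse.
    """
    d = transform.ndim
    inv = np.linalg.inv(transform.matrix)
    out = ndimage.affine_transform(
        img.data, inv[:d, :d], offset=inv[:d, -1], output_shape=out_shape,
        order=1, mode="constant", cval=0.0)
    return img.with_data(out)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else -1.0


def spatial_normalize(
    img: VolumeImage, template: VolumeImage,
    cfg: RegistrationConfig | None = None,
) -> tuple[VolumeImage, AffineTransform]:
    """Affine registration of a skull-stripped subject onto a template.

    Maximizes normalized cross-correlation over translation + rotation +
    isotropic scale: a coarse translation grid seeds coordinate-descent
    hill climbing with geometrically shrinking steps (coarse-to-fine).
    Returns the resampled image (template grid) and the recovered transform.
    """
    cfg = cfg or RegistrationConfig()
    if np.ptp(img.data) == 0 or np.ptp(template.data) == 0:
        raise DegenerateInputError("cannot register constant (empty) images")
    d = img.ndim
    if d != template.ndim:
        raise InvalidParameterError("subject and template dimensionality differ")
    sm = GaussianFilterConfig(sigma=cfg.smooth_sigma)
    sub = gaussian_smooth(img, sm).data
    tpl = gaussian_smooth(template, sm).data
    center = (np.array(tpl.shape, dtype=np.float64) - 1) / 2.0
    n_ang = 1 if d == 2 else 3
    n_par = d + n_ang + 1
    lo = np.concatenate([np.full(d, -cfg.max_translation),
                         np.full(n_ang, -cfg.max_rotation), [-cfg.max_log_scale]])
    hi = -lo

    def score(params: np.ndarray) -> float:
        tr = _params_to_affine(params, d, center)
        inv = np.linalg.inv(tr.matrix)
        warped = ndimage.affine_transform(sub, inv[:d, :d], offset=inv[:d, -1],
                                          output_shape=tpl.shape, order=1)
        return _ncc(warped, tpl)

    # coarse translation-only seeding
    best = np.zeros(n_par)
    axes = [np.arange(-cfg.max_translation, cfg.max_translation + 1e-9,
                      cfg.coarse_translation_step) for _ in range(d)]
    best_score = -np.inf
    for shift in np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, d):
        p = np.zeros(n_par)
        p[:d] = shift
        sc = score(p)
        if sc > best_score:
            best_score, best = sc, p
    # coordinate-descent refinement over all parameters
    steps = np.concatenate([np.full(d, cfg.initial_steps[0]),
                            np.full(n_ang, cfg.initial_steps[1]), [cfg.initial_steps[2]]])
    for _ in range(cfg.n_refinements):
        improved = True
        while improved:
            improved = False
            for k in range(n_par):
                for sgn in (1.0, -1.0):
                    cand = best.copy()
                    cand[k] = np.clip(cand[k] + sgn * steps[k], lo[k], hi[k])
                    sc = score(cand)
                    if sc > best_score + 1e-12:
                        best_score, best = sc, cand
                        improved = True
        steps = steps / 2.0
    transform = _params_to_affine(best, d, center)
    return resample(img, transform, tpl.shape), transform


def segment_tissues(img: VolumeImage, mask: BrainMask, seed: int) -> TissueMaps:
    """Three-class tissue segmentation by a 1D Gaussian intensity mixture.

    Fits a 3-component Gaussian mixture to in-mask intensities (k-means++
    initialization seeded by ``seed``, EM to tolerance 1e-6 or 200
    iterations), relabels components by ascending mean as CSF < GM < WM, and
    returns per-voxel posteriors; out-of-mask voxels get (0, 0, 0).
    """
    _require_congruent(img.data, mask.data)
    sel = mask.as_bool()
    vals = img.data[sel].reshape(-1, 1)
    if vals.shape[0] < 30:
        raise DegenerateInputError(
            f"insufficient data: {vals.shape[0]} in-mask voxels (< 30) for segmentation")
    gmm = GaussianMixture(
        n_components=3, covariance_type="full", tol=1e-6, max_iter=200,
        n_init=1, init_params="k-means++", random_state=int(seed))
    gmm.fit(vals)
    order = np.argsort(gmm.means_.ravel())  # CSF < GM < WM (T1-like)
    post = gmm.predict_proba(vals)[:, order]
    maps = []
    for k in range(3):
        grid = np.zeros(img.shape)
        grid[sel] = post[:, k]
        maps.append(grid)
    csf, gm, wm = maps
    return TissueMaps(gm=gm, wm=wm, csf=csf)


def glm_tmap(groupA: list[np.ndarray], groupB: list[np.ndarray]) -> StatMap:
    """Voxel-wise two-sample t map: the GLM with a single group regressor.

    t = (meanA - meanB) / (s_p * sqrt(1/nA + 1/nB)) with pooled variance
    s_p^2 = ((nA-1) varA + (nB-1) varB) / (nA + nB - 2); voxels with zero
    pooled variance get t = 0.
    """
    if len(groupA) < 2 or len(groupB) < 2:
        raise InvalidParameterError("each group needs at least 2 subjects")
    a = np.stack([np.asarray(g, dtype=np.float64) for g in groupA])
    b = np.stack([np.asarray(g, dtype=np.float64) for g in groupB])
    _require_congruent(a[0], b[0])
    na, nb = a.shape[0], b.shape[0]
    df = na + nb - 2
    var_p = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / df
    se = np.sqrt(var_p * (1.0 / na + 1.0 / nb))
    diff = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    return StatMap(t_values=t, df=df)


def gm_mask(tissues: TissueMaps, threshold: float = 0.5) -> BrainMask:
    """Binary gray-matter mask: gm probability >= threshold (inclusive)."""
    if not 0 < threshold < 1:
        raise InvalidParameterError(f"threshold must be in (0, 1), got {threshold}")
    mask = (tissues.gm >= threshold).astype(np.uint8)
    if mask.sum() == 0:
        logger.warning("gm_mask: empty mask at threshold %.3f", threshold)
    return BrainMask(mask)


def smooth_gm(gm: np.ndarray, fwhm: float = 8.0) -> np.ndarray:
    """Smooth a gray-matter probability map with a Gaussian of given FWHM (voxels)."""
    cfg = GaussianFilterConfig(sigma=fwhm * FWHM_TO_SIGMA)
    return gaussian_smooth(VolumeImage(gm + 0.0), cfg).data
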