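"""Benchmark objectives and planted problems for the swarm optimizer.

These are the standard desk-scale testbeds: a concave quadratic with a known
maximizer (convergence accuracy), a sum of well-separated Gaussian bumps
(multimodal capture — the setting GSO is designed for), and a planted
feature-selection problem with known informative coordinates.
"""

from __future__ import annotations

import numpy as np


def concave_quadratic(center: np.ndarray):
    """``f(p) = -||p - center||^2``; unique maximum at ``center`` with value 0."""
    center = np.asarray(center, dtype=float)
    return lambda p: -float(((np.asarray(p) - center) ** 2).sum())


def gaussian_bumps(centers: np.ndarray, sd: float = 0.3):
    """Sum of isotropic Gaussian bumps at ``centers`` (rows), scale ``sd``."""
    centers = np.asarray(centers, dtype=float)
    return lambda p: float(
        np.exp(-((np.asarray(p) - centers) ** 2).sum(axis=1) / (2 * sd**2)).sum())


TRIMODAL_CENTERS = np.array([[-2.0, -2.0], [2.0, -1.0], [0.0, 2.5]])


def planted_feature_problem(
    n: int = 200, d: int = 40, k: int = 6, shift: float = 2.0,
    n_classes: int = 4, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Four-class data with ``k`` informative features among ``d``.

    Each informative feature receives a random (non-constant) +/- pattern of
    class means separated by ``shift`` standard deviations; the remaining
    ``d - k`` features are pure standard-normal noise.  Returns
    ``(features, labels, informative_indices)``.
    """
    rng = np.random.default_rng(seed)
    y = np.repeat(np.arange(n_classes), n // n_classes)
    x = rng.normal(size=(y.size, d))
    informative = np.sort(rng.choice(d, size=k, replace=False))
    for f in informative:
        pattern = rng.choice([-1.0, 1.0], size=n_classes)
        while len(set(pattern)) < 2:
            pattern = rng.choice([-1.0, 1.0], size=n_classes)
        x[:, f] += shift * pattern[y] / 2.0
    return x, y, informative
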