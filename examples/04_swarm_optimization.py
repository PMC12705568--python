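"""Glowworm swarm optimization on its two benchmark landscapes, plus
bounded hyperparameter tuning in log space.
"""

import numpy as np

from neurofuse import (
    GlowwormSwarm,
    HyperRange,
    SwarmConfig,
    TRIMODAL_CENTERS,
    concave_quadratic,
    gaussian_bumps,
    gws_optimize,
    tune_hyperparameters,
)

center = np.array([0.3, -0.2])
best, fit, trace = gws_optimize(concave_quadratic(center), 2, (-1.0, 1.0),
                                SwarmConfig(seed=0))
print(f"quadratic: best {np.round(best, 4)} (true optimum {center}), "
      f"error {np.linalg.norm(best - center):.4f}")

objective = gaussian_bumps(TRIMODAL_CENTERS, sd=0.3)
cfg = SwarmConfig(seed=0)
swarm = GlowwormSwarm.initialize(2, (np.full(2, -3.0), np.full(2, 3.0)), cfg)
for _ in range(cfg.iterations):
    swarm.iterate(objective)
d = np.linalg.norm(swarm.positions[:, None, :] - TRIMODAL_CENTERS[None], axis=2)
print(f"trimodal: peaks with a worm within 0.3: {(d.min(axis=0) < 0.3).sum()} of 3")

space = {"lr": HyperRange(1e-4, 1e-3, log=True)}
best_cfg, score, _ = tune_hyperparameters(
    lambda c: -(np.log10(c["lr"]) + 3.5) ** 2, space, SwarmConfig(seed=0))
print(f"tuning: best lr {best_cfg['lr']:.2e} (score peak at 3.16e-04)")
# Sub-swarms settle on several optima at once — the behavior that makes this
# metaheuristic suited to multimodal search spaces.
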