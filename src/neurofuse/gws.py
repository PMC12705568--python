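"""Glowworm swarm optimization (GSO) with feature-selection and
hyperparameter-tuning adapters.

Each agent ("glowworm") carries a scalar luciferin level that tracks the
fitness of its position and an adaptive neighborhood range.  One synchronous
iteration has three phases:

1. **Luciferin update** — exponential decay plus a fitness-proportional gain,
   ``k_j <- (1 - rho) k_j + z * I(w_j)``, applied to all worms at once.
2. **Movement** — each worm looks for *strictly brighter* worms within its
   current range, picks one with probability proportional to the luciferin
   excess, and takes a fixed-length step toward it; a worm with no brighter
   neighbor (always including the current brightest) instead takes a random
   step of length at most the step size (the local-search fallback).
3. **Range update** — the neighborhood range moves toward the desired
   neighbor count, ``q <- min(q_t, max(range_min, q + beta (m_s - |N|)))``.

Because movement is attracted only locally, distinct sub-swarms can settle on
distinct optima, which is what makes GSO suitable for multimodal landscapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import InvalidParameterError, NeurofuseError

#: finite stand-in for "minus infinity" fitness: low enough never to win,
#: finite so luciferin stays numerically well-behaved.
REJECT_FITNESS = -1e6


@dataclass
class SwarmConfig:
    """GSO parameters.

    Defaults follow the model's stated operating ranges: population 20-50
    (default 30), luciferin decay rho in (0, 1) with default 0.5 (stated band
    0.4-0.6), luciferin gain z = 0.6 (canonical GSO value), step size 0.05
    (band 0.03-0.1), range gain beta = 0.08, desired neighbor count m_s = 5,
    initial range q0 = 1.0 with cap q_t = 5.0 and floor range_min = 0, and
    100-200 iterations (default 150).
    """

    population: int = 30
    rho: float = 0.5
    z: float = 0.6
    step: float = 0.05
    beta: float = 0.08
    m_s: int = 5
    q0: float = 1.0
    q_t: float = 5.0
    range_min: float = 0.0
    iterations: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.rho < 1:
            raise InvalidParameterError(f"rho must be in (0, 1), got {self.rho}")
        if self.step <= 0:
            raise InvalidParameterError(f"step must be > 0, got {self.step}")
        if self.q0 > self.q_t:
            raise InvalidParameterError(f"q0 ({self.q0}) must not exceed q_t ({self.q_t})")
        if self.population < 2:
            raise InvalidParameterError(f"population must be >= 2, got {self.population}")


@dataclass
class Glowworm:
    """One agent: position w_j, luciferin k_j, adaptive range q_c^j."""

    position: np.ndarray
    luciferin: float
    range: float


@dataclass
class SwarmTrace:
    """Per-iteration record: best-ever fitness, best position, mean luciferin."""

    best_fitness: list[float] = field(default_factory=list)
    best_position: list[np.ndarray] = field(default_factory=list)
    mean_luciferin: list[float] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "iteration": np.arange(len(self.best_fitness)),
            "best_fitness": self.best_fitness,
            "mean_luciferin": self.mean_luciferin,
        })


def luciferin_update(luciferin: float | np.ndarray, fitness: float | np.ndarray,
                     rho: float, z: float) -> float | np.ndarray:
    """Decay-plus-gain luciferin rule ``(1 - rho) k + z I``."""
    if not 0 < rho < 1:
        raise InvalidParameterError(f"rho must be in (0, 1), got {rho}")
    return (1.0 - rho) * luciferin + z * fitness


def neighbor_set(swarm: "GlowwormSwarm", j: int) -> np.ndarray:
    """Indices of strictly brighter worms strictly within worm j's range.

    N_j = { i != j : ||w_i - w_j|| < q_c^j  and  k_j < k_i }.
    """
    d = np.linalg.norm(swarm.positions - swarm.positions[j], axis=1)
    mask = (d < swarm.ranges[j]) & (swarm.luciferin > swarm.luciferin[j])
    mask[j] = False
    return np.flatnonzero(mask)


def select_neighbor(swarm: "GlowwormSwarm", j: int, neighbors: np.ndarray,
                    rng: np.random.Generator) -> int:
    """Sample a neighbor with probability proportional to its luciferin excess."""
    if len(neighbors) == 0:
        raise NeurofuseError(
            f"worm {j} has no neighbors; caller must apply the random-search fallback")
    excess = swarm.luciferin[neighbors] - swarm.luciferin[j]
    probs = excess / excess.sum()
    return int(rng.choice(neighbors, p=probs))


def move(position_j: np.ndarray, position_i: np.ndarray, step: float) -> np.ndarray:
    """Step of fixed length toward a neighbor: w_j + t (w_i - w_j)/||w_i - w_j||."""
    if step <= 0:
        raise InvalidParameterError(f"step must be > 0, got {step}")
    delta = np.asarray(position_i, dtype=float) - np.asarray(position_j, dtype=float)
    dist = np.linalg.norm(delta)
    if dist < 1e-12:
        return np.asarray(position_j, dtype=float).copy()
    return position_j + step * delta / dist


def range_update(range_: float, n_neighbors: int, beta: float, m_s: int,
                 q_t: float, range_min: float) -> float:
    """Adaptive range: grow when under-populated, shrink when crowded, clamped."""
    return min(q_t, max(range_min, range_ + beta * (m_s - n_neighbors)))


class GlowwormSwarm:
    """Mutable swarm state plus the synchronous iteration.

    Positions, luciferin, and ranges are stored as arrays (one row/entry per
    worm).  ``iterate`` runs one full luciferin/movement/range cycle against
    an objective mapping a position vector to a finite fitness.
    """

    def __init__(self, positions: np.ndarray, cfg: SwarmConfig,
                 bounds: tuple[np.ndarray, np.ndarray],
                 luciferin: np.ndarray | None = None,
                 ranges: np.ndarray | None = None):
        self.cfg = cfg
        self.positions = np.asarray(positions, dtype=float).copy()
        p = self.positions.shape[0]
        self.luciferin = (np.zeros(p) if luciferin is None
                          else np.asarray(luciferin, dtype=float).copy())
        self.ranges = (np.full(p, cfg.q0) if ranges is None
                       else np.asarray(ranges, dtype=float).copy())
        self.lo, self.hi = bounds
        self.rng = np.random.default_rng(cfg.seed)
        self.best_position: np.ndarray | None = None
        self.best_fitness = -np.inf

    @classmethod
    def initialize(cls, dims: int, bounds: tuple[np.ndarray, np.ndarray],
                   cfg: SwarmConfig) -> "GlowwormSwarm":
        """Population placed uniformly at random inside the bounds (seeded)."""
        lo, hi = bounds
        rng = np.random.default_rng(cfg.seed)
        pos = rng.uniform(lo, hi, size=(cfg.population, dims))
        swarm = cls(pos, cfg, bounds)
        swarm.rng = rng  # continue the same stream for movement draws
        return swarm

    def worm(self, j: int) -> Glowworm:
        return Glowworm(self.positions[j].copy(), float(self.luciferin[j]),
                        float(self.ranges[j]))

    def _evaluate(self, objective) -> np.ndarray:
        fit = np.array([float(objective(p)) for p in self.positions])
        bad = np.isnan(fit) | (fit == np.inf)
        if bad.any():
            j = int(np.flatnonzero(bad)[0])
            raise NeurofuseError(
                f"objective returned non-finite value at position {self.positions[j]}")
        return fit

    def iterate(self, objective) -> np.ndarray:
        """One synchronous GSO iteration; returns this iteration's fitness vector."""
        cfg = self.cfg
        fitness = self._evaluate(objective)
        k = int(np.argmax(fitness))
        if fitness[k] > self.best_fitness:
            self.best_fitness = float(fitness[k])
            self.best_position = self.positions[k].copy()
        # phase 1: luciferin, all worms simultaneously
        self.luciferin = luciferin_update(self.luciferin, fitness, cfg.rho, cfg.z)
        # phase 2: movement, decisions taken against the pre-movement snapshot
        new_positions = self.positions.copy()
        n_neighbors = np.zeros(len(self.positions), dtype=int)
        for j in range(len(self.positions)):
            nbrs = neighbor_set(self, j)
            n_neighbors[j] = len(nbrs)
            if len(nbrs) > 0:
                i = select_neighbor(self, j, nbrs, self.rng)
                pos = move(self.positions[j], self.positions[i], cfg.step)
            else:  # local random search: step of length <= t in a random direction
                direction = self.rng.normal(size=self.positions.shape[1])
                norm = np.linalg.norm(direction)
                direction = direction / norm if norm > 0 else direction
                pos = self.positions[j] + self.rng.uniform(0, cfg.step) * direction
            new_positions[j] = np.clip(pos, self.lo, self.hi)
        self.positions = new_positions
        # phase 3: adaptive ranges
        for j in range(len(self.positions)):
            self.ranges[j] = range_update(self.ranges[j], int(n_neighbors[j]),
                                          cfg.beta, cfg.m_s, cfg.q_t, cfg.range_min)
        assert np.all(self.ranges >= cfg.range_min) and np.all(self.ranges <= cfg.q_t)
        return fitness


def _as_bounds(dims: int, bounds) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = bounds
    lo = np.broadcast_to(np.asarray(lo, dtype=float), (dims,)).copy()
    hi = np.broadcast_to(np.asarray(hi, dtype=float), (dims,)).copy()
    if np.any(lo > hi):
        raise InvalidParameterError("lower bounds exceed upper bounds")
    return lo, hi


def gws_optimize(objective, dims: int, bounds,
                 cfg: SwarmConfig | None = None,
                 ) -> tuple[np.ndarray, float, SwarmTrace]:
    """Maximize ``objective`` over a box by glowworm swarm optimization.

    Returns the best-ever position, its fitness, and the full trace.  The
    objective must be finite on the bounds (``REJECT_FITNESS`` may be used to
    veto positions); NaN or +inf raises an error naming the position.
    """
    cfg = cfg or SwarmConfig()
    b = _as_bounds(dims, bounds)
    swarm = GlowwormSwarm.initialize(dims, b, cfg)
    trace = SwarmTrace()
    for _ in range(cfg.iterations):
        swarm.iterate(objective)
        trace.best_fitness.append(swarm.best_fitness)
        trace.best_position.append(swarm.best_position.copy())
        trace.mean_luciferin.append(float(swarm.luciferin.mean()))
    return swarm.best_position, swarm.best_fitness, trace


# ---------------------------------------------------------------------------
# adapters


def select_features(features: np.ndarray, labels: np.ndarray,
                    cfg: SwarmConfig | None = None, eval_folds: int = 3,
                    sparsity: float = 0.01) -> np.ndarray:
    """Wrapper feature selection: worms live in [0, 1]^D, a position decodes
    to the mask ``position >= 0.5``, and fitness is the ``eval_folds``-fold
    cross-validated accuracy of a lightweight linear (one-hot ridge)
    classifier on the masked features minus ``sparsity * (selected / D)``.
    The all-zero mask is vetoed (assigned ``REJECT_FITNESS``) and can never
    be returned.

    The ridge fit is closed-form on per-fold Gram matrices precomputed once,
    so a fitness evaluation costs one small linear solve per fold regardless
    of the swarm size.
    """
    from sklearn.model_selection import StratifiedKFold

    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n, d = x.shape
    if d < 2 or n < 10:
        raise InvalidParameterError(f"need >= 2 features and >= 10 samples, got {x.shape}")
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise InvalidParameterError("labels contain a single class")
    cfg = cfg or SwarmConfig()
    skf = StratifiedKFold(n_splits=eval_folds, shuffle=True, random_state=cfg.seed)
    xb = np.hstack([x, np.ones((n, 1))])  # bias column, always retained
    onehot = np.eye(classes.size)[y_idx]
    folds = []
    for tr, te in skf.split(x, y_idx):
        folds.append((xb[tr].T @ xb[tr], xb[tr].T @ onehot[tr], xb[te], y_idx[te]))
    ridge = 1.0

    def objective(position: np.ndarray) -> float:
        mask = position >= 0.5
        if not mask.any():
            return REJECT_FITNESS
        idx = np.append(np.flatnonzero(mask), d)  # masked features + bias
        correct = 0
        for gram, xty, xte, yte in folds:
            a = gram[np.ix_(idx, idx)] + ridge * np.eye(idx.size)
            w = np.linalg.solve(a, xty[idx])
            correct += int(((xte[:, idx] @ w).argmax(axis=1) == yte).sum())
        return correct / n - sparsity * mask.mean()

    best_pos, _, _ = gws_optimize(objective, d, (0.0, 1.0), cfg)
    return best_pos >= 0.5


@dataclass
class HyperRange:
    """A named bounded search dimension; ``log=True`` searches in log10 space
    (appropriate for learning rates)."""

    low: float
    high: float
    log: bool = False

    def decode(self, u: float) -> float:
        if self.log:
            lo, hi = np.log10(self.low), np.log10(self.high)
            return float(10.0 ** (lo + u * (hi - lo)))
        return float(self.low + u * (self.high - self.low))


def tune_hyperparameters(eval_fn, space: dict[str, HyperRange],
                         cfg: SwarmConfig | None = None,
                         ) -> tuple[dict[str, float], float, SwarmTrace]:
    """Maximize ``eval_fn(named config) -> score`` over bounded ranges.

    Worm coordinates live in the unit cube and map (log-)affinely onto each
    named range; returns the best named configuration, its score, and the trace.
    """
    if not space:
        raise InvalidParameterError("hyperparameter space is empty")
    names = list(space)

    def decode(position: np.ndarray) -> dict[str, float]:
        return {nm: space[nm].decode(float(u)) for nm, u in zip(names, position)}

    best_pos, best_fit, trace = gws_optimize(
        lambda p: float(eval_fn(decode(p))), len(names), (0.0, 1.0), cfg)
    return decode(best_pos), best_fit, trace
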