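"""The enriched CNN (ECNN) classifier.

Architecture: one 3-block convolutional branch per modality (3x3 'same'
convolutions with 32/64/128 filters by default, each followed by ReLU and
2x2 max pooling; for a 128x128 input the per-branch feature maps evolve as
128x128x32 -> 64x64x64 -> 32x32x128), branch outputs concatenated along
channels, spatial multimodal attention fusing the halves, then a
batch-normalized fully connected head (256 -> 128 with dropout after each
block) and a softmax over the four diagnostic stages.  An optional binary
mode replaces the softmax with a single sigmoid unit.

Training is plain Adam on categorical cross-entropy with seeded shuffling;
everything is NumPy, so a fixed seed gives bit-identical runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..image import InvalidParameterError
from .attention import SMAttLayer
from .engine import (
    Adam,
    BatchNorm1D,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    MaxPool2,
    ReLU,
    softmax,
    softmax_xent,
)

CLASS_NAMES = ("NC", "SMC", "MCI", "AD")


@dataclass
class NetworkConfig:
    """ECNN hyperparameters.

    Defaults follow the model's canonical settings: conv filters (32, 64,
    128) with 3x3 kernels and 2x2 max pooling, FC sizes (256, 128), dropout
    0.4 (the admissible band is [0.3, 0.5]), Adam with learning rate 3e-4
    inside the tuning range [1e-4, 1e-3], batch size 16, categorical
    cross-entropy.  ``n_branches`` is 2 for two-modality input, 1 for a
    single channel; ``binary`` switches to the sigmoid head.
    """

    conv_filters: tuple[int, int, int] = (32, 64, 128)
    kernel: int = 3
    fc_sizes: tuple[int, int] = (256, 128)
    dropout: float = 0.4
    n_classes: int = 4
    learning_rate: float = 3e-4
    batch_size: int = 16
    epochs: int = 50
    input_size: int = 64
    n_branches: int = 2
    attention: bool = True
    binary: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.3 <= self.dropout <= 0.5:
            raise InvalidParameterError(
                f"dropout must lie in [0.3, 0.5], got {self.dropout}")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise InvalidParameterError("learning_rate, batch_size, epochs must be positive")
        if self.input_size % 8 != 0:
            raise InvalidParameterError(
                f"input spatial size must be divisible by 8 (three 2x2 pools), "
                f"got {self.input_size}")
        if self.n_branches not in (1, 2):
            raise InvalidParameterError("n_branches must be 1 or 2")


class ECNN:
    """Two-branch attention-fused convolutional classifier (see module docs)."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        f1, f2, f3 = cfg.conv_filters
        self.branches = []
        for _ in range(cfg.n_branches):
            layers = []
            cin = 1
            for f in (f1, f2, f3):
                layers += [Conv2D(cin, f, cfg.kernel, self.rng), ReLU(), MaxPool2()]
                cin = f
            self.branches.append(layers)
        side = cfg.input_size // 8
        concat_c = f3 * cfg.n_branches
        if cfg.attention:
            self.head = [SMAttLayer(), Flatten()]
            flat = side * side * (concat_c // 2)
        else:  # ablation: raw concatenated features, no attention fusion
            self.head = [Flatten()]
            flat = side * side * concat_c
        out_units = 1 if cfg.binary else cfg.n_classes
        fin = flat
        for fc in cfg.fc_sizes:
            self.head += [Dense(fin, fc, self.rng), BatchNorm1D(fc), ReLU(),
                          Dropout(cfg.dropout, self.rng)]
            fin = fc
        self.final = Dense(fin, out_units, self.rng)
        self.head.append(self.final)

    def branch_shapes(self, input_size: int | None = None) -> list[tuple[int, int, int]]:
        """Per-branch feature-map shapes after each convolution block."""
        s = input_size or self.cfg.input_size
        shapes = []
        for f in self.cfg.conv_filters:
            shapes.append((s, s, f))
            s //= 2
        return shapes

    def _all_layers(self):
        for branch in self.branches:
            yield from branch
        yield from self.head

    def parameters(self):
        for layer in self._all_layers():
            yield from layer.params()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for a batch ``(N, H, W, n_branches)`` of fused inputs."""
        if x.ndim != 4 or x.shape[-1] != self.cfg.n_branches:
            raise InvalidParameterError(
                f"expected input (N, H, W, {self.cfg.n_branches}), got {x.shape}")
        if x.shape[1] != self.cfg.input_size or x.shape[2] != self.cfg.input_size:
            raise InvalidParameterError(
                f"expected spatial size {self.cfg.input_size}, got {x.shape[1:3]}")
        outs = []
        for b, layers in enumerate(self.branches):
            h = x[..., b:b + 1]
            for layer in layers:
                h = layer.forward(h, training)
            outs.append(h)
        h = np.concatenate(outs, axis=-1) if len(outs) > 1 else outs[0]
        for layer in self.head:
            h = layer.forward(h, training)
        return h

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.head):
            d = layer.backward(d)
        if len(self.branches) > 1:
            f3 = self.cfg.conv_filters[-1]
            splits = [d[..., i * f3:(i + 1) * f3] for i in range(len(self.branches))]
        else:
            splits = [d]
        for layers, db in zip(self.branches, splits):
            for layer in reversed(layers):
                db = layer.backward(db)

    def features(self, x: np.ndarray) -> np.ndarray:
        """Penultimate activations (evaluation mode): the feature pool offered
        to the swarm's feature-selection stage."""
        outs = []
        for b, layers in enumerate(self.branches):
            h = x[..., b:b + 1]
            for layer in layers:
                h = layer.forward(h, False)
            outs.append(h)
        h = np.concatenate(outs, axis=-1) if len(outs) > 1 else outs[0]
        for layer in self.head[:-1]:
            h = layer.forward(h, False)
        return h

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class-probability vectors (evaluation mode: running BN stats, no dropout)."""
        logits = self.forward(x, training=False)
        if self.cfg.binary:
            p = 1.0 / (1.0 + np.exp(-logits[:, 0]))
            return np.stack([1 - p, p], axis=1)
        return softmax(logits)


@dataclass
class TrainedModel:
    """A fitted ECNN with its configuration and per-epoch history."""

    model: ECNN
    config: NetworkConfig
    history: list[dict] = field(default_factory=list)

    def save(self, path: str | Path) -> Path:
        """Checkpoint: parameters as .npz plus a JSON config/history sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"p{i}": v for i, (_, v, _) in enumerate(self.model.parameters())}
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in self.config.__dict__.items()},
                "history": self.history}
        path.with_suffix(".json").write_text(json.dumps(meta, sort_keys=True, indent=1))
        return path.with_suffix(".npz")


def build_ecnn(cfg: NetworkConfig) -> ECNN:
    """Construct an untrained ECNN from its configuration."""
    return ECNN(cfg)


def forward_classify(model: ECNN | TrainedModel, x: np.ndarray) -> np.ndarray:
    """Probability vector(s) for one input ``(H, W, C)`` or a batch ``(N, H, W, C)``."""
    net = model.model if isinstance(model, TrainedModel) else model
    single = x.ndim == 3
    xb = x[None] if single else x
    p = net.predict_proba(np.asarray(xb, dtype=np.float64))
    return p[0] if single else p


def _accuracy(p: np.ndarray, y: np.ndarray) -> float:
    return float((p.argmax(axis=1) == y).mean())


def train(
    model: ECNN,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray] | None,
    cfg: NetworkConfig | None = None,
) -> TrainedModel:
    """Adam optimization of categorical cross-entropy with per-epoch history.

    ``train_set``/``val_set`` are ``(X, y)`` pairs with X of shape
    ``(N, H, W, n_branches)`` and integer labels y.  Shuffling and dropout
    come from the model's seeded generator, so identical seeds give
    bit-identical histories.
    """
    cfg = cfg or model.cfg
    if cfg.binary:
        raise InvalidParameterError(
            "the sigmoid head is a forward-only mode; train with the softmax head")
    x, y = train_set
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y)
    if x.shape[0] == 0:
        raise InvalidParameterError("empty training set")
    if np.unique(y).size < 2:
        raise InvalidParameterError("training set must contain at least 2 classes")
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history: list[dict] = []
    n = x.shape[0]
    for epoch in range(cfg.epochs):
        order = model.rng.permutation(n)
        losses, accs = [], []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward(xb, training=True)
            loss, dlogits = softmax_xent(logits, yb)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            accs.append(float((logits.argmax(axis=1) == yb).mean()))
        rec = {"epoch": epoch, "train_loss": float(np.mean(losses)),
               "train_acc": float(np.mean(accs))}
        if val_set is not None:
            pv = model.predict_proba(np.asarray(val_set[0], dtype=np.float64))
            vloss = -np.log(pv[np.arange(len(val_set[1])), val_set[1]] + 1e-12).mean()
            rec["val_loss"] = float(vloss)
            rec["val_acc"] = _accuracy(pv, np.asarray(val_set[1]))
        history.append(rec)
    return TrainedModel(model=model, config=cfg, history=history)
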