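"""End-to-end orchestration: preprocess -> VBM -> fusion -> train -> evaluate,
plus the ablation sweep over fusion/attention/optimization variants.

A pipeline run takes a phantom cohort (or a written dataset manifest),
preprocesses both channels of every subject (Gaussian smoothing, skull
stripping, Z-score normalization), spatially normalizes the pair onto a
clean template, segments tissues to obtain the gray-matter probability map
and binary GM mask, builds the requested fused input, trains the ECNN, and
scores the held-out test split.  With the swarm stage enabled, the trained
network's penultimate activations become a feature pool: glowworm swarm
optimization selects a subset by cross-validated fitness and a multinomial
logistic classifier on the selected features produces the final test
predictions (select-then-retrain, mirroring the hybrid algorithm's
``SelectFeaturesFromSwarm``/``TrainFinalClassifier`` steps).

Model variants (ablation rows, in reporting order):

====================  ========================================================
``mri_only``          ECNN on the structural channel alone
``pet_only``          ECNN on the functional channel alone
``vbm_only``          ECNN on the gray-matter probability map alone
``concat``            direct two-channel stack, no masking
``mask_hard``         PET gated by the binary GM mask
``mask_soft``         PET modulated by the GM probability map (alpha = 1)
``no_smatt``          soft fusion + swarm feature selection, attention off
``no_gws``            soft fusion + attention, no swarm stage
``full``              soft fusion + attention + swarm feature selection
====================  ========================================================

Every stage is seeded from the single pipeline seed, so a rerun with the
same configuration is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .fusion import mask_code_fuse, simple_concat, soft_fuse
from .gws import SwarmConfig, select_features
from .image import BrainMask, InvalidParameterError, VolumeImage
from .metrics import MetricsReport, evaluate
from .nn import NetworkConfig, build_ecnn, train
from .preprocess import GaussianFilterConfig, gaussian_smooth, skull_strip, zscore_normalize
from .synthetic import CLASS_NAMES, PhantomSpec, make_cohort
from .vbm import RegistrationConfig, gm_mask, resample, segment_tissues, spatial_normalize

VARIANTS = ("mri_only", "pet_only", "vbm_only", "concat", "mask_hard",
            "mask_soft", "no_smatt", "no_gws", "full")

# variant -> (channel recipe, attention on, swarm stage on)
_VARIANT_TABLE = {
    "mri_only": ("mri", True, False),
    "pet_only": ("pet_raw", True, False),
    "vbm_only": ("gm", True, False),
    "concat": ("concat", False, False),
    "mask_hard": ("hard", False, False),
    "mask_soft": ("soft", False, False),
    "no_smatt": ("soft", False, True),
    "no_gws": ("soft", True, False),
    "full": ("soft", True, True),
}


@dataclass
class PipelineConfig:
    """Toggles and sub-configurations of one end-to-end run.

    The default network profile is a reduced desk-scale ECNN (8/16/32
    filters, 20 epochs at 64x64) — same architecture as the canonical
    configuration, sized so a full CPU run takes seconds rather than hours.
    """

    variant: str = "full"
    phantom: PhantomSpec = field(default_factory=lambda: PhantomSpec(n_per_class=40,
                                                                     complementary=True))
    smooth_sigma: float = 1.0
    skullstrip: bool = True
    register: bool = True
    gm_threshold: float = 0.5
    alpha: float = 1.0
    conv_filters: tuple[int, int, int] = (8, 16, 32)
    epochs: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 16
    dropout: float = 0.3
    swarm: SwarmConfig | None = None
    seed: int = 0
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.variant not in _VARIANT_TABLE:
            raise InvalidParameterError(
                f"unknown variant {self.variant!r}; choose from {VARIANTS}")


@dataclass
class PreparedData:
    """Per-subject processed channels, stacked per split."""

    channels: dict[str, dict[str, np.ndarray]]  # split -> name -> (n, H, W)
    labels: dict[str, np.ndarray]

    def stack(self, names: tuple[str, ...], split: str) -> np.ndarray:
        return np.stack([self.channels[split][n] for n in names], axis=-1)


class StageError(RuntimeError):
    """Wraps a failure with the stage and subject where it occurred."""


def _template(spec: PhantomSpec) -> VolumeImage:
    from .synthetic import generate_subject

    clean = replace(spec, noise_sd=0.0, complementary=False)
    pair = generate_subject(clean, 0, 0, jitter=False)
    stripped, _ = skull_strip(pair.mri)
    return zscore_normalize(stripped)


def prepare_inputs(cfg: PipelineConfig) -> PreparedData:
    """Run preprocessing + VBM for every subject and collect channel grids."""
    pairs, splits = make_cohort(cfg.phantom)
    template = _template(cfg.phantom) if cfg.register else None
    reg_cfg = RegistrationConfig(max_translation=4.0, max_rotation=2.0,
                                 max_log_scale=0.05, n_refinements=3)
    smooth = GaussianFilterConfig(sigma=cfg.smooth_sigma)
    channels: dict[str, dict[str, list[np.ndarray]]] = {
        s: {"mri": [], "pet_raw": [], "pet_hard": [], "pet_soft": [], "gm": []}
        for s in ("train", "val", "test")}
    labels: dict[str, list[int]] = {s: [] for s in ("train", "val", "test")}
    for idx, (pair, split) in enumerate(zip(pairs, splits)):
        try:
            # strip on the raw image: the sharp background/brain separation
            # makes the mask insensitive to the intensity composition inside
            # the brain (smoothing first would put the boundary on a ramp)
            if cfg.skullstrip:
                _, mask = skull_strip(pair.mri)
            else:
                mask = BrainMask((pair.mri.data != 0).astype(np.uint8))
            mri = gaussian_smooth(pair.mri, smooth)
            pet = gaussian_smooth(pair.pet, smooth)
            mri = mri.with_data(mri.data * mask.data)
            pet = pet.with_data(pet.data * mask.data)  # co-registered channels
            mri = zscore_normalize(mri, mask)
            pet = zscore_normalize(pet, mask)
            if template is not None:
                mri, transform = spatial_normalize(mri, template, reg_cfg)
                pet = resample(pet, transform, template.shape)
                mask_img = resample(VolumeImage(mask.data.astype(float)),
                                    transform, template.shape)
                mask = BrainMask((mask_img.data >= 0.5).astype(np.uint8))
            tissues = segment_tissues(mri, mask, seed=cfg.seed)
            gmask = gm_mask(tissues, cfg.gm_threshold)
            hard = mask_code_fuse(mri, pet, gmask)
            soft = soft_fuse(mri, pet, tissues.gm, cfg.alpha)
            bucket = channels[split]
            bucket["mri"].append(mri.data)
            bucket["pet_raw"].append(simple_concat(mri, pet).pet)
            bucket["pet_hard"].append(hard.pet)
            bucket["pet_soft"].append(soft.pet)
            bucket["gm"].append(tissues.gm)
            labels[split].append(pair.label)
        except Exception as exc:  # noqa: BLE001 — annotate stage context
            raise StageError(
                f"pipeline failed at subject {idx} ({pair.class_name}, {split}): {exc}"
            ) from exc
    return PreparedData(
        channels={s: {k: np.stack(v) for k, v in d.items() if v}
                  for s, d in channels.items()},
        labels={s: np.asarray(v) for s, v in labels.items()})


def _channel_names(recipe: str) -> tuple[str, ...]:
    return {
        "mri": ("mri",), "pet_raw": ("pet_raw",), "gm": ("gm",),
        "concat": ("mri", "pet_raw"), "hard": ("mri", "pet_hard"),
        "soft": ("mri", "pet_soft"),
    }[recipe]


def _run_variant(cfg: PipelineConfig, data: PreparedData) -> MetricsReport:
    recipe, attention, use_gws = _VARIANT_TABLE[cfg.variant]
    names = _channel_names(recipe)
    xs = {s: data.stack(names, s) for s in ("train", "val", "test")}
    ys = data.labels
    net_cfg = NetworkConfig(
        conv_filters=cfg.conv_filters, dropout=cfg.dropout,
        learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
        epochs=cfg.epochs, input_size=xs["train"].shape[1],
        n_branches=len(names), attention=attention, seed=cfg.seed)
    model = build_ecnn(net_cfg)
    trained = train(model, (xs["train"], ys["train"]), (xs["val"], ys["val"]))
    if use_gws:
        from sklearn.linear_model import LogisticRegression

        feats_tr = model.features(xs["train"])
        feats_te = model.features(xs["test"])
        swarm_cfg = cfg.swarm or SwarmConfig(population=20, iterations=40, seed=cfg.seed)
        mask = select_features(feats_tr, ys["train"], swarm_cfg)
        clf = LogisticRegression(max_iter=2000, random_state=cfg.seed)
        clf.fit(feats_tr[:, mask], ys["train"])
        proba = clf.predict_proba(feats_te[:, mask])
        # classifier classes may be a subset; embed into the 4-class simplex
        preds = np.full((proba.shape[0], 4), 1e-12)
        preds[:, clf.classes_] = proba
        preds /= preds.sum(axis=1, keepdims=True)
        extras = {"selected_features": int(mask.sum()), "feature_pool": int(mask.size)}
    else:
        preds = model.predict_proba(xs["test"])
        extras = {}
    report = evaluate(preds, ys["test"], class_names=CLASS_NAMES)
    report.extras = {"variant": cfg.variant, "seed": cfg.seed,
                     "history": trained.history, **extras}
    return report


def run_pipeline(cfg: PipelineConfig,
                 data: PreparedData | None = None) -> MetricsReport:
    """Execute the configured end-to-end run and return its metrics report.

    ``data`` may carry pre-computed channels (the ablation sweep shares one
    preprocessing pass across variants).  With ``cfg.out_dir`` set, the
    report, history, and confusion matrix are persisted.
    """
    if data is None:
        data = prepare_inputs(cfg)
    report = _run_variant(cfg, data)
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.save(out / "report.json")
        pd.DataFrame(report.extras["history"]).to_csv(out / "history.csv", index=False)
        pd.DataFrame(report.confusion_matrix, index=CLASS_NAMES,
                     columns=CLASS_NAMES).to_csv(out / "confusion.csv")
        scalars = {"accuracy": report.accuracy, "macro_recall": report.macro_recall,
                   "macro_f1": report.macro_f1, "micro_auc": report.micro_auc,
                   "macro_auc": report.macro_auc}
        scalars.update({f"sensitivity_{k}": v for k, v in report.sensitivity.items()})
        scalars.update({f"specificity_{k}": v for k, v in report.specificity.items()})
        pd.DataFrame([scalars]).to_csv(out / "metrics.csv", index=False)
        roc_rows = [{"class": c, "fpr": f, "tpr": t}
                    for c, curve in report.roc.items()
                    for f, t in zip(curve["fpr"], curve["tpr"])]
        pd.DataFrame(roc_rows).to_csv(out / "roc.csv", index=False)
        pr_rows = [{"class": c, "precision": p, "recall": r}
                   for c, curve in report.pr.items()
                   for p, r in zip(curve["precision"], curve["recall"])]
        pd.DataFrame(pr_rows).to_csv(out / "pr.csv", index=False)
    return report


def ablation(cfg: PipelineConfig, variants: tuple[str, ...] = VARIANTS) -> pd.DataFrame:
    """Run several variants on the same data and seed; one result row each.

    Differences between rows are attributable to the variant alone: the
    preprocessing pass, phantom cohort, and seed are shared.  A failing
    variant is marked ``failed`` instead of aborting the sweep.
    """
    if len(set(variants)) != len(variants):
        raise InvalidParameterError("duplicate variant names in ablation list")
    data = prepare_inputs(cfg)
    rows = []
    for name in variants:
        try:
            rep = run_pipeline(replace(cfg, variant=name, out_dir=None), data=data)
            rows.append({"variant": name, "accuracy": rep.accuracy,
                         "macro_f1": rep.macro_f1, "status": "ok"})
        except Exception as exc:  # noqa: BLE001 — sweep must continue
            rows.append({"variant": name, "accuracy": np.nan,
                         "macro_f1": np.nan, "status": f"failed: {exc}"})
    table = pd.DataFrame(rows)
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "ablation.csv", index=False)
        (out / "ablation.md").write_text(table.to_markdown(index=False))
    return table
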