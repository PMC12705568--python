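"""Synthetic co-registered MRI/PET brain phantoms.

The generator emulates the statistical structure of a four-class staged
dementia cohort (NC < SMC < MCI < AD) with balanced class counts: disease
severity monotonically thins a cortical gray-matter annulus and dims a
"hippocampus" proxy blob in the structural channel, and depresses metabolism
in the same blob in the functional channel.  Both channels share the
subject's spatial jitter, so pairs are co-registered by construction;
backgrounds are exactly zero so skull stripping always has a clean
foreground.

Two constructions are available:

* the default *severity-coded* cohort: all class information rides on a
  single severity scalar expressed in both channels (plus noise);
* the *complementary-signal* variant: class identity is a pair of bits, one
  expressed only in the structural channel (annulus thinning) and one only
  in the functional channel (metabolic dip).  Either channel alone can at
  best resolve two of the four classes (~50% Bayes accuracy); only the fused
  pair identifies the class, which is the regime where multimodal fusion
  must beat any unimodal model.

Phantoms are 2D by default (all pipeline stages are dimension-agnostic);
intensities are arbitrary units in [0, 1] before noise.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .image import InvalidParameterError, Modality, VolumeImage, save_image
from .preprocess import GaussianFilterConfig, gaussian_smooth

CLASS_NAMES = ("NC", "SMC", "MCI", "AD")

# complementary-signal class coding: (structural bit, functional bit)
_CLASS_BITS = {0: (0, 0), 1: (1, 0), 2: (0, 1), 3: (1, 1)}


@dataclass
class PhantomSpec:
    """Geometry, effect sizes, and cohort layout of the phantom generator.

    Radii are in voxels for ``image_size`` 64 and scale linearly with size.
    ``severity`` must be strictly increasing NC -> AD.  ``signal_scale``
    multiplies every class-discriminative effect (1.0 = study conditions).
    """

    image_size: int = 64
    severity: tuple[float, float, float, float] = (0.0, 0.2, 0.5, 0.9)
    brain_radius: float = 24.0
    gm_inner: float = 16.0
    csf_radius: float = 8.0
    atrophy_radius: float = 4.5
    max_thinning: float = 3.0      # annulus thinning at severity 1 (voxels)
    max_dimming: float = 0.25      # structural blob intensity drop at severity 1
    max_hypometabolism: float = 0.4  # fractional PET dip in the blob at severity 1
    noise_sd: float = 0.04
    n_per_class: int = 10
    signal_scale: float = 1.0
    complementary: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise InvalidParameterError("n_per_class must be >= 1")
        sev = np.asarray(self.severity, dtype=float)
        if not np.all(np.diff(sev) > 0):
            raise InvalidParameterError("severity must be strictly increasing NC -> AD")
        scale = self.image_size / 64.0
        if self.brain_radius * scale >= self.image_size / 2 - 3:
            raise InvalidParameterError("brain radius does not fit inside the image")
        if not self.csf_radius < self.gm_inner < self.brain_radius:
            raise InvalidParameterError("require csf_radius < gm_inner < brain_radius")


@dataclass
class LabeledPair:
    """One subject: co-registered structural and functional phantoms plus truth."""

    mri: VolumeImage
    pet: VolumeImage
    label: int
    class_name: str
    ground_truth: dict = field(default_factory=dict)


def _subject_rng(spec: PhantomSpec, class_idx: int, subject_seed: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, class_idx, subject_seed])


def generate_subject(spec: PhantomSpec, class_label: int | str,
                     subject_seed: int, jitter: bool = True) -> LabeledPair:
    """Generate one co-registered MRI/PET pair for the given diagnostic class.

    Deterministic in ``(spec, class_label, subject_seed)``.  Structural
    intensities follow T1-like contrast (CSF 0.25 < GM 0.55 < WM 0.75);
    the functional channel is a smooth metabolic field (~0.85) with a
    severity-graded dip in the atrophy blob.  Subject jitter: center +/- 2
    voxels, global intensity +/- 5%; Gaussian noise only inside the brain.
    """
    c = CLASS_NAMES.index(class_label) if isinstance(class_label, str) else int(class_label)
    rng = _subject_rng(spec, c, subject_seed)
    s = spec.image_size
    geo = s / 64.0
    sev = spec.severity[c] * spec.signal_scale
    if spec.complementary:
        amp = spec.severity[-1] * spec.signal_scale
        mri_bit, pet_bit = _CLASS_BITS[c]
        thinning = mri_bit * amp * spec.max_thinning
        dimming = 0.0
        dip = pet_bit * amp * spec.max_hypometabolism
    else:
        thinning = sev * spec.max_thinning
        dimming = sev * spec.max_dimming
        dip = sev * spec.max_hypometabolism

    if jitter:
        center = (s - 1) / 2.0 + rng.uniform(-2.0, 2.0, size=2)
        gain = 1.0 + rng.uniform(-0.05, 0.05)
    else:
        center = np.full(2, (s - 1) / 2.0)
        gain = 1.0
    ii, jj = np.meshgrid(np.arange(s), np.arange(s), indexing="ij")
    r = np.hypot(ii - center[0], jj - center[1])

    brain_r = spec.brain_radius * geo
    gm_in = (spec.gm_inner + thinning) * geo
    csf_r = spec.csf_radius * geo
    brain = r < brain_r
    gm_ring = (r >= gm_in) & brain
    wm = (r >= csf_r) & (r < gm_in)
    csf = r < csf_r
    # atrophy blob centered mid-annulus on the 45 degree diagonal
    blob_d = (spec.gm_inner + spec.brain_radius) / 2.0 * geo
    blob_c = center + blob_d / np.sqrt(2.0)
    blob = (np.hypot(ii - blob_c[0], jj - blob_c[1]) < spec.atrophy_radius * geo) & brain

    mri = np.zeros((s, s))
    mri[csf] = 0.25
    mri[wm] = 0.75
    mri[gm_ring] = 0.55
    mri[blob & gm_ring] -= dimming
    mri *= gain
    mri[brain] += rng.normal(0.0, spec.noise_sd, size=int(brain.sum()))

    pet = np.zeros((s, s))
    pet[brain] = 0.85 * (1.0 - 0.2 * (r[brain] / brain_r) ** 2)
    pet[blob] *= 1.0 - dip
    pet = gaussian_smooth(VolumeImage(pet), GaussianFilterConfig(sigma=1.0)).data
    pet[~brain] = 0.0
    pet *= gain
    pet[brain] += rng.normal(0.0, spec.noise_sd, size=int(brain.sum()))

    truth = {"severity": spec.severity[c], "brain_mask": brain,
             "gm_ring_mask": gm_ring, "atrophy_mask": blob,
             "class_index": c}
    return LabeledPair(
        mri=VolumeImage(mri, modality=Modality.MRI),
        pet=VolumeImage(pet, modality=Modality.PET),
        label=c, class_name=CLASS_NAMES[c], ground_truth=truth)


def _split_counts(n: int, class_idx: int) -> tuple[int, int, int]:
    """Per-class 70/15/15 counts; odd remainders alternate between val and test
    across classes so cohort totals stay exact."""
    n_tr = int(round(0.7 * n))
    rem = n - n_tr
    n_val = rem // 2 + (1 if (rem % 2 and class_idx % 2 == 0) else 0)
    return n_tr, n_val, rem - n_val


def make_cohort(spec: PhantomSpec) -> tuple[list[LabeledPair], list[str]]:
    """All subjects of the balanced cohort plus their train/val/test split.

    The split is stratified per class; subject order within a class is
    shuffled by the spec seed before assignment.
    """
    pairs: list[LabeledPair] = []
    splits: list[str] = []
    rng = np.random.default_rng(spec.seed)
    for c in range(4):
        subjects = [generate_subject(spec, c, k) for k in range(spec.n_per_class)]
        order = rng.permutation(spec.n_per_class)
        n_tr, n_val, _ = _split_counts(spec.n_per_class, c)
        assign = {}
        for pos, idx in enumerate(order):
            assign[idx] = "train" if pos < n_tr else ("val" if pos < n_tr + n_val else "test")
        for k, subj in enumerate(subjects):
            pairs.append(subj)
            splits.append(assign[k])
    return pairs, splits


def generate_dataset(spec: PhantomSpec, out_dir: str | Path) -> Path:
    """Write the cohort as PNG pairs with a manifest CSV; returns the manifest path.

    Manifest columns: subject_id, class, mri_path, pet_path, split.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs, splits = make_cohort(spec)
    rows = []
    for pair, split in zip(pairs, splits):
        sid = f"{pair.class_name}_{len([r for r in rows if r['class'] == pair.class_name]):03d}"
        mri_path = out_dir / f"{sid}_mri.png"
        pet_path = out_dir / f"{sid}_pet.png"
        save_image(pair.mri, mri_path)
        save_image(pair.pet, pet_path)
        rows.append({"subject_id": sid, "class": pair.class_name,
                     "mri_path": mri_path.name, "pet_path": pet_path.name,
                     "split": split})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def complementary_signal_variant(spec: PhantomSpec) -> PhantomSpec:
    """Spec whose class signal is split across the modalities (see module docs)."""
    return replace(spec, complementary=True)


def manifest_hash(manifest: str | Path) -> str:
    """SHA-256 of the manifest file bytes (reproducibility checks)."""
    return hashlib.sha256(Path(manifest).read_bytes()).hexdigest()
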