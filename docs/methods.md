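# Methods

This note documents the models, numerical choices, and known limitations of
the package, in the order the pipeline runs them.

## Preprocessing

The Gaussian filter is the 1D normal pdf sampled at integer voxel offsets
−r..r about a zero-mean center and renormalized to unit sum, applied
separably per axis. Support is fixed at r = ⌈3σ⌉, which truncates less than
0.3% of the kernel mass; renormalization makes the filter exactly
constant-preserving (unit DC gain), and boundary handling is edge
replication so the brain edge acquires no dark halo. σ is in voxels
(default 1.0).

Skull stripping is deliberately simple and reproducible: Otsu threshold →
binary closing with a radius-2 disk (ball in 3D) → largest connected
component → hole filling (the dark CSF core must remain inside the brain).
It assumes a bright head on a darker background, which the phantom generator
guarantees; it is not tuned for real scanner data. An image with no
foreground (e.g. all zeros) raises a stripping error naming the input.

Z-score normalization uses the *population* standard deviation so that the
in-mask output has unit variance exactly at any n; out-of-mask voxels are
set to zero. Constant in-mask intensity (including the single-voxel case)
is a degenerate input and raises rather than returning zeros.

In the end-to-end pipeline the stripping mask is computed on the **raw**
image and smoothing/normalization happen afterwards. On phantoms the raw
background is exactly zero, so the mask boundary is the true brain boundary.
Stripping the smoothed image instead would place the Otsu threshold on the
smoothed edge ramp, making mask size — and therefore the Z-score statistics
of both channels — weakly dependent on the intensity composition inside the
brain. That coupling is a nuisance covariate: in particular it lets a
class-dependent structural change leak into the normalized functional
channel, which would blur the unimodal/fused comparison the package is
designed to expose.

## Voxel-based morphometry (desk scale)

Spatial normalization is affine-only: translation + rotation + isotropic
scale, scored by normalized cross-correlation on lightly smoothed images
(σ = 1), optimized by a coarse translation grid followed by coordinate
descent with 5 step-halvings (initial steps: 2 voxels, 2°, 0.04 log-scale).
Against the spec of classical VBM this omits nonlinear warps, Jacobian
modulation and tissue priors; at phantom scale the affine family contains
the true misalignment (jitter is translation-only), and the recovery
tolerances are pinned by tests (≤ 0.5 voxel translation, ≤ 2% scale). The
transform maps subject to template coordinates with rotation/scale taken
about the grid center; resampling is linear interpolation through the
inverse map.

Tissue segmentation is a three-component 1D Gaussian mixture on in-mask
intensities (scikit-learn, k-means++ init seeded, EM to 1e-6 or 200
iterations), with components relabeled by ascending mean as CSF < GM < WM —
the T1-like contrast convention; for other contrasts the caller can permute
the maps. Fewer than 30 in-mask voxels is rejected as insufficient data.

The statistical stage is the two-sample pooled-variance t statistic per
voxel — the general linear model with a single group-indicator regressor,
the only design the group comparison requires — with df = n_A + n_B − 2 and
t = 0 wherever pooled variance vanishes. No multiple-comparison correction
is applied (none is specified for this pipeline); the null calibration of
the uncorrected 5% level is verified by simulation. On near-deterministic
posterior maps, voxels with tiny but nonzero variance can produce very
large |t|; downstream use is peak localization, which is robust to this.

The binary GM mask thresholds the GM posterior at 0.5, inclusive (≥), so
masks are reproducible at ties. Smoothing of GM maps reuses the Gaussian
filter with FWHM expressed in voxels (σ = FWHM/2.3548, default FWHM 8).

## Fusion

Channel order is fixed (structural first) so downstream weights are
deterministic. The soft-fusion family `PET ⊙ p_GM^α` was chosen as the
minimal one-parameter family containing both the hard-mask variant (binary
p) and plain concatenation (α = 0). Fusion happens at the pixel level for
the network input; the attention block fuses again at the feature level
after the convolutional branches — both placements exist in the ablation
variants.

## Attention network

The attention block is parameter-free: the concatenated branch map is
multiplied voxel-wise by its channel-mean (CAP) and channel-max (CMP) maps,
split into its two modality halves in concatenation order, and the halves
averaged. The broadcast of the G×X×1 maps across all channels is the only
shape-consistent reading of the elementwise product. If an attention map is
non-finite the block degrades to the identity, retaining raw features. The
backward pass is exact: mean pooling contributes a uniform 1/C share, max
pooling routes its gradient to the arg-max channel (first occurrence on
ties), verified against finite differences.

The network itself is implemented in NumPy with explicit forward/backward
layers (im2col convolution, 2×2 max pooling, batch-normalized dense head,
inverted dropout, Adam, seeded He-uniform init). Every random decision
flows from one seeded generator, so training histories are bit-identical
across reruns on the same machine — the property the determinism contracts
rely on. Evaluation mode uses batch-norm running statistics and disables
dropout, making predictions per-sample (batch-permutation consistent).

Canonical configuration: filters (32, 64, 128), 3×3 kernels, FC 256/128,
dropout 0.4 (admissible band 0.3–0.5), Adam with learning rate within
[1e-4, 1e-3], batch 16, four-class softmax; a sigmoid head exists as a
forward-only binary mode. The 128×128 shape chain of the canonical
configuration is contract-tested. The end-to-end pipeline defaults to a
reduced profile — filters (8, 16, 32), 20 epochs at 64×64, learning rate
1e-3, dropout 0.3 — the same architecture sized so a complete CPU run takes
tens of seconds; the phantom problem is comfortably within this capacity,
so the reduction trades no measurable accuracy.

## Glowworm swarm optimization

The update scheme is synchronous: luciferin for all worms, then movement
decisions for all worms against the pre-movement snapshot, then range
updates from the movement-phase neighbor counts. Defaults: ρ = 0.5 (stated
band 0.4–0.6), z = 0.6 (the canonical GSO value; no value is stated for
this pipeline), step t = 0.05 (band 0.03–0.1), β = 0.08, m_s = 5, q₀ = 1,
q_t = 5, q_min = 0, population 30 (band 20–50), 150 iterations (band
100–200). Neighborhood and distance inequalities are strict; the published
neighbor rule is sometimes printed with the luciferin inequality reversed,
and this implementation follows the standard reading — worms pursue
*strictly brighter* neighbors. A worm with no brighter neighbor in range
(always including the current brightest) takes a uniform random step of
length ≤ t, clipped to bounds — the local-search fallback; its form is not
prescribed anywhere, so the simplest isotropic choice is used. The best
position/fitness ever evaluated is recorded separately (elitism recording),
making the reported optimum monotone over iterations without affecting the
dynamics. NaN or +inf fitness raises an error naming the position; a large
negative sentinel (`REJECT_FITNESS`) is the sanctioned way to veto a
position (used for the all-zero feature mask).

Feature selection decodes positions in [0,1]^D at threshold 0.5 and scores
masks by stratified k-fold (default 3) cross-validated accuracy of a
closed-form one-hot ridge classifier minus λ·(selected/D), λ = 0.01. The
ridge fit is solved on per-fold Gram matrices precomputed once, so a fitness
evaluation costs one small linear solve per fold; the bias column is always
retained and the ridge strength is 1. The true fitness function of the
original formulation is unstated; full-network validation accuracy can be
plugged in via `gws_optimize` directly but is far too expensive per
evaluation at desk scale. Hyperparameter tuning maps unit-cube coordinates
(log-)affinely onto named ranges; learning rates are searched in log10
space.

## Synthetic phantoms

The generator emulates a four-class staged cohort (NC, SMC, MCI, AD) with
balanced counts and severity 0.0/0.2/0.5/0.9. Structural channel: a brain
disk (radius 24 at 64×64) with a dark CSF core (r < 8), bright white matter,
and a cortical gray-matter annulus (16–24) whose thickness shrinks with
severity (3 voxels at severity 1) and whose "hippocampus" blob (radius 4.5,
mid-annulus on the diagonal) dims with severity (0.25 at severity 1).
Functional channel: a smooth metabolic field (≈0.85 with mild radial
falloff) depressed in the same blob by up to 40% at severity 1. Subjects
share center jitter (±2 voxels) and intensity gain (±5%) across channels —
co-registration by construction — and receive independent Gaussian noise
(σ = 0.04) strictly inside the brain, so backgrounds are exactly zero.
Splits are stratified 70/15/15 with odd remainders alternating between
validation and test across classes so cohort totals stay exact.

The complementary-signal variant re-codes class identity as two bits —
annulus thinning only in the structural channel (NC/MCI off, SMC/AD on) and
the metabolic dip only in the functional channel (NC/SMC off, MCI/AD on) —
with amplitude tied to the severity scale so `signal_scale = 0` removes all
signal. Either channel alone then separates at most two of four classes
(≈50% Bayes accuracy); only the fused pair identifies the class. This is
the regime in which the fused-beats-unimodal ordering is a property of the
data, not of tuning. In practice unimodal models score somewhat above 50%:
co-registration estimated from the structural image imprints a faint
geometric trace of the structural bit on the resampled functional channel,
exactly as in real co-registered pipelines; the ordering and the gap remain
large.

What passing tests on phantoms do **not** show: robustness to scanner
artifacts, bias fields, anatomical variability, nonlinear deformation, or
PET kinetics — the generator models none of these, and the skull stripper
and affine registration are not expected to transfer to clinical data
unmodified.

## Pipeline and evaluation

Nine variants share one preprocessing pass, one cohort, and one seed, so
ablation differences are attributable to the variant alone. The swarm stage
realizes the select-then-retrain hybrid: the trained network's penultimate
(FC-128) activations form the feature pool, the swarm selects a subset, and
a multinomial logistic classifier on the selected features produces the
final test predictions.

Metrics use the standard definitions (sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP) per class) with macro averaging for multi-class
recall/F1 — chosen because the cohorts are balanced — and one-vs-rest ROC
from a local threshold sweep with trapezoidal AUC (endpoints (0,0) and
(1,1) always included; ties collapsed to the last index per distinct
score), cross-checked against scikit-learn in a test. Micro-average AUC
pools all class scores. Reports serialize to key-sorted JSON with no
timestamps, so identical runs are byte-identical.

## Problem sizes

Defaults throughout are chosen so the full test suite and the acceptance
script each run in minutes on one CPU core: 64×64 phantoms with 40 subjects
per class for end-to-end runs, 10,000 voxels for null calibration, and
swarm populations of 20–30 with 40–150 iterations. All are configuration
fields, and the 128×128 canonical network is exercised where its printed
shape contract is checked.
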