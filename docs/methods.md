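# Methods

This note records the models, conventions and numerical choices behind
`otoseg`, and what the synthetic studies do and do not demonstrate.

## Problem setting

Temporal-bone CT volumes contain the inner-ear labyrinth: the fluid-filled
cochlear spiral, the vestibule, and three semicircular canals, bounded by
dense bone and by the oval- and round-window membranes. Two tasks are
solved jointly: voxel-wise segmentation of that fluid space, and
localization of three landmarks — helicotrema (cochlear apex), oval window,
round window — given as 0-based voxel coordinate vectors. All coordinates
are array-ordered `(axis0, axis1, axis2)`; physical↔voxel conversion
happens only at I/O boundaries (NIfTI and 3DSlicer FCSV carry millimetres;
internally spacing and origin are micrometres).

## Preprocessing

Volumes are first resampled to the isotropic 99 µm working grid (trilinear
for intensities, nearest-neighbor for labels; landmark coordinates scale by
`spacing/target` per axis). Intensities are clipped at the empirical 0.01
and 0.99 quantiles and z-normalized to zero mean, unit SD. Conventions
fixed here: quantiles interpolate linearly between order statistics, and
the SD is the population (ddof = 0) value — both choices are arbitrary but
frozen for reproducibility.

Domain-shifted volumes (different scanners, specimen preservation) are
additionally histogram-matched onto a reference quantile table (256 levels)
built once from the training cohort, optionally per intensity *cluster*
with user-supplied thresholds; cluster discovery is deliberately out of
scope. The order is clip → match → global z-normalize. One limitation is
inherent: quantile matching is monotone and therefore rank-preserving, so
it can map an intensity-inverted volume *into the training range* but can
never restore a flipped foreground/background ordering within a cluster.
The uncertainty machinery (below) is the designated detector for such
inputs.

## Network

Dual-headed 3D U-Net with a shared encoder. Default geometry: 4 stride-2
downsampling steps, channel cascade (32, 64, 128, 256, 320); a 128³ input
yields encoder features at 64³…8³. Building block: *double convolution* =
(norm → 3³ conv → activation) twice — the norm-first order is intentional
and switchable in principle but not exposed, since every configuration here
uses it. Down/upsampling use kernel-2 stride-2 (transposed) convolutions;
channel count is constant across a level transition; decoders concatenate
the (optionally attention-gated) encoder skip after upsampling. Heads are
1×1×1 convolutions: 1 sigmoid channel (segmentation), 3 linear channels
(heatmaps). Deep supervision adds auxiliary heads at decoder levels 1..L−1
(resolutions 1/2, 1/4, …); auxiliary targets are strided labels
(nearest-neighbor) and re-rendered Gaussians with coordinates and spread
divided by the resolution factor (spread floored at 0.5 voxel).

The attention gate is the additive formulation: skip and gating signal
(the decoder feature after upsampling, at skip resolution) are projected by
1×1×1 convolutions to half the skip channels, summed, rectified, projected
to one channel, and squashed by a sigmoid; the coefficient multiplies the
skip voxel-wise. Placement is configurable per head or global.

Ablation axes exposed in `NetworkConfig`: depth/channels, instance vs
batch norm (with an implicit batch of one, batch norm differs only through
its running statistics in evaluation mode), activation
(leaky-ReLU slope 0.025 default; ReLU, PReLU, GELU, SiLU, Mish), attention
placement, deep supervision, and single-task variants (`tasks=
"segmentation"` or `"heatmap"` drop the other decoder entirely).

Initialization is uniform with fan-in bounds, drawn from a generator seeded
by `NetworkConfig.seed`; a build is a pure function of (config, seed) and
forward passes are bitwise-deterministic on CPU.

### Why a NumPy engine

The network, reverse-mode autodiff, conv3d/transposed-conv kernels, norm
layers and AdamW/SGD live in `otoseg.nn` (~700 lines). Convolutions are
slab-wise im2col GEMMs with a bounded scratch buffer, so a default-config
encoder pass over a 128³ chunk fits comfortably in memory and runs in tens
of seconds on one core — adequate for the desk-scale studies this package
targets, and free of any GPU/framework dependency. The engine preserves
float64 end-to-end when fed float64, which the finite-difference gradient
checks and the gradient-accumulation equivalence test exploit; training
runs in float32.

## Losses

Composite objective: segmentation term + heatmap term, summed over
supervision terminals with weights (1, 0.5, 0.25, 0.125) normalized to
sum 1 (the weighting is not prescribed anywhere authoritative; this
geometric decay is a common default). Segmentation default is BCE + soft
Dice with smoothing ε = 1e−5; variants: pure Dice, squared Dice
(squared sums in the denominator), log-cosh Dice, pure BCE. Heatmap term is
the voxel-mean MSE (mean, not sum, so the scale is chunk-size invariant).
Weight decay (λ = 0.025 default) is applied decoupled inside the optimizer
step and never added to the reported loss.

## Heatmap targets and decoding

Targets are α·exp(−r²/(2β²)) — β acts as a standard deviation in voxel
units. The schedule ("gamma") raises α and tightens β at iteration
milestones: (α, β) = (1, 6) → (5, 4) → (10, 2) at 0%, 20% and 50% of the
run; lookups are piecewise-constant and right-continuous, and monotonicity
(α non-decreasing, β non-increasing) is enforced at construction. The
milestone fractions rescale automatically to shorter runs. Decoding is the
per-channel argmax with ties broken toward the lexicographically smallest
index; no sub-voxel refinement, so decoded coordinates are integral and
localization error is naturally quantized (hence the ~1-voxel noise floor).

## Training

One iteration = one chunk forward + loss + backward. Parameters update
every N iterations with the *mean* of the accumulated gradients (N = 10
default, 15 in the gold configuration), making the effective step invariant
to N — verified against the large-batch computation to 1e−5 relative in
float64. Learning rate follows a trapezoid: linear warmup (10% of
iterations), plateau (60%), linear anneal to zero; peak 1e−3 for AdamW.
Every 750 iterations (full scale) the model is validated: chunked
prediction per validation instance, DSC/IoU on the binarized map, MSE/MAE
on heatmaps, plus the training-loss snapshot. Both the best-validation-DSC
and the last parameters are checkpointed; DSC ties resolve to the later
iteration. Cross-validation uses independent seeded resampling per fold
(each fold freshly splits instances into train and validation), not a
strict partition.

Augmentation protocols: *alpha* = fixed quarter-turn rotations about axis 0
plus free-angle rotations up to 30°; *beta* = fixed rotations about all
three axes and 45° free rotations. Both optionally rescale contrast
(×0.85–1.15) and add Gaussian (σ = 0.08 on normalized intensities) or
Poisson noise (rate 60 per intensity unit, applied after shifting to a
positive range since normalized intensities are signed). Per-transform
probabilities default to 0.5. Fixed rotations are exact voxel permutations;
free rotations interpolate intensities trilinearly, labels
nearest-neighbor, and transport landmarks with the exact rotation matrix
about the chunk center (verified against one-hot voxel oracles).

## Inference and uncertainty

Whole volumes are chunked (128³, stride 25; the final origin per axis snaps
to `dim − chunk`, guaranteeing coverage; axes smaller than the chunk are
zero-padded symmetrically and cropped after fusion; strides larger than the
chunk are rejected since they provably leave gaps). Overlapping predictions
fuse by unweighted voxel means. TTA applies the 10 exact rotations per
chunk, inverse-rotates both heads' outputs, and averages; the segmentation
supersamples' per-voxel population SD (ddof = 0, computed in float64, with
bitwise-identical supersamples mapping to exactly zero) aggregates across
chunks like any other map. Its volume mean is the scalar
out-of-distribution signal. Binarization threshold is 0.5; landmarks are
decoded from the fully aggregated heatmap volume so the argmax is global.

## Evaluation metrics

DSC, IoU and volumetric similarity on binary masks (both-empty convention:
1); the identity IoU = DSC/(2 − DSC) holds exactly. HD and ⟨HD⟩ are
computed between the full foreground voxel *sets* via Euclidean distance
transforms — HD is the max of the two directed maxima, ⟨HD⟩ the mean of the
two directed means — and verified exactly against an all-pairs brute-force
oracle; an empty mask raises rather than reporting 0. Landmark deviation is
the per-landmark Euclidean distance in voxel units plus their mean. Table
aggregation reports mean, sample SD (ddof = 1) and median per column — note
the deliberate asymmetry with the population SD used for TTA voxel
uncertainty, mirroring the different roles (inter-instance spread vs
within-voxel spread over a fixed 10-sample ensemble). The worst-case
cochlear-duct-length error is (dev_helicotrema + dev_round_window) ×
voxel size, reported in millimetres.

## Synthetic phantoms and the scaled-down study

The phantom emulates the labyrinth's *testable structure*, not its
anatomy: a conical-spiral tube (radius shrinking linearly over 2.5 turns)
for the cochlea, three orthogonal tori for the canals, an ellipsoid
vestibule; helicotrema = the spiral's apical endpoint, windows = two disc
patches on the vestibule boundary. Intensities are two-phase (bone ≈ 1800,
fluid ≈ 300, arbitrary CT-like units) plus Gaussian noise (σ = 60, a
realistic ~4% of dynamic range); rotations are applied to the geometry
before rasterization, so labels and landmarks stay exact. Cohorts jitter
turns, radii (±10%) and orientation (±15°). Foreground occupies 1–3% of
the volume, matching the sparsity of temporal-bone CT.

The scaled-down study (`otoseg.study`) trains a 2-level network (channels
8/16/24, no deep supervision or attention) on 15 phantoms of 32³ voxels for
400 iterations (accumulation 5, peak lr 2e−3, protocol alpha, schedule
gamma rescaled) and evaluates 5 held-out phantoms. These sizes are the
package's standard desk-scale conditions: large enough that the joint task
is non-trivial (landmarks sit a few voxels apart on a curved, noisy
structure), small enough to run in minutes on one core. Held-out metrics
are computed without TTA — rotational TTA is the tool for rotation-shifted
external data, and here feeds the uncertainty contrast instead, where the
out-of-distribution inputs are contrast-inverted (dry-specimen analog)
phantoms that are z-normalized but not histogram-matched.

What passing these studies shows: the full pipeline — normalization,
chunking, augmentation-consistent geometry, heatmap scheduling, the
optimizer loop, TTA and the metric suite — is wired correctly and can fit
a genuinely 3D joint task to high overlap (DSC ≳ 0.9) with few-voxel
localization error, and the TTA-SD signal separates shifted inputs by an
order of magnitude. What it does not show: performance on real CT — the
phantom has no partial-volume effects, beam hardening, anatomical
variability beyond parameter jitter, annotation noise, or the thin
bone/membrane interfaces that dominate real error budgets.

## Known limitations

- Histogram matching cannot repair rank-inverting domain shifts (by
  design; see Preprocessing).
- Argmax decoding quantizes landmarks to whole voxels; no center-of-mass
  refinement.
- The NumPy engine is single-threaded compute; full-scale (75k-iteration,
  128³) training is out of its intended envelope.
- Batch size is fixed at one chunk per forward pass; effective batches come
  from gradient accumulation only.
- No post-processing (largest-component extraction, shape priors) is
  applied to segmentations — metrics reflect raw model output, and
  dissociated false-positive islands are possible.
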