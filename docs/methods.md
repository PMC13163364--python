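# Methods

`priorseg` implements a prior-guided volumetric segmentation framework for
kidney-transplant MRI and the evaluation protocol around it. This note
documents the model, the numerical choices, the synthetic data world, and
what the tests do and do not establish.

## Problem setting

Transplanted kidneys vary strongly in position and orientation across
patients (surgical placement), and several clinically relevant MR sequences
(T2-weighted, BOLD, diffusion-weighted) offer low or heterogeneous
kidney-to-background contrast. Purely image-driven segmentation networks
struggle exactly where the image evidence is weakest, so the framework
conditions a generative adversarial segmentation network on two data-driven
priors computed from the training fold:

1. a **probabilistic appearance map** `P_app : Ω → [0,1]` — spatially
   stratified intensity statistics;
2. an **anatomical shape prior** `S : Ω → [0,1]` — the voxelwise mean of
   the training masks.

The network input is the three-channel condition volume `c = (g, P_app, S)`
on a common kidney-centered lattice, and the output is a logit volume
thresholded at 0.5.

## Appearance prior

Each axial slice is partitioned into concentric **iso-contour bands** of
fixed in-plane thickness around the reference boundary `∂M_z`: band
`c = max(1, ceil(d / thickness))` where `d` is the unsigned Euclidean
distance to the boundary, capped at `N_c`; bands extend on both sides of
the contour and boundary voxels (d = 0) belong to band 1. Bands localize
intensity statistics: the same gray value can be kidney-typical near the
boundary and background-typical further out.

For each banded voxel a neighborhood response is accumulated over the
voxels within in-plane Chebyshev radius `r` on slices `z−1, z, z+1` that
share the center's band label:

    Φ(x, y, z) = Σ_k Σ_(i,j)∈N_r  I(i, j, k).

For histogramming, Φ is divided by the number of contributing voxels and
rounded, so the response lives on the same quantized intensity scale
(`{0..255}` by default) regardless of neighborhood occupancy; without this
normalization the histogram domain would depend on how many same-band
neighbors a voxel happens to have, and gray-level tolerance windows would
be meaningless. Per band, foreground and background histograms `H_c^K`,
`H_c^B` of these response levels are accumulated over all training
subjects.

At evaluation the kidney likelihood of a voxel with response level `I` in
band `c` is

    P = H_c^K(I) / (H_c^K(I) + H_c^B(I)).

Empty bins fall back to symmetric pooling over `{I−δ, I+δ}` for
δ = 1, 2, 3 (both sides jointly, first δ with support wins); with no
support within the tolerance the voxel receives the neutral value 0.5.
Voxels outside any band also carry 0.5.

**Inference-time banding.** The held-out subject has no reference contour.
Bands for its appearance map are computed from the boundary of the
binarized shape prior (`S ≥ 0.5`) on the common ROI grid — the only
mask-free, anatomy-shaped reference available. For train/test consistency
the same prior-derived band field is used when building the *condition
channel* of training subjects as well (their own masks are still used for
histogram accumulation, where ground truth is legitimately available).

Defaults: `N_c = 8` bands of thickness 1 voxel, radius `r = 1`, 256
intensity levels, `δ_max = 3`. Fine bands preserve the spatial locality
that motivates the prior; both parameters are configurable.

## Shape prior

`S(x) = (1/N) Σ_n M_n(x)` over the training-fold masks on the common ROI
grid. Values are exact rationals `k/N`; the prior is recomputed per
cross-validation fold and per modality. No parametric shape model is
imposed: transplant cohorts are too variable for landmark or PCA shape
spaces, and the frequency atlas is assumption-free. Ties at the 0.5
binarization threshold resolve to foreground, matching the network's
output threshold convention.

Averaging masks voxelwise requires correspondence across subjects. The
only alignment the protocol applies is kidney-centered ROI cropping to a
fixed per-cohort size (training subjects: own mask centroid; held-out
subject: the reference-cohort mean centroid, the only mask-free estimate).
No deformable registration is performed.

## Adversarial network

The generator is a residual 3D U-Net operating on the condition volume.
All strides are anisotropic `(1, 2, 2)`: MRI voxels are much coarser
through-slice than in-plane, so the slice axis is never downsampled.
Encoder channels double per level (64 → 512 in the full preset; the tiny
CPU preset uses 8 → 64); the decoder restores resolution via trilinear
upsampling and residual decoding blocks (two conv–norm–ReLU units with an
identity shortcut, 1×1×1-projected when widths differ) fed by skip
connections. The discriminator is a conditional 3D PatchGAN: it scores the
(mask, condition) concatenation as a spatial grid of patch logits rather
than a single scalar, penalizing locally implausible structure everywhere.

Losses (BCE-with-logits against 1/0 grids at the patch resolution):

    L_D = ½ [BCE(D(y, c), 1) + BCE(D(ŷ, c), 0)]
    L_G = BCE(D(ŷ, c), 1) + λ_rec ‖ŷ − y‖₁,   λ_rec = 200

with ŷ the generator's sigmoid output (the ℓ1 operand is the probability,
keeping the term bounded). Training alternates one D step and one G step
per sample at batch size 1 with Adam (lr 4 × 10⁻⁴, betas (0.5, 0.999) —
the conventional conditional-GAN setting). No learning-rate schedule and no
augmentation. When a validation split is given, the epoch with the best
mean validation Dice is kept (checkpoint selection); the selection rule is
an artifact decision, as is the 1:1 D/G alternation.

**Backend.** The networks are implemented directly on numpy with explicit
backprop: convolutions are lowered to a patch-buffer GEMM, and each layer's
analytic gradient is verified against finite differences in the test
suite. This keeps the package free of deep-learning framework dependencies
and fully deterministic on CPU for a fixed seed; it is also why the test
presets are small. Batch normalization at batch size 1 normalizes each
channel over its spatial extent and keeps running moments for evaluation
passes; those moments are part of the checkpoint state.

## Metrics

Dice and IoU are voxel-count ratios (both-empty pairs score 1 by
convention). HD95 and ASSD operate on boundary voxels (foreground voxels
with a face-adjacent background neighbor, volume faces counting as
background) with distances in millimetres under the anisotropic header
spacing. Both statistics are taken over the *pooled symmetric* distance
list — every boundary voxel of each mask to the nearest boundary voxel of
the other — with the 95th percentile computed by linear interpolation
between order statistics. The directional-max convention for HD95 exists in
the literature; the pooled-symmetric one is declared here and fixed so
results are bit-stable. Empty predictions raise at the metric level and are
recorded as NaN sentinels with an exclusion flag by the pipeline.

## Cross-validation and ablation protocol

Leave-one-out over subjects, per modality. Per fold, the reference set is
shuffled with a seeded generator and split 80/20 into training and
validation (`n_val = max(1, round(0.2 |R|))`). Priors are built from the
reference set only; the held-out mask is read exclusively at evaluation —
an audit test verifies that deleting the held-out subject's data after
condition construction leaves priors and trained checkpoints byte-identical.

Input configurations: `raw` (uncropped grayscale, 1 channel), `roi`
(kidney-centered crop, 1 channel), `roi_prob` (ROI, P_app, P_app) and
`full` (ROI, P_app, S). The network's input width adapts per
configuration.

Aggregates report per-metric mean, std, and a seeded nonparametric
percentile-bootstrap 95% CI (2000 resamples) across subjects — the CI
method is distribution-free and not otherwise specified by the protocol.
Configuration pairs are compared with two-sided Wilcoxon signed-rank tests
on per-subject differences, Benjamini–Hochberg-corrected across the metric
family within a modality.

## Synthetic phantoms

The phantom generator emulates the statistical challenges the method
targets, not MR physics. Each subject is a single connected kidney-like
object — an ellipsoid with per-subject random in-plane rotation (±20°),
center jitter, semi-axes, and an optional boundary dent (a hilum-like
concavity) — rendered analytically so masks are exact. Images are
two-level fields (fg/bg means) degraded by a smooth multiplicative bias
field (2–3 random low-frequency cosine modes, amplitude 0.2, a standard
inhomogeneity surrogate) and additive Gaussian noise. Modality presets fix
the contrast-to-noise ordering observed across sequences: `dw_like`
(CNR 10) > `bold_like` (2.75, plus a through-slice signal-decay surrogate)
> `t2_like` (1.6). The default test grid is 16×64×64 with spacing
(4, 0.72, 0.72) mm — divisible by 8 in-plane for the 4-level network and
fast on CPU. Unless given explicitly, semi-axis and jitter ranges scale
proportionally with the grid (clamped so the jittered object stays inside
it), so smaller test grids carry geometrically similar cohorts.

What the phantoms do **not** model: anatomy beyond one convex-ish organ,
susceptibility artifacts, partial-volume effects at boundaries, multi-echo
or multi-b-value structure, or inter-scanner variation. A green end-to-end
test therefore establishes that the pipeline's machinery (priors,
conditioning, adversarial training, evaluation, no-leakage bookkeeping) is
correct and that the priors carry usable information under the stated
noise/contrast regimes — not that the reported patient-data accuracy would
be reproduced.

## Scaled-down evaluation worlds

Training a 3D GAN on CPU bounds what the default test run can afford. The
end-to-end acceptance check runs the stated phantom world (12 subjects,
16×64×64, high-contrast preset) with the tiny network preset, 30 epochs
and the first 3 LOOCV folds. The ablation-ordering check runs a
low-contrast cohort at reduced scale (8 subjects, 8×32×32 grid, 10
epochs, 3 folds) and averages each configuration's mean Dice over 3 seeds
before comparing; single-fold Dice at this scale is noisy, and the
ordering claim concerns the information content of the inputs, not any
single run. Both checks assert scale-free properties (threshold accuracy;
monotone ordering with a small tolerance), not patient-data accuracy
figures.

## Numerical conventions

* Axis order `(z, y, x)`, 0-based, slice axis first; NIfTI I/O transposes
  accordingly and reads spacing from the header.
* Intensities are min–max quantized to 256 integer levels per subject
  before histogramming (constant volumes map to zero); gray-level
  tolerance operations presume an integer scale.
* ROI crops zero-pad out-of-bounds regions for both image and mask.
* Ties: sigmoid output exactly 0.5 ⇒ foreground; shape prior exactly at
  threshold ⇒ foreground; band distance 0 ⇒ band 1.
* All randomness flows through seeded `numpy` generators; fixed seeds
  reproduce cohorts, fold plans, and training histories exactly on a
  fixed BLAS backend.

## Known limitations

* The numpy backend is single-sample and CPU-bound; the full 64→512
  preset is exercised for its contracts, not trained to convergence in
  tests.
* The appearance prior assumes the binarized shape prior is a usable band
  reference at inference; with very small reference cohorts (N ≲ 4) the
  prior's 0.5 level set can be coarse.
* Phantom realism is deliberately limited (see above); absolute metric
  values on phantoms do not transfer to patient data.
* LOOCV variance estimates are optimistic relative to repeated k-fold;
  the significance machinery reports what the protocol defines, nothing
  more.
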