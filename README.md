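# priorseg

Prior-guided 3D adversarial segmentation of transplanted kidneys in MRI.

Automated kidney delineation is the prerequisite for quantitative graft
assessment (volume, oxygenation, diffusion biomarkers), but transplant MRI
is a hostile setting for purely image-driven networks: surgical placement
makes kidney position and orientation highly variable across patients, and
sequences like T2-weighted and BOLD MRI offer low kidney-to-background
contrast with strong intensity inhomogeneity. `priorseg` addresses this by
conditioning a volumetric adversarial segmentation network on two
data-driven priors computed from the training cohort, and ships the full
evaluation protocol (leave-one-out cross-validation, input ablation,
paired significance testing) plus a synthetic phantom generator so the
entire pipeline is testable without patient data.

## The model

For a grayscale volume `g` on lattice Ω, the network input is the
three-channel condition volume

```
c = (g, P_app, S)
```

* **Appearance prior** `P_app(x) ∈ [0,1]`: each slice is partitioned into
  concentric iso-contour bands of fixed thickness around the kidney
  boundary; per band, foreground/background histograms of a 3-slice
  same-band neighborhood intensity response Φ are accumulated over the
  training subjects, and a voxel with response level `I` in band `c`
  scores `H_c^K(I) / (H_c^K(I) + H_c^B(I))`, with symmetric gray-level
  pooling `I ± δ` (δ ≤ 3) on empty bins and a neutral 0.5 fallback.
* **Shape prior** `S(x) = (1/N) Σ_n M_n(x)`: the voxelwise frequency atlas
  of the training-fold masks on a common kidney-centered ROI grid.

The generator is a residual 3D U-Net (anisotropic strides (1,2,2) — the
slice axis is never downsampled; encoder widths 64→512, trilinear
upsampling, residual decoding blocks); the discriminator is a conditional
3D PatchGAN scoring (mask, condition) patches. Training minimizes

```
L_D = ½ [BCE(D(y,c), 1) + BCE(D(ŷ,c), 0)]
L_G = BCE(D(ŷ,c), 1) + λ_rec ‖ŷ − y‖₁ ,   λ_rec = 200
```

with Adam (lr 4e-4, batch size 1); masks are `sigmoid(logit) ≥ 0.5`.
Everything — including the 3D conv nets with backprop — runs on numpy/BLAS,
so results are deterministic on CPU for a fixed seed; gradients are
verified against finite differences in the test suite.

## Worked example

Run a scaled-down leave-one-out cross-validation on a synthetic
high-contrast (DW-like) phantom cohort with the full three-channel
condition:

```python
from priorseg import PhantomConfig, make_cohort, plan_loocv
from priorseg.gan import TINY_GENERATOR, TINY_DISCRIMINATOR
from priorseg.pipeline import PipelineConfig, run_fold

pairs, manifest = make_cohort(PhantomConfig(n_subjects=12, modality_preset="dw_like", seed=11))
subjects = dict(enumerate(pairs))
cfg = PipelineConfig(roi_size=(16, 48, 48), gen=TINY_GENERATOR,
                     disc=TINY_DISCRIMINATOR, epochs=30, seed=11)
for plan in plan_loocv(sorted(subjects), seed=11)[:3]:
    row, art, gen = run_fold(subjects, plan, "full", cfg)
    print(f"held-out {row['subject']}: dice={row['dice']:.4f} "
          f"hd95={row['hd95']:.2f}mm assd={row['assd']:.2f}mm")
```

Output (one fold ≈ 2 min on one CPU core):

```
held-out 0: dice=0.9738 hd95=0.72mm assd=0.07mm
held-out 1: dice=0.9611 hd95=0.72mm assd=0.11mm
held-out 2: dice=0.9787 hd95=0.72mm assd=0.08mm
```

Dice is the volumetric overlap of predicted and reference masks (1.0 is
perfect); HD95 and ASSD are boundary disagreements in millimetres under the
anisotropic voxel spacing (4, 0.72, 0.72) mm — sub-voxel here.

The same protocol is scriptable from the shell:

```bash
priorseg phantom --out cohort/ --n-subjects 12 --preset dw_like --seed 11
priorseg loocv --cohort cohort/ --out results/ --input-config full --n-folds 3 --seed 11
priorseg ablation --cohort cohort/ --out results/ --seed 11   # raw/roi/roi_prob/full + Wilcoxon-BH
```

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from
scratch: it generates a fresh phantom cohort from the given seed, executes
three LOOCV folds of the full prior-conditioned pipeline (priors built per
fold from the reference subjects only, GAN trained, held-out subject
scored), prints the per-fold and aggregate metrics, and writes the results
JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

```
src/priorseg/
  grid.py        NIfTI I/O, (z,y,x) lattice types, ROI standardization, quantization
  appearance.py  contour bands, neighborhood response, histograms, likelihood map
  shape.py       cohort-average shape prior
  nn.py          numpy conv-net layers with explicit backprop (im2col GEMM)
  gan.py         residual 3D U-Net, conditional PatchGAN, losses, training loop
  metrics.py     Dice / IoU / HD95 / ASSD (mm, pooled-symmetric surfaces)
  phantom.py     synthetic MRI phantom cohorts (pose, contrast, bias, noise)
  pipeline.py    LOOCV harness, ablation configs, aggregation, significance
  cli.py         `priorseg` command-line interface
docs/methods.md  model assumptions, numerical conventions, limitations
```
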