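# Methods

## The problem

Quantitative T1ρ (spin-lattice relaxation in the rotating frame) of knee
cartilage tracks proteoglycan loss in early osteoarthritis, but conventional
mapping needs several spin-lock-prepared volumes (typically TSL = 0/10/30/50 ms)
fitted voxelwise, which costs scan time. This package implements an accelerated
alternative: predict the T1ρ map from a *reduced* acquisition — one anatomical
I0-like volume (a PD-weighted image, or the TSL = 0 volume) plus a single
T1ρ-weighted volume at non-zero TSL — with a learned regressor, and benchmark
it against the classical fits.

## Signal model and fitting

Magnitude signal under spin-lock preparation follows the two-parameter
mono-exponential

    I(TSL) = I0 · exp(−TSL / T1ρ).

`relaxometry` provides:

- the forward model (`signal_intensity`);
- the closed-form two-point inversion `T1ρ = (TSL_k − TSL_0) / ln(I_0/I_k)`;
- a vectorized Levenberg–Marquardt NLLS fitter over (I0, T1ρ) for K ≥ 2
  samples, initialized from the log-linear regression of ln I on TSL,
  converging on a relative parameter step below 1e−8 (≤ 200 iterations),
  with box constraints T1ρ ∈ [1, 500] ms and I0 ∈ [0, 10·max(I)].
  Out-of-bound optima are clamped and flagged, never silently returned;
  voxels with any non-positive sample are marked invalid rather than fitted.
  The initialization makes the fitter deterministic, and on two points it
  reproduces the closed form exactly.

Four-point NLLS over the full grid serves as the reference ("ground truth")
map in every experiment, as in clinical practice; the bounds deliberately
bracket the physiologic cartilage range (≈ 20–80 ms) with a wide margin so
that clamping signals model violation, not a tight prior.

PD-weighted images have contrast *comparable* to TSL = 0 but no exact signal
relation to it, so two-point fitting with a PD image as I0 is ill-posed; the
package implements it anyway as the cautionary reference (it inflates regional
error by an order of magnitude) and flags such runs as model-nonconforming.

## Predictor architectures

Both predictors consume two channels — the I0-like volume and the
T1ρ-weighted volume — normalized per subject by the mean I0-source intensity
inside the ROI bounding box (subject-level, so the I_0/I_k ratio that encodes
T1ρ is preserved; slice-level scaling would break it).

**Range limiter.** Every regressor output x passes through

    ŷ = clip(ReLU(x) + y_min, y_min, y_max),   (y_min, y_max) = (10, 100) ms,

pinning predictions to a physiologic window and zeroing the gradient of
grossly mispredicted voxels. The limiter's worked values: x = −3 → 10 ms,
x = 10⁶ → 100 ms.

**2D U-Net.** A standard encoder–decoder with two Conv3×3–BatchNorm–ReLU
blocks per level, 2×2 max pooling, nearest-neighbor 2× upsampling with skip
concatenation, and a 1×1 regressor head. Default depth 4 / 32 base channels;
the desk-scale preset trains depth 3 / 8 base channels (see *Problem sizes*).
Input patches are 64×64; whole-slice inference uses a sliding window (stride
32, overlaps averaged, smaller slices reflect-padded).

**1D MLP.** A linear stem lifting the (I0, Ik) pair to 64 features, four
FC–ReLU–BatchNorm blocks with residual skips, and a linear head. It predicts
each voxel independently; on noise-free pairs it learns the analytic inverse
of the signal model to a held-out MAPE well under 2% (the
universal-approximation behavior the approach relies on). Whether the MLP
uses the limiter is exposed as a flag (default on, for parity with the U-Net).

**ms-affine head.** Between the final layer and the limiter both models apply
a fixed affine rescaling x_ms = 45·z + 40. Networks initialize near z ≈ 0, so
predictions start mid-window (≈ 50 ms) and the optimizer works on O(1)
activations; without it, reaching ms-scale outputs from small random
initialization consumes most of the decayed learning-rate budget.

The engine behind both models is a compact NumPy neural-network library
(`t1rho.nn`): channels-last tensors, im2col-GEMM convolutions, explicit
backward passes verified against finite differences to ~1e−7 relative,
float32 compute (switchable to float64 for gradient checks), and
deterministic initialization given a seed.

## Training recipes

Both models minimize L1 (MAE) loss in ms. The U-Net trains on randomly
cropped 64×64 patches; crops are centered on a cartilage voxel with
probability 0.8 (`roi_bias`, the "higher probability around the ROI"), else
uniform. Augmentation applies random flips (p = 0.5/axis), rotation ±15°,
translation ±8 px with identical geometry to inputs and target, and Gaussian
noise (σ = 2% of the patch intensity scale) to inputs only. The MLP trains on
ROI voxel vectors in shuffled batches of 512.

Optimizers: Adam for the U-Net, RMSProp for the MLP, both with initial
learning rate 1e−3, weight decay 3e−4, and exponential decay by 0.9 applied
per epoch (`lr(e) = 1e−3 · 0.9^e`; the decay granularity is a package choice —
the recipe's source states only that the rate decayed as training progressed).
Final-epoch weights are used; there is no early stopping or checkpoint
selection.

In the default (unmasked) regime the U-Net loss is averaged over voxels with
a *trusted* target — those where the reference NLLS fit converged. This keeps
air and non-conforming marrow (whose "ground truth" is meaningless) out of
the objective while still exposing the network to them as input context. With
`roi_loss_only` (the masked regime) the loss is restricted to cartilage
voxels, and `mask_to_roi` zeroes non-cartilage input voxels, reproducing the
masked-input experiment.

Supervision: networks are trained against the four-point NLLS maps (not the
phantom's generating field), mirroring the fact that real studies only ever
have fitted references.

## Evaluation protocol

Cross-validation is stratified k-fold (default 5-fold at full scale, 3-fold
at desk scale): every subject is predicted exactly once, by the model whose
training folds exclude it, and the fold bookkeeping is asserted at run time.
Stratification uses the cohort's binary patient/volunteer label as the joint
stratum.

Per subject, over the cartilage ROI (and per subregion):

| metric | definition | units |
|---|---|---|
| MAE | mean \|y − ŷ\| | ms |
| MAPE | mean \|y − ŷ\|/y × 100 | % |
| RE | \|mean y − mean ŷ\| | ms |
| RPE | RE / mean y × 100 | % |
| Bias | mean ŷ − mean y (signed) | ms |
| %Bias | Bias / mean y × 100 | % |

RE/RPE are reported as magnitudes with the sign carried by Bias; printed
regional-error equations admit either reading, and this convention keeps
RE ≤ MAE (triangle inequality) and |cohort bias| ≤ mean RE, both asserted in
tests. Cohort figures are mean ± sample SD (n−1) across subjects; a single
subject reports SD 0 by convention. The cohort %Bias denominator is
subject-level by default, with a cohort-level option
(`pct_bias_denominator="cohort"`). The working performance target is RPE < 5%.

SSIM-within-ROI (Gaussian window, σ = 1.5, 11×11 support, shared data range
= max − min over both volumes, averaged over ROI voxels of the full SSIM map)
is the inter-contrast alignment check; the phantom's default PD surrogate
scores ≈ 0.97, and a rigid-shift stressor (`misalignment_mm`) lets users
probe registration sensitivity.

## The synthetic phantom

No public multi-TSL knee dataset exists, so the `phantom` module generates
the study conditions at desk scale (default grid 8×128×128, cartilage on the
middle 6 slices, spacing 3×1×0.8 mm):

- **Geometry.** Femoral cartilage as a 3–4 px annulus arc under the condyle,
  lateral/medial tibial cartilage as upper caps of two ellipses, patellar
  cartilage as a thin anterior band (labels 1–4); surrounding soft tissue;
  bone interiors; air outside.
- **T1ρ field.** Region bases 50/45/45/55 ms (femoral/tibial×2/patellar)
  plus a smooth ±10 ms perturbation, clipped to [25, 80] ms — bracketing the
  ≈ 45 ms cohort mean of mixed OA/healthy knees; conforming background tissue
  at 30 ms. Per-subject global offsets (+0..8 ms for "patients", −4..0 ms for
  "volunteers", 3:1 ratio) give the stratification label physiological
  meaning.
- **Out-of-model region.** Bone marrow renders as I(TSL) = c·(0.8 +
  0.2·exp(−TSL/150)) with bright c — a slow offset decay the two-parameter
  model cannot represent, occupying `ood_fraction` (default 8%) of non-ROI
  tissue. This is what makes the unmasked-vs-masked experiment meaningful.
- **Noise.** Rician: out = sqrt((I+n₁)² + n₂²), σ = (mean cartilage I0)/SNR,
  default SNR 30. Magnitude images, hence the positive bias at low SNR
  (verified by Monte Carlo).
- **PD surrogate.** pd = 1.2 · I(TSL=0)^0.9 · B(x) with B a smooth ±15%
  multiplicative bias field, plus an independent noise draw — similar but not
  identical contrast, so that NLLS on it fails while learning succeeds. The
  true joint distribution of PD vs TSL=0 contrast is unknowable without
  scanner data; these parameters tune the surrogate's difficulty, they do not
  claim in-vivo fidelity.

Everything is a pure function of (spec, seed): cohorts are bitwise
reproducible, and per-subject seeds derive from the master seed.

**What the phantom does not emulate:** FSE echo-train blurring, B0/B1
inhomogeneity, fat signal, k-space sampling, partial-volume anatomy, or
realistic PD contrast. Passing results show the pipeline recovers T1ρ under
the stated noise and bias models — not that it matches in-vivo performance.

## Problem sizes (desk scale)

The reference recipes (1 000 epochs, 40 subjects) are scaled down so a full
simulate → cross-validate → evaluate run fits one CPU:

- cohort: 12 subjects, 3 folds; ~4 700 cartilage voxels each.
- MLP preset: 200 epochs, batch 512 (~1–2 s/epoch/fold).
- U-Net preset: depth 3, 8 base channels, 6 patches/slice, batch 6, 25
  epochs. With per-epoch 0.9 decay the learning-rate mass beyond epoch 25 is
  ≈ 7% of the total, so longer schedules buy little; the small batch raises
  optimizer steps per epoch at constant FLOPs, which is what the
  decayed-schedule budget rewards. The preset keeps geometric augmentation
  but injects no extra Gaussian noise: the rendered inputs already carry the
  acquisition's Rician noise, and stacking more noise on top measurably
  biases the learned inversion within the short schedule.
- the limiter, loss, optimizers, learning rates, decay, weight decay, patch
  size, batch 512, and the ROI-bias probability keep their reference values.

## Design choices on genuinely open points

- NLLS algorithm details (variant, initialization, bounds) are not in the
  main source text: Levenberg–Marquardt with log-linear initialization was
  chosen for determinism and exact agreement with the two-point closed form.
- U-Net/MLP widths and depths are unstated at the source: defaults are
  "standard U-Net" proportions and a 4×64 skip-MLP, CPU-trainable.
- Nearest-neighbor (not bilinear) decoder upsampling: its adjoint is exact
  block summation, which keeps the hand-written backward pass simple and
  testable; at 64-px patches the difference is not measurable.
- Sliding-window stride (32) and overlap averaging are package choices; a
  constant-output model yields stride-invariant maps (tested).
- Non-ROI voxels of output maps are 0 with `valid = False`; evaluation only
  ever reads inside the ROI.
- Fold stratification reduces "gender and OA severity" to the single joint
  stratum label the cohort generator provides.

## Known limitations

- The NumPy engine is CPU-bound; training wall-time, not statistics, sets
  the desk-scale problem sizes.
- No Rician-bias-corrected maximum-likelihood fitting; at SNR 30 the bias is
  negligible relative to the regional errors studied, but at much lower SNR
  the NLLS reference itself would drift.
- BatchNorm statistics are batch-dependent, so bitwise reproducibility holds
  for fixed seeds and single-threaded execution, not across BLAS builds.
- The phantom's PD surrogate difficulty is parameterized, not validated
  against scanners; regional errors on it should be read as relative
  comparisons between methods, not absolute clinical accuracy.
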