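# t1rho — accelerated T1ρ mapping of knee cartilage

T1ρ (spin-lattice relaxation in the rotating frame) is a compositional MRI
marker of cartilage proteoglycan content, used for early osteoarthritis
assessment. Conventional mapping acquires several spin-lock-prepared volumes
(spin-lock times TSL = 0/10/30/50 ms) and fits the mono-exponential decay

    I(TSL) = I0 · exp(−TSL / T1ρ)

per voxel — robust, but slow to acquire. This package implements and evaluates
an accelerated alternative: predict the voxelwise T1ρ map from a **reduced
acquisition** — one anatomical I0-like volume (a PD-weighted image or the
TSL = 0 volume) plus a single T1ρ-weighted volume — using either

- a **2D U-Net** with a prediction-range limiter
  `ŷ = clip(ReLU(x) + y_min, y_min, y_max)`, (10, 100) ms by default, trained
  on 64×64 patches and applied with sliding-window inference, or
- a **1D skip MLP** over (I0, Ik) voxel intensity pairs,

benchmarked against closed-form two-point fitting and multi-point
Levenberg–Marquardt NLLS. For the PD-based input pair no signal model links
the two contrasts, so classical fitting is not applicable — only the learned
predictors are.

The package is aimed at quantitative-MRI researchers prototyping reduced
acquisition strategies. Since no public multi-TSL knee dataset exists, a
first-class synthetic phantom module generates knee-like cohorts (curved
cartilage bands with labeled subregions, conforming background tissue, an
out-of-model bright "bone marrow" region, Rician noise, a PD-like surrogate
contrast) so every stage is testable end to end. The evaluation protocol is
the full study design: stratified k-fold cross-validation with per-subject
MAE / MAPE / RE / RPE / Bias over the cartilage ROI, summarized as
mean ± SD, with RPE < 5% as the working performance target.

## Worked example

```bash
python examples/01_fit_t1rho_map.py
```

```
cartilage voxels fitted : 4734
mean T1rho (truth)      : 58.11 ms
mean T1rho (NLLS fit)   : 58.81 ms
MAE  4.13 ms | MAPE 7.04% | RPE 1.193% | bias +0.694 ms
  femoral         n=2328  MAE 4.23 ms  RPE 1.267%
  lateral_tibial  n=960   MAE 4.65 ms  RPE 1.356%
  medial_tibial   n=960   MAE 3.50 ms  RPE 0.887%
  patellar        n=486   MAE 3.84 ms  RPE 1.058%
```

One synthetic subject at cartilage SNR 30: the voxelwise error (MAE ≈ 4 ms)
reflects the noise floor, while the regional error (RPE ≈ 1%) — the quantity
clinical reads care about — is far smaller because noise averages out over a
region. `examples/02_two_point_vs_multipoint.py` shows two-point fitting
matching the four-point reference on model-conforming contrasts and failing
by ~20 ms when a PD-weighted image is misused as I0;
`examples/03_mlp_learns_the_signal_model.py` trains the MLP to a sub-percent
match with the analytic inversion; `examples/04_crossval_reduced_acquisition.py`
runs a full 12-subject cross-validated study.

## Command line

```bash
t1rho simulate --out cohort/ --subjects 12 --seed 1   # write a phantom cohort
t1rho fit --subject cohort/sub-001 --out maps/        # voxelwise NLLS map
t1rho crossval --config run.yaml --seed 1 --out out/  # CV train + predict + metrics
t1rho predict --checkpoint model.npz --i0 ... --ik ... --roi ... --out pred.nii.gz
t1rho evaluate --pred ... --truth ... --roi ... --out metrics.csv
```

Volumes and masks are NIfTI-1 with JSON sidecars (contrast tag, TSL in ms);
configurations are YAML; metrics land in CSV stamped with the config hash and
master seed.

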