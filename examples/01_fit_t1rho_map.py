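"""Fit a voxelwise T1rho map from a multi-TSL phantom acquisition.

Generates one synthetic knee subject (four spin-lock times: 0/10/30/50 ms,
cartilage SNR 30), fits the mono-exponential signal model per voxel with
Levenberg-Marquardt NLLS, and compares the fitted map to the generating field.
"""
import numpy as np

from t1rho.metrics import compute_subject_metrics
from t1rho.phantom import DEFAULT_PROTOCOL, PhantomSpec, generate_cohort
from t1rho.relaxometry import fit_volume

subject = generate_cohort(1, PhantomSpec(snr=30.0), DEFAULT_PROTOCOL, seed=42)[0]

fitted = fit_volume(subject.volumes, DEFAULT_PROTOCOL, roi=subject.roi, method="nlls")
rep = compute_subject_metrics(fitted, subject.truth, subject.roi, subregions=True)

sel = subject.roi.mask
print(f"cartilage voxels fitted : {int(sel.sum())}")
print(f"mean T1rho (truth)      : {subject.truth.values[sel].mean():.2f} ms")
print(f"mean T1rho (NLLS fit)   : {fitted.values[sel].mean():.2f} ms")
print(f"MAE  {rep.mae:.2f} ms | MAPE {rep.mape:.2f}% | RPE {rep.rpe:.3f}% | bias {rep.bias:+.3f} ms")
for name, sub in rep.subregions.items():
    print(f"  {name:<15s} n={sub.n_voxels:<5d} MAE {sub.mae:.2f} ms  RPE {sub.rpe:.3f}%")
# The voxelwise MAE reflects the Rician noise at SNR 30; the regional error
# (RPE, the clinical figure of merit) is far smaller because noise averages
# out over the region.
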