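"""Evaluation statistics for T1rho maps.

Per subject, over the cartilage ROI (or one labeled subregion):

    MAE   = mean |y - yhat|                      (ms, voxelwise)
    MAPE  = mean |y - yhat| / y * 100            (%)
    RE    = |mean(y) - mean(yhat)|               (ms, regional)
    RPE   = RE / mean(y) * 100                   (%)
    Bias  = mean(yhat) - mean(y)                 (ms, signed)
    %Bias = Bias / mean(y) * 100                 (%)

RE/RPE are reported as magnitudes, with the signed quantity carried by Bias.
Cohort summaries are mean +- sample SD across subjects. SSIM-within-ROI
verifies inter-contrast alignment.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from .core import REGION_LABELS, ROIMask, T1rhoMap

__all__ = [
    "MetricsReport",
    "CohortSummary",
    "compute_subject_metrics",
    "compute_region_metrics",
    "summarize_cohort",
    "ssim_roi",
]

METRIC_NAMES = ("mae", "mape", "re", "rpe", "bias", "pct_bias")


@dataclass
class MetricsReport:
    mae: float
    mape: float
    re: float
    rpe: float
    bias: float
    pct_bias: float
    n_voxels: int
    mean_truth: float
    mean_pred: float
    region: str = "all"
    subject_id: str | None = None
    model_conforming: bool = True
    subregions: dict[str, "MetricsReport"] = field(default_factory=dict)


@dataclass
class CohortSummary:
    """Across-subject mean and sample SD of each metric, plus the cohort bias
    (mean of the per-subject signed biases)."""

    mean: dict[str, float]
    sd: dict[str, float]
    n_subjects: int
    cohort_bias: float
    cohort_pct_bias: float


def _selection(pred: T1rhoMap, truth: T1rhoMap, roi: ROIMask, label) -> np.ndarray:
    if pred.shape != truth.shape or pred.shape != roi.shape:
        raise ValueError("pred, truth and ROI must share one grid")
    sel = roi.mask if label == "all" else roi.region(int(label))
    sel = sel & truth.valid
    if not np.any(sel):
        raise ValueError(f"empty selection for region {label!r}")
    if np.any(truth.values[sel] <= 0):
        raise ValueError("ground truth must be strictly positive on the selection")
    return sel


def compute_region_metrics(pred: T1rhoMap, truth: T1rhoMap, roi: ROIMask, label="all") -> MetricsReport:
    """Metrics over one region (``"all"`` = unified cartilage, or a label 1-4)."""
    sel = _selection(pred, truth, roi, label)
    y = truth.values[sel]
    yhat = pred.values[sel]
    mean_y = float(y.mean())
    mean_yhat = float(yhat.mean())
    bias = mean_yhat - mean_y
    re = abs(bias)
    return MetricsReport(
        mae=float(np.abs(y - yhat).mean()),
        mape=float((np.abs(y - yhat) / y).mean() * 100.0),
        re=re,
        rpe=re / mean_y * 100.0,
        bias=bias,
        pct_bias=bias / mean_y * 100.0,
        n_voxels=int(sel.sum()),
        mean_truth=mean_y,
        mean_pred=mean_yhat,
        region="all" if label == "all" else REGION_LABELS[int(label)],
    )


def compute_subject_metrics(
    pred: T1rhoMap,
    truth: T1rhoMap,
    roi: ROIMask,
    label="all",
    subregions: bool = False,
) -> MetricsReport:
    """Subject-level metrics; with ``subregions`` also per cartilage subregion
    (skipping subregions absent from the mask)."""
    rep = compute_region_metrics(pred, truth, roi, label)
    if subregions and label == "all":
        for lbl, name in REGION_LABELS.items():
            if np.any(roi.region(lbl) & truth.valid):
                rep.subregions[name] = compute_region_metrics(pred, truth, roi, lbl)
    return rep


def summarize_cohort(reports, pct_bias_denominator: str = "subject") -> CohortSummary:
    """Mean +- sample SD of each metric across subjects.

    ``pct_bias_denominator`` selects the %Bias convention for the cohort
    figure: "subject" averages the per-subject %Bias values; "cohort" divides
    the cohort bias by the mean of the subjects' ground-truth means.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("no reports to summarize")
    if pct_bias_denominator not in ("subject", "cohort"):
        raise ValueError("pct_bias_denominator must be 'subject' or 'cohort'")
    mean, sd = {}, {}
    for m in METRIC_NAMES:
        vals = np.array([getattr(r, m) for r in reports], dtype=np.float64)
        mean[m] = float(vals.mean())
        sd[m] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    cohort_bias = float(np.mean([r.bias for r in reports]))
    if pct_bias_denominator == "cohort":
        denom = float(np.mean([r.mean_truth for r in reports]))
        cohort_pct_bias = cohort_bias / denom * 100.0
    else:
        cohort_pct_bias = mean["pct_bias"]
    return CohortSummary(
        mean=mean,
        sd=sd,
        n_subjects=len(reports),
        cohort_bias=cohort_bias,
        cohort_pct_bias=cohort_pct_bias,
    )


def ssim_roi(a: np.ndarray, b: np.ndarray, roi: ROIMask) -> float:
    """Structural similarity between two volumes, averaged inside the ROI.

    SSIM is computed per slice with an 11-tap Gaussian window (sigma 1.5) over
    a shared data range (max - min over both volumes), and the full SSIM map
    is averaged over ROI voxels only.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.shape != roi.shape:
        raise ValueError("volumes and ROI must share one grid")
    if not np.any(roi.mask):
        raise ValueError("empty ROI")
    data_range = float(max(a.max(), b.max()) - min(a.min(), b.min()))
    if data_range == 0:
        return 1.0
    total, count = 0.0, 0
    for s in range(a.shape[0]):
        m = roi.mask[s]
        if not np.any(m):
            continue
        _, smap = structural_similarity(
            a[s],
            b[s],
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            data_range=data_range,
            full=True,
        )
        total += float(smap[m].sum())
        count += int(m.sum())
    return total / count
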