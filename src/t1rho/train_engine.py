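"""Training machinery: patch sampling, augmentation, ROI masking, the two
training recipes (U-Net / MLP), and stratified k-fold cross-validation.

Training targets are T1rho maps in ms. Inputs are the two contrast volumes of
an I0-Ik combination, normalized per subject by the mean I0-source intensity
inside the ROI bounding box so arbitrary scanner units cancel. Loss is L1; in
the default (unmasked) regime it is averaged over voxels with a trusted
target, with ``roi_loss_only`` it is restricted to cartilage voxels.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.model_selection import StratifiedKFold

from .core import ROIMask, T1rhoMap, WeightedVolume
from .nets import (
    MLPConfig,
    SkipMLP,
    UNet2D,
    UNetConfig,
    build_mlp,
    build_unet,
)
from .nn.optim import Adam, RMSProp

__all__ = [
    "Combo",
    "TABLE_COMBOS",
    "subject_input_volumes",
    "AugmentConfig",
    "TrainConfig",
    "FAST_UNET_TRAIN",
    "FAST_MLP_TRAIN",
    "FAST_UNET_NET",
    "FoldSplit",
    "make_folds",
    "sample_patches",
    "augment_patch",
    "mask_to_roi",
    "SliceSample",
    "prepare_slice_samples",
    "extract_voxel_pairs",
    "normalization_scale",
    "train_unet",
    "train_mlp",
    "run_cross_validation",
    "CrossValResult",
]


# ---------------------------------------------------------------------------
# input combinations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Combo:
    """One I0-Ik input combination: I0 from PD or the TSL=0 volume, Ik at a
    non-zero TSL."""

    i0: str  # "pd" | "tsl0"
    ik_tsl: float

    def __post_init__(self) -> None:
        if self.i0 not in ("pd", "tsl0"):
            raise ValueError("i0 source must be 'pd' or 'tsl0'")
        object.__setattr__(self, "ik_tsl", float(self.ik_tsl))
        if self.ik_tsl <= 0:
            raise ValueError("ik_tsl must be a non-zero TSL")


#: The six admissible combinations (I0 in {PD, TSL=0}; Ik TSL in {10, 30, 50}).
TABLE_COMBOS = tuple(
    Combo(i0, tsl) for i0 in ("pd", "tsl0") for tsl in (10.0, 30.0, 50.0)
)


def subject_input_volumes(subject, combo: Combo):
    """The (I0-source, Ik) volume pair of a subject for a combination."""
    i0_vol = subject.pd_volume if combo.i0 == "pd" else subject.volume_at(0.0)
    return i0_vol, subject.volume_at(combo.ik_tsl)


def normalization_scale(i0_vol: WeightedVolume, roi: ROIMask) -> float:
    """Subject-level intensity scale: mean I0-source intensity in the ROI
    bounding box. Both input channels are divided by it, which preserves the
    I0/Ik ratio the signal model cares about."""
    if not np.any(roi.mask):
        raise ValueError("empty ROI: no bounding box")
    sl = ndimage.find_objects(roi.mask.astype(np.int8))[0]
    scale = float(i0_vol.data[sl].mean())
    if scale <= 0:
        raise ValueError("degenerate I0 volume: non-positive scale")
    return scale


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AugmentConfig:
    """Patch augmentation: random flips, rotation, translation (applied with
    identical geometry to inputs and target) and Gaussian noise on the inputs
    only. Magnitudes are mild, sized for 64-px patches."""

    flip: float = 0.5
    rotation: float = 15.0  # max degrees
    translation: float = 8.0  # max pixels
    gaussian_noise_sigma: float = 0.02  # fraction of the input intensity scale

    def __post_init__(self) -> None:
        if not 0 <= self.flip <= 1:
            raise ValueError("flip probability in [0, 1]")
        if self.rotation < 0 or self.translation < 0 or self.gaussian_noise_sigma < 0:
            raise ValueError("augmentation magnitudes must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (
            self.flip == 0
            and self.rotation == 0
            and self.translation == 0
            and self.gaussian_noise_sigma == 0
        )


@dataclass(frozen=True)
class TrainConfig:
    loss: str = "l1"
    optimizer: str = "adam"
    lr0: float = 1e-3
    lr_decay: float = 0.9  # exponential factor applied per epoch
    weight_decay: float = 3e-4
    epochs: int = 1000
    batch_size: int = 16
    patch_size: int = 64
    roi_bias: float = 0.8  # probability of an ROI-centered crop
    patches_per_slice: int = 4
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    masked_inputs: bool = False
    roi_loss_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss != "l1":
            raise ValueError("only the L1 loss is supported")
        if self.optimizer not in ("adam", "rmsprop"):
            raise ValueError("optimizer must be 'adam' or 'rmsprop'")
        if not 0 < self.lr_decay <= 1:
            raise ValueError("lr_decay in (0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs >= 1")
        if not 0 <= self.roi_bias <= 1:
            raise ValueError("roi_bias in [0, 1]")


#: Desk-scale recipes. The U-Net preset trains 25 epochs: with per-epoch 0.9
#: decay the learning-rate mass beyond epoch 25 is ~7% of the total, so longer
#: schedules buy little; the small batch (6) raises optimizer steps per epoch
#: at constant compute, which is what the decayed schedule rewards. Geometric
#: augmentation is kept but no extra Gaussian noise is injected: the rendered
#: inputs already carry the acquisition's Rician noise, and noise-on-noise
#: biases the learned inversion within the short schedule.
FAST_UNET_TRAIN = TrainConfig(
    optimizer="adam",
    epochs=25,
    batch_size=6,
    patches_per_slice=6,
    augment=AugmentConfig(gaussian_noise_sigma=0.0),
)
FAST_MLP_TRAIN = TrainConfig(optimizer="rmsprop", epochs=200, batch_size=512)
FAST_UNET_NET = UNetConfig(depth=3, base_channels=8)


def lr_schedule(cfg: TrainConfig, epoch: int) -> float:
    """lr(e) = lr0 * lr_decay**e (e = 0 for the first epoch)."""
    return cfg.lr0 * cfg.lr_decay**epoch


def _make_optimizer(params, cfg: TrainConfig):
    cls = Adam if cfg.optimizer == "adam" else RMSProp
    return cls(params, lr=cfg.lr0, weight_decay=cfg.weight_decay)


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------


@dataclass
class FoldSplit:
    """Partition of subjects into k mutually exclusive, stratified folds."""

    assignments: dict[str, int]
    k: int
    strata: dict[str, str]

    def fold_of(self, subject_id: str) -> int:
        return self.assignments[subject_id]

    def test_ids(self, fold: int) -> list[str]:
        return [s for s, f in self.assignments.items() if f == fold]

    def train_ids(self, fold: int) -> list[str]:
        return [s for s, f in self.assignments.items() if f != fold]


def make_folds(subject_ids, strata, k: int, seed: int) -> FoldSplit:
    """Stratified k-fold partition, deterministic given ``seed``.

    Per-fold counts of each stratum are within +-1 of proportional.
    """
    subject_ids = list(subject_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(subject_ids):
        raise ValueError("more folds than subjects")
    if isinstance(strata, dict):
        labels = [strata[s] for s in subject_ids]
    else:
        labels = list(strata)
    if len(labels) != len(subject_ids):
        raise ValueError("one stratum label per subject required")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % 2**32)
    assignments: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(subject_ids)), labels)):
        for i in test_idx:
            assignments[subject_ids[i]] = fold
    return FoldSplit(assignments=assignments, k=k, strata=dict(zip(subject_ids, labels)))


# ---------------------------------------------------------------------------
# patches and augmentation
# ---------------------------------------------------------------------------


def sample_patches(slice_pair, target, roi_slice, n, cfg: TrainConfig, rng=None):
    """Sample ``n`` random patch triples from one 2-D slice.

    With probability ``cfg.roi_bias`` a patch center is drawn uniformly from
    ROI pixels (falling back to uniform if the slice has none), otherwise
    uniformly over the slice; windows are clamped inside the slice bounds.
    Returns a list of (input patch (2, p, p), target patch, roi patch).
    """
    slice_pair = np.asarray(slice_pair)
    target = np.asarray(target)
    roi_slice = np.asarray(roi_slice)
    p = cfg.patch_size
    H, W = target.shape[-2:]  # target may carry extra leading channels
    if H < p or W < p:
        raise ValueError(f"slice {target.shape} smaller than patch size {p}")
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    roi_idx = np.argwhere(roi_slice > 0)
    out = []
    for _ in range(n):
        if roi_idx.size and rng.random() < cfg.roi_bias:
            r, c = roi_idx[rng.integers(len(roi_idx))]
        else:
            r = rng.integers(H)
            c = rng.integers(W)
        r0 = int(np.clip(r - p // 2, 0, H - p))
        c0 = int(np.clip(c - p // 2, 0, W - p))
        out.append(
            (
                slice_pair[:, r0 : r0 + p, c0 : c0 + p],
                target[..., r0 : r0 + p, c0 : c0 + p],
                roi_slice[r0 : r0 + p, c0 : c0 + p],
            )
        )
    return out


def augment_patch(inp, tgt, cfg: AugmentConfig, seed, masks=None):
    """Augment one patch: flips / rotation / translation applied with the same
    geometry to input channels, target, and any mask channels (nearest-neighbor
    for masks); Gaussian noise added to input channels only. An all-zero config
    returns the arrays unchanged.
    """
    inp = np.asarray(inp)
    tgt = np.asarray(tgt)
    if inp.shape[-2:] != tgt.shape[-2:]:
        raise ValueError("input and target patch shapes must match")
    if cfg.is_identity:
        return (inp, tgt) if masks is None else (inp, tgt, masks)
    rng = np.random.default_rng(seed)
    flip_r = cfg.flip > 0 and rng.random() < cfg.flip
    flip_c = cfg.flip > 0 and rng.random() < cfg.flip
    angle = rng.uniform(-cfg.rotation, cfg.rotation) if cfg.rotation > 0 else 0.0
    tr = (
        rng.uniform(-cfg.translation, cfg.translation, size=2)
        if cfg.translation > 0
        else np.zeros(2)
    )

    def geom(a, order):
        if flip_r:
            a = a[..., ::-1, :]
        if flip_c:
            a = a[..., :, ::-1]
        if angle != 0.0 or np.any(tr != 0.0):
            th = np.deg2rad(angle)
            R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            center = (np.asarray(a.shape[-2:]) - 1) / 2.0
            offset = center - R @ (center + tr)
            if a.ndim == 2:
                a = ndimage.affine_transform(a, R, offset=offset, order=order, mode="constant")
            else:
                a = np.stack(
                    [
                        ndimage.affine_transform(ch, R, offset=offset, order=order, mode="constant")
                        for ch in a
                    ]
                )
        return np.ascontiguousarray(a)

    inp = geom(inp, order=1)
    tgt = geom(tgt, order=1 if np.issubdtype(tgt.dtype, np.floating) else 0)
    if cfg.gaussian_noise_sigma > 0:
        scale = float(np.max(np.abs(inp))) or 1.0
        inp = inp + rng.normal(0.0, cfg.gaussian_noise_sigma * scale, inp.shape)
    if masks is None:
        return inp, tgt
    masks = geom(np.asarray(masks), order=0)
    return inp, tgt, masks


def mask_to_roi(volumes: list[WeightedVolume], roi: ROIMask) -> list[WeightedVolume]:
    """Zero every voxel outside the cartilage ROI; ROI voxels pass unchanged."""
    out = []
    for v in volumes:
        if v.shape != roi.shape:
            raise ValueError("volume/ROI shape mismatch")
        out.append(
            WeightedVolume(
                np.where(roi.mask, v.data, 0.0),
                contrast=v.contrast,
                voxel_spacing=v.voxel_spacing,
            )
        )
    return out


# ---------------------------------------------------------------------------
# training data preparation
# ---------------------------------------------------------------------------


@dataclass
class SliceSample:
    """One 2-D training slice: normalized 2-channel input, target map (ms),
    target-trust mask and ROI mask."""

    inputs: np.ndarray  # (2, H, W)
    target: np.ndarray  # (H, W) ms; 0 where untrusted
    valid: np.ndarray  # (H, W) bool
    roi: np.ndarray  # (H, W) int labels


def prepare_slice_samples(
    subjects,
    combo: Combo,
    targets: dict[str, T1rhoMap] | None = None,
    masked_inputs: bool = False,
) -> list[SliceSample]:
    """Build per-slice training samples for the U-Net from whole subjects.

    Only slices containing ROI are used (the sliding-window evaluation visits
    the same slices). ``targets`` overrides ``subject.truth`` as supervision,
    e.g. with an NLLS-fitted map.
    """
    samples = []
    for sub in subjects:
        i0_vol, ik_vol = subject_input_volumes(sub, combo)
        if masked_inputs:
            i0_vol, ik_vol = mask_to_roi([i0_vol, ik_vol], sub.roi)
        scale = normalization_scale(i0_vol, sub.roi)
        tgt = targets[sub.subject_id] if targets is not None else sub.truth
        for s in range(sub.roi.shape[0]):
            if not np.any(sub.roi.labels[s]):
                continue
            samples.append(
                SliceSample(
                    inputs=np.stack([i0_vol.data[s], ik_vol.data[s]]) / scale,
                    target=np.where(tgt.valid[s], tgt.values[s], 0.0),
                    valid=tgt.valid[s].copy(),
                    roi=sub.roi.labels[s].copy(),
                )
            )
    return samples


def extract_voxel_pairs(
    subjects,
    combo: Combo,
    targets: dict[str, T1rhoMap] | None = None,
):
    """Cartilage-ROI voxel vectors for the MLP: X (n, 2) normalized intensity
    pairs, y (n,) target T1rho (ms). Only ROI voxels with a trusted target."""
    xs, ys = [], []
    for sub in subjects:
        i0_vol, ik_vol = subject_input_volumes(sub, combo)
        scale = normalization_scale(i0_vol, sub.roi)
        tgt = targets[sub.subject_id] if targets is not None else sub.truth
        sel = sub.roi.mask & tgt.valid
        xs.append(np.stack([i0_vol.data[sel], ik_vol.data[sel]], axis=1) / scale)
        ys.append(tgt.values[sel])
    X = np.concatenate(xs) if xs else np.empty((0, 2))
    y = np.concatenate(ys) if ys else np.empty(0)
    if len(y) == 0:
        raise ValueError("no ROI voxels with trusted targets")
    return X, y


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------


def _l1_loss_and_grad(pred, target, mask):
    """Masked mean absolute error and its gradient wrt pred."""
    m = mask.astype(pred.dtype)
    n = m.sum()
    if n == 0:
        return 0.0, np.zeros_like(pred)
    r = pred - target
    loss = float(np.abs(r * m).sum() / n)
    return loss, np.sign(r) * m / n


def train_unet(
    slices: list[SliceSample],
    cfg: TrainConfig,
    unet_cfg: UNetConfig = UNetConfig(),
) -> tuple[UNet2D, list[float]]:
    """Train the 2D U-Net on randomly cropped, augmented 64x64 patches.

    Loss is L1 over trusted-target voxels, or over cartilage voxels only when
    ``cfg.roi_loss_only``. Returns the trained model and the per-epoch mean
    loss history. Deterministic given the seeds in the configs.
    """
    if not slices:
        raise ValueError("no training slices")
    if cfg.roi_loss_only and not any(np.any(s.roi) for s in slices):
        raise ValueError("roi_loss_only with an all-zero ROI: no supervised voxels")
    model = build_unet(unet_cfg)
    opt = _make_optimizer(model.params(), cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7EA1]))
    history = []
    for epoch in range(cfg.epochs):
        opt.lr = lr_schedule(cfg, epoch)
        batch_in, batch_tgt, batch_mask = [], [], []
        for s in slices:
            for inp, tgt, roi in sample_patches(
                s.inputs, np.stack([s.target, s.valid.astype(float)]), s.roi,
                cfg.patches_per_slice, cfg, rng=rng,
            ):
                inp, tgt, roi = augment_patch(
                    inp, tgt, cfg.augment, rng.integers(2**31), masks=roi
                )
                target, valid = tgt[0], tgt[1] > 0.5
                mask = (roi > 0) if cfg.roi_loss_only else valid
                batch_in.append(inp)
                batch_tgt.append(target)
                batch_mask.append(mask)
        order = rng.permutation(len(batch_in))
        losses = []
        for i0 in range(0, len(order), cfg.batch_size):
            idx = order[i0 : i0 + cfg.batch_size]
            xb = np.stack([batch_in[i] for i in idx])
            tb = np.stack([batch_tgt[i] for i in idx])[:, None]
            mb = np.stack([batch_mask[i] for i in idx])[:, None]
            pred = model.forward(xb, train=True)
            loss, dpred = _l1_loss_and_grad(pred, tb, mb)
            opt.zero_grad()
            model.backward(dpred)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def train_mlp(
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    mlp_cfg: MLPConfig = MLPConfig(),
) -> tuple[SkipMLP, list[float]]:
    """Train the voxelwise MLP on (I0, Ik) intensity pairs with L1 loss.

    Rows are reshuffled every epoch into batches of ``cfg.batch_size``.
    Returns the model and the per-epoch mean loss history.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, 2) with matching y")
    if len(y) == 0:
        raise ValueError("no training voxels")
    model = build_mlp(mlp_cfg)
    opt = _make_optimizer(model.params(), cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7EA2]))
    history = []
    for epoch in range(cfg.epochs):
        opt.lr = lr_schedule(cfg, epoch)
        order = rng.permutation(len(y))
        losses = []
        for i0 in range(0, len(order), cfg.batch_size):
            idx = order[i0 : i0 + cfg.batch_size]
            if len(idx) < 2:
                continue  # BatchNorm needs more than one row
            pred = model.forward(X[idx], train=True)
            loss, dpred = _l1_loss_and_grad(pred, y[idx][:, None], np.ones((len(idx), 1)))
            opt.zero_grad()
            model.backward(dpred)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CrossValResult:
    predictions: dict[str, T1rhoMap]
    reports: list  # per-subject MetricsReport, in subject order
    summary: object  # CohortSummary
    audit: dict[str, dict]  # subject -> {"fold": f, "trained_without": bool}
    histories: dict[int, list[float]]


def run_cross_validation(
    cohort,
    folds: FoldSplit,
    combo: Combo,
    model: str = "mlp",
    train_cfg: TrainConfig | None = None,
    net_cfg=None,
    targets: dict[str, T1rhoMap] | None = None,
) -> CrossValResult:
    """k-fold cross-validated prediction: each subject is predicted exactly
    once, by the model whose training folds exclude it; metrics are computed
    per subject and aggregated over the cohort.

    ``model`` is "unet", "mlp", or "nlls" (the two-point closed form; no
    training, included as the classical reference). Learned models require a
    Table-3 combination; two-point NLLS on a PD-based combination violates the
    signal model and is flagged in the reports.
    """
    from . import metrics as _metrics
    from .predict import sliding_window_map, voxelwise_map

    if model in ("unet", "mlp") and combo not in TABLE_COMBOS:
        raise ValueError(f"combo {combo} not one of the admissible combinations")
    subjects = {s.subject_id: s for s in cohort}
    if set(subjects) != set(folds.assignments):
        raise ValueError("fold assignments do not cover the cohort")
    if train_cfg is None:
        train_cfg = FAST_MLP_TRAIN if model == "mlp" else FAST_UNET_TRAIN
    predictions: dict[str, T1rhoMap] = {}
    audit: dict[str, dict] = {}
    histories: dict[int, list[float]] = {}
    for fold in range(folds.k):
        train_subs = [subjects[s] for s in folds.train_ids(fold)]
        test_subs = [subjects[s] for s in folds.test_ids(fold)]
        if model == "mlp":
            X, y = extract_voxel_pairs(train_subs, combo, targets=targets)
            net, hist = train_mlp(X, y, train_cfg, net_cfg or MLPConfig())
            histories[fold] = hist
        elif model == "unet":
            samples = prepare_slice_samples(
                train_subs, combo, targets=targets, masked_inputs=train_cfg.masked_inputs
            )
            net, hist = train_unet(samples, train_cfg, net_cfg or FAST_UNET_NET)
            histories[fold] = hist
        for sub in test_subs:
            i0_vol, ik_vol = subject_input_volumes(sub, combo)
            if model == "nlls":
                pred = _two_point_reference(i0_vol, ik_vol, combo, sub.roi)
            elif model == "mlp":
                pred = voxelwise_map(net, i0_vol, ik_vol, sub.roi)
            else:
                if train_cfg.masked_inputs:
                    i0_vol, ik_vol = mask_to_roi([i0_vol, ik_vol], sub.roi)
                pred = sliding_window_map(net, i0_vol, ik_vol, sub.roi)
            predictions[sub.subject_id] = pred
            audit[sub.subject_id] = {
                "fold": fold,
                "trained_without": sub.subject_id not in folds.train_ids(fold),
            }
    reports = []
    for sid, sub in subjects.items():
        tgt = targets[sid] if targets is not None else sub.truth
        rep = _metrics.compute_subject_metrics(predictions[sid], tgt, sub.roi)
        rep.subject_id = sid
        rep.model_conforming = not (model == "nlls" and combo.i0 == "pd")
        reports.append(rep)
    summary = _metrics.summarize_cohort(reports)
    return CrossValResult(predictions, reports, summary, audit, histories)


def _two_point_reference(i0_vol, ik_vol, combo: Combo, roi: ROIMask) -> T1rhoMap:
    """Closed-form two-point fit treating the I0 source as the TSL=0 sample.

    For a PD-weighted I0 this deliberately misapplies the signal model — the
    classical reference against which the learned predictors are compared.
    """
    from .core import AcquisitionProtocol
    from .relaxometry import fit_volume

    protocol = AcquisitionProtocol(tsls=(0.0, combo.ik_tsl))
    vols = [
        WeightedVolume(i0_vol.data, contrast=0.0, voxel_spacing=i0_vol.voxel_spacing),
        ik_vol,
    ]
    return fit_volume(vols, protocol, roi=roi, method="two_point")
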