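"""Whole-volume inference.

The U-Net path tiles every ROI-containing slice with overlapping 64x64 windows
(averaging overlaps); the MLP path extracts ROI voxel intensity pairs, predicts
them as a batch, and scatters the predictions back to their voxel positions.
Outside the ROI the output map is 0 with ``valid`` False — evaluation happens
inside the cartilage only.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ROIMask, T1rhoMap, WeightedVolume

__all__ = ["TilingPlan", "sliding_window_map", "voxelwise_map"]


@dataclass(frozen=True)
class TilingPlan:
    """Sliding-window layout: window size, stride, and the slices to visit."""

    window: int = 64
    stride: int = 32
    slice_indices: tuple[int, ...] | None = None  # None: every slice with ROI

    def __post_init__(self) -> None:
        if not 1 <= self.stride <= self.window:
            raise ValueError("need 1 <= stride <= window")

    def starts(self, extent: int) -> list[int]:
        """Window start offsets covering [0, extent); the last window is
        clamped to the edge so every pixel is covered."""
        if extent <= self.window:
            return [0]
        s = list(range(0, extent - self.window + 1, self.stride))
        if s[-1] != extent - self.window:
            s.append(extent - self.window)
        return s


def _normalized_pair(i0_vol: WeightedVolume, ik_vol: WeightedVolume, roi: ROIMask):
    from .train_engine import normalization_scale

    if i0_vol.shape != ik_vol.shape or i0_vol.shape != roi.shape:
        raise ValueError("volumes and ROI must share one grid")
    scale = normalization_scale(i0_vol, roi)
    return np.stack([i0_vol.data, ik_vol.data]) / scale


def sliding_window_map(
    model,
    i0_vol: WeightedVolume,
    ik_vol: WeightedVolume,
    roi: ROIMask,
    plan: TilingPlan = TilingPlan(),
) -> T1rhoMap:
    """Predict a T1rho volume with overlapping-window U-Net inference.

    Every pixel of every ROI-containing slice is covered by at least one
    window; overlapping predictions are averaged. Slices smaller than the
    window are reflect-padded and cropped back.
    """
    pair = _normalized_pair(i0_vol, ik_vol, roi)
    S, H, W = roi.shape
    w = plan.window
    slices = (
        list(plan.slice_indices)
        if plan.slice_indices is not None
        else [s for s in range(S) if np.any(roi.labels[s])]
    )
    values = np.zeros((S, H, W))
    pr = max(0, w - H)
    pc = max(0, w - W)
    for s in slices:
        sl = pair[:, s]
        if pr or pc:
            sl = np.pad(sl, ((0, 0), (0, pr), (0, pc)), mode="reflect")
        Hp, Wp = sl.shape[1:]
        acc = np.zeros((Hp, Wp))
        cnt = np.zeros((Hp, Wp))
        tiles, boxes = [], []
        for r0 in plan.starts(Hp):
            for c0 in plan.starts(Wp):
                tiles.append(sl[:, r0 : r0 + w, c0 : c0 + w])
                boxes.append((r0, c0))
        pred = model.predict(np.stack(tiles))
        for (r0, c0), tile in zip(boxes, pred):
            acc[r0 : r0 + w, c0 : c0 + w] += tile
            cnt[r0 : r0 + w, c0 : c0 + w] += 1.0
        values[s] = (acc / cnt)[:H, :W]
    values = np.where(roi.mask, values, 0.0)
    return T1rhoMap(values, roi.mask.copy())


def voxelwise_map(
    model,
    i0_vol: WeightedVolume,
    ik_vol: WeightedVolume,
    roi: ROIMask,
) -> T1rhoMap:
    """Predict T1rho for every cartilage voxel with the voxelwise MLP.

    Extraction -> batched prediction -> reassembly preserves voxel positions
    exactly; non-ROI voxels are 0 / invalid.
    """
    if not np.any(roi.mask):
        raise ValueError("empty ROI")
    pair = _normalized_pair(i0_vol, ik_vol, roi)
    sel = roi.mask
    X = np.stack([pair[0][sel], pair[1][sel]], axis=1)
    pred = model.predict(X)
    values = np.zeros(roi.shape)
    values[sel] = pred
    return T1rhoMap(values, sel.copy())
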