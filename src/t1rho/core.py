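"""Core data containers for spin-lock relaxometry.

All volumes are 3-D magnitude images indexed as (slice, row, col); intensities
are in arbitrary scanner units, spin-lock times (TSL) and T1rho in milliseconds.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Cartilage subregion labels used throughout the package.
REGION_LABELS = {1: "femoral", 2: "lateral_tibial", 3: "medial_tibial", 4: "patellar"}

#: Tag marking a proton-density-weighted anatomical volume (no TSL attached).
PD_CONTRAST = "pd"


@dataclass(frozen=True)
class AcquisitionProtocol:
    """An ordered multi-TSL spin-lock acquisition.

    Parameters
    ----------
    tsls
        Spin-lock times in ms, strictly increasing, all >= 0 (the first is
        typically 0, giving PD-like contrast).
    fsl
        Spin-lock frequency in Hz. Metadata only; it does not enter the
        mono-exponential signal model.
    """

    tsls: tuple[float, ...]
    fsl: float = 300.0

    def __post_init__(self) -> None:
        tsls = tuple(float(t) for t in self.tsls)
        if len(tsls) == 0:
            raise ValueError("protocol needs at least one TSL")
        if any(t < 0 for t in tsls):
            raise ValueError("TSLs must be >= 0")
        if any(b <= a for a, b in zip(tsls, tsls[1:])):
            raise ValueError("TSLs must be strictly increasing")
        if not self.fsl > 0:
            raise ValueError("spin-lock frequency must be positive")
        object.__setattr__(self, "tsls", tsls)


@dataclass
class WeightedVolume:
    """One 3-D magnitude image tagged with its contrast.

    ``contrast`` is either the TSL in ms of a T1rho-weighted volume, or the
    string ``"pd"`` for a proton-density-weighted anatomical volume.
    """

    data: np.ndarray
    contrast: float | str
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D (slice, row, col)")
        if np.any(self.data < 0):
            raise ValueError("magnitude intensities must be >= 0")
        if isinstance(self.contrast, str):
            if self.contrast != PD_CONTRAST:
                raise ValueError(f"unknown contrast tag {self.contrast!r}")
        else:
            self.contrast = float(self.contrast)
            if self.contrast < 0:
                raise ValueError("TSL contrast must be >= 0")

    @property
    def is_pd(self) -> bool:
        return isinstance(self.contrast, str)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class T1rhoMap:
    """A voxelwise T1rho map (ms) with a per-voxel trust mask."""

    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid mask must share shape")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("values must be finite wherever valid")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass
class ROIMask:
    """Labeled cartilage mask: 0 background, 1-4 the subregions of REGION_LABELS."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("ROI labels must be 3-D")
        bad = set(np.unique(self.labels)) - {0, 1, 2, 3, 4}
        if bad:
            raise ValueError(f"unknown ROI labels {sorted(bad)}")
        self.labels = self.labels.astype(np.int16)

    @property
    def mask(self) -> np.ndarray:
        """Boolean unified-cartilage mask (any nonzero label)."""
        return self.labels > 0

    def region(self, label: int) -> np.ndarray:
        if label not in REGION_LABELS:
            raise ValueError(f"label must be one of {sorted(REGION_LABELS)}")
        return self.labels == label

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape


@dataclass
class FitResult:
    """Outcome of fitting the mono-exponential model to one voxel."""

    i0_hat: float
    t1rho_hat: float
    residual_norm: float
    converged: bool
    clamped: bool = False
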