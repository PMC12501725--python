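"""Predictor architectures: a range-limited 2D U-Net and a 1D skip MLP.

Both models map two input contrasts (an I0-like channel and a T1rho-weighted
channel) to T1rho in milliseconds. The regressor output passes through a fixed
affine rescaling (unit-scale activations -> ms) and then the range limiter

    y = clip(relu(x) + ymin, ymin, ymax)

which pins predictions to a physiologic T1rho window and silences the gradient
of grossly mispredicted voxels.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .nn import layers as nn_layers
from .nn.layers import (
    AffineHead,
    BatchNorm1d,
    BatchNorm2d,
    Conv1x1,
    Conv2d3x3,
    Layer,
    Limiter,
    Linear,
    MaxPool2,
    ReLU,
    Sequential,
    UpNearest2,
)

__all__ = [
    "LimiterConfig",
    "UNetConfig",
    "MLPConfig",
    "apply_limiter",
    "UNet2D",
    "SkipMLP",
    "build_unet",
    "build_mlp",
    "save_checkpoint",
    "load_checkpoint",
]

# Fixed regressor head: x_ms = _HEAD_SCALE * z + _HEAD_SHIFT, so a freshly
# initialized network (z ~ 0) starts near the middle of the limiter window and
# the optimizer works on O(1) quantities.
_HEAD_SCALE = 45.0
_HEAD_SHIFT = 40.0


@dataclass(frozen=True)
class LimiterConfig:
    """Output window of the limiter, in ms."""

    ymin: float = 10.0
    ymax: float = 100.0

    def __post_init__(self) -> None:
        if not 0 < self.ymin < self.ymax:
            raise ValueError("need 0 < ymin < ymax")


def apply_limiter(x, cfg: LimiterConfig = LimiterConfig()):
    """Limit a regressor output to [ymin, ymax]: ``clip(relu(x) + ymin, ymin, ymax)``."""
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("limiter input must be finite")
    out = np.clip(np.maximum(x, 0.0) + cfg.ymin, cfg.ymin, cfg.ymax)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class UNetConfig:
    depth: int = 4
    base_channels: int = 32
    in_channels: int = 2
    patch_size: int = 64
    limiter: LimiterConfig = field(default_factory=LimiterConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.in_channels != 2:
            raise ValueError("the predictor consumes exactly 2 contrasts")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.patch_size % (2**self.depth) != 0:
            raise ValueError(
                f"patch_size {self.patch_size} not divisible by 2^depth = {2**self.depth}"
            )


@dataclass(frozen=True)
class MLPConfig:
    n_blocks: int = 4
    width: int = 64
    in_features: int = 2
    skip: bool = True
    limiter: LimiterConfig | None = field(default_factory=LimiterConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.in_features != 2:
            raise ValueError("the predictor consumes exactly 2 contrasts")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")


def _double_conv(cin: int, cout: int, rng, first: bool = False) -> Sequential:
    return Sequential(
        Conv2d3x3(cin, cout, rng, first=first),
        BatchNorm2d(cout),
        ReLU(),
        Conv2d3x3(cout, cout, rng),
        BatchNorm2d(cout),
        ReLU(),
    )


class UNet2D:
    """Standard encoder-decoder U-Net with skip concatenation and a limiter head.

    Each level is Conv3x3-BN-ReLU twice; downsampling is 2x2 max pooling,
    upsampling nearest-neighbor 2x followed by concatenation with the encoder
    feature of the same resolution; the head is a 1x1 convolution feeding the
    fixed ms-affine and the limiter. Output spatial size equals input size.
    """

    kind = "unet"

    def __init__(self, cfg: UNetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c = cfg.base_channels
        self.enc: list[Sequential] = []
        self.pools: list[MaxPool2] = []
        cin = cfg.in_channels
        for i in range(cfg.depth):
            self.enc.append(_double_conv(cin, c * 2**i, rng, first=(i == 0)))
            self.pools.append(MaxPool2())
            cin = c * 2**i
        self.bottleneck = _double_conv(cin, c * 2**cfg.depth, rng)
        self.ups: list[UpNearest2] = []
        self.dec: list[Sequential] = []
        ch = c * 2**cfg.depth
        for i in reversed(range(cfg.depth)):
            skip_ch = c * 2**i
            self.ups.append(UpNearest2())
            self.dec.append(_double_conv(ch + skip_ch, skip_ch, rng))
            ch = skip_ch
        self.head = Conv1x1(ch, 1, rng, std=0.01)
        self.affine = AffineHead(_HEAD_SCALE, _HEAD_SHIFT)
        self.limiter = Limiter(cfg.limiter.ymin, cfg.limiter.ymax)

    # -- plumbing -------------------------------------------------------
    def modules(self) -> list[Layer]:
        return [*self.enc, self.bottleneck, *self.dec, self.head]

    def params(self):
        return [p for m in self.modules() for p in m.params()]

    def _bn_layers(self):
        for m in self.modules():
            if isinstance(m, Sequential):
                for l in m.layers:
                    if isinstance(l, BatchNorm2d):
                        yield l

    # -- compute --------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Map (N, 2, H, W) input patches to (N, 1, H, W) T1rho patches (ms).

        Internally the engine is channels-last; the conversion happens once at
        entry and exit.
        """
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ValueError("expected input of shape (N, 2, H, W)")
        if x.shape[2] % 2**self.cfg.depth or x.shape[3] % 2**self.cfg.depth:
            raise ValueError("spatial dims must be divisible by 2^depth")
        x = np.ascontiguousarray(np.asarray(x, dtype=nn_layers.DTYPE).transpose(0, 2, 3, 1))
        feats = []
        for enc, pool in zip(self.enc, self.pools):
            x = enc.forward(x, train=train)
            feats.append(x)
            x = pool.forward(x, train=train)
        x = self.bottleneck.forward(x, train=train)
        self._skip_ch = []
        for up, dec, f in zip(self.ups, self.dec, reversed(feats)):
            x = up.forward(x, train=train)
            self._skip_ch.append(x.shape[-1])
            x = np.concatenate([x, f], axis=-1)
            x = dec.forward(x, train=train)
        x = self.head.forward(x, train=train)
        x = self.affine.forward(x, train=train)
        x = self.limiter.forward(x, train=train)
        return x.transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = np.ascontiguousarray(np.asarray(dy, dtype=nn_layers.DTYPE).transpose(0, 2, 3, 1))
        dy = self.limiter.backward(dy)
        dy = self.affine.backward(dy)
        dy = self.head.backward(dy)
        skip_grads = []
        for up, dec, ch in zip(reversed(self.ups), reversed(self.dec), reversed(self._skip_ch)):
            dcat = dec.backward(dy)
            du, dskip = dcat[..., :ch], dcat[..., ch:]
            skip_grads.append(dskip)
            dy = up.backward(du)
        dy = self.bottleneck.backward(dy)
        for enc, pool, dskip in zip(reversed(self.enc), reversed(self.pools), reversed(skip_grads)):
            dy = pool.backward(dy) + dskip
            dy = enc.backward(dy)
        # the first conv skips its input gradient (nothing upstream needs it)
        return None if dy is None else dy.transpose(0, 3, 1, 2)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode forward pass -> (N, H, W) T1rho patches in ms."""
        return self.forward(np.asarray(x), train=False)[:, 0]


class SkipMLP:
    """Voxelwise MLP over (I0-like, Ik) intensity pairs.

    A linear stem lifts the pair to ``width`` features, followed by
    ``n_blocks`` FC-ReLU-BN blocks with residual skips, a linear unit to one
    output, the fixed ms-affine, and (optionally) the limiter.
    """

    kind = "mlp"

    def __init__(self, cfg: MLPConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.stem = Linear(cfg.in_features, cfg.width, rng)
        self.blocks = [
            Sequential(Linear(cfg.width, cfg.width, rng), ReLU(), BatchNorm1d(cfg.width))
            for _ in range(cfg.n_blocks)
        ]
        self.head = Linear(cfg.width, 1, rng, std=0.01)
        self.affine = AffineHead(_HEAD_SCALE, _HEAD_SHIFT)
        self.limiter = (
            Limiter(cfg.limiter.ymin, cfg.limiter.ymax) if cfg.limiter is not None else None
        )

    def modules(self) -> list[Layer]:
        return [self.stem, *self.blocks, self.head]

    def params(self):
        return [p for m in self.modules() for p in m.params()]

    def _bn_layers(self):
        for b in self.blocks:
            for l in b.layers:
                if isinstance(l, BatchNorm1d):
                    yield l

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.cfg.in_features:
            raise ValueError("expected input of shape (N, 2)")
        x = np.asarray(x, dtype=nn_layers.DTYPE)
        x = self.stem.forward(x, train=train)
        for b in self.blocks:
            h = b.forward(x, train=train)
            x = x + h if self.cfg.skip else h
        x = self.head.forward(x, train=train)
        x = self.affine.forward(x, train=train)
        return self.limiter.forward(x, train=train) if self.limiter is not None else x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.limiter is not None:
            dy = self.limiter.backward(dy)
        dy = self.affine.backward(dy)
        dy = self.head.backward(dy)
        for b in reversed(self.blocks):
            db = b.backward(dy)
            dy = dy + db if self.cfg.skip else db
        return self.stem.backward(dy)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode forward pass -> (N,) T1rho values in ms."""
        return self.forward(np.asarray(x, dtype=nn_layers.DTYPE), train=False)[:, 0]


def build_unet(cfg: UNetConfig = UNetConfig()) -> UNet2D:
    """Construct the range-limited 2D U-Net; weights deterministic given cfg.seed."""
    return UNet2D(cfg)


def build_mlp(cfg: MLPConfig = MLPConfig()) -> SkipMLP:
    """Construct the voxelwise skip MLP; weights deterministic given cfg.seed."""
    return SkipMLP(cfg)


# ---------------------------------------------------------------------------
# checkpoints: npz with the config embedded as JSON, self-describing
# ---------------------------------------------------------------------------


def _cfg_to_json(cfg) -> str:
    return json.dumps(dataclasses.asdict(cfg))


def _cfg_from_json(kind: str, payload: str):
    d = json.loads(payload)
    if d.get("limiter") is not None:
        d["limiter"] = LimiterConfig(**d["limiter"])
    return UNetConfig(**d) if kind == "unet" else MLPConfig(**d)


def save_checkpoint(model, path) -> None:
    arrays = {}
    for i, p in enumerate(model.params()):
        arrays[f"param_{i}"] = p.data
    for i, bn in enumerate(model._bn_layers()):
        arrays[f"bn_{i}_mean"] = bn.running_mean
        arrays[f"bn_{i}_var"] = bn.running_var
    np.savez(
        path,
        kind=np.str_(model.kind),
        config=np.str_(_cfg_to_json(model.cfg)),
        **arrays,
    )


def load_checkpoint(path):
    with np.load(path, allow_pickle=False) as z:
        kind = str(z["kind"])
        cfg = _cfg_from_json(kind, str(z["config"]))
        model = build_unet(cfg) if kind == "unet" else build_mlp(cfg)
        for i, p in enumerate(model.params()):
            p.data[...] = z[f"param_{i}"]
        for i, bn in enumerate(model._bn_layers()):
            bn.running_mean[...] = z[f"bn_{i}_mean"]
            bn.running_var[...] = z[f"bn_{i}_var"]
    return model
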