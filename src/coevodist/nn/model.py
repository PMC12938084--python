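"""The distance-map network: encoder, KAN refiner, decoder, full model.

The encoder is a stack of residual stages at constant L x L resolution,
each stage being conv (alternating 1x5 / 3x3 kernels) -> instance norm
-> SiLU -> Mamba block -> residual add; per-stage outputs are kept as
skip tensors.  The refiner flattens the grid to a (B, H*W, C) sequence,
applies a depthwise-separable conv block with sequence-norm + ReLU and
a KAN channel mapping, all inside a residual connection.  The decoder
mirrors the encoder with N-1 stages of stride-1 transposed convolutions,
skip concatenation and depthwise-separable convs, ending in a 1x1 conv
and Softplus so predicted distances are strictly positive.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np

from ..errors import ConfigError, DimensionError
from ..metrics import DistanceMap
from ..msa import PairFeatureTensor
from . import autograd as ag
from .autograd import Tensor
from .kan import KANLayerConfig, KANLinear, kan_grid_update
from .layers import (
    Conv2d,
    ConvTranspose2d,
    DepthwiseSeparableConv2d,
    InstanceNorm2d,
    Module,
    SequenceNorm,
)
from .mamba import MambaBlock, MambaBlockConfig

KERNEL_SCHEDULE = ((1, 5), (3, 3))     # alternating per encoder stage


@dataclasses.dataclass
class ModelConfig:
    in_channels: int
    base_channels: int = 64
    encoder_stages: int = 8
    mamba_state_dim: int = 4
    mamba_expand: int = 2
    mamba_conv_kernel: int = 4
    kan_grid_size: int = 5
    kan_spline_order: int = 3
    kan_grid_range: tuple[float, float] = (-2.0, 2.0)
    kan_grid_update_interval: int = 200
    symmetrize_output: bool = True
    output_bias_init: float = 15.0     # Softplus pre-activation; ~mean Cβ distance

    def __post_init__(self) -> None:
        if self.encoder_stages < 2:
            raise ValueError("need at least 2 encoder stages (decoder has N-1)")

    @property
    def decoder_stages(self) -> int:
        return self.encoder_stages - 1

    def mamba_config(self) -> MambaBlockConfig:
        return MambaBlockConfig(
            channels=self.base_channels,
            state_dim=self.mamba_state_dim,
            expand_factor=self.mamba_expand,
            conv_kernel=self.mamba_conv_kernel,
        )

    def kan_config(self) -> KANLayerConfig:
        return KANLayerConfig(
            n_in=self.base_channels,
            n_out=self.base_channels,
            grid_size=self.kan_grid_size,
            spline_order=self.kan_spline_order,
            grid_range=self.kan_grid_range,
            grid_update_interval=self.kan_grid_update_interval,
        )

    @classmethod
    def tiny(cls, in_channels: int, **overrides) -> "ModelConfig":
        """Desk-scale preset for fast CPU experiments and tests."""
        defaults = dict(
            base_channels=16,
            encoder_stages=2,
            mamba_state_dim=4,
            mamba_expand=2,
        )
        defaults.update(overrides)
        return cls(in_channels=in_channels, **defaults)

    @classmethod
    def full_scale(cls, in_channels: int, **overrides) -> "ModelConfig":
        """Full-depth preset: 64 residual stages, 64 channels."""
        defaults = dict(base_channels=64, encoder_stages=64)
        defaults.update(overrides)
        return cls(in_channels=in_channels, **defaults)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["kan_grid_range"] = list(d["kan_grid_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelConfig":
        d = dict(d)
        d["kan_grid_range"] = tuple(d["kan_grid_range"])
        return cls(**d)


# ---------------------------------------------------------------------------
# encoder
# ---------------------------------------------------------------------------

class EncoderStage(Module):
    def __init__(self, channels: int, kernel: tuple[int, int],
                 mamba_cfg: MambaBlockConfig, rng: np.random.Generator):
        self.conv = Conv2d(channels, channels, kernel, rng)
        self.norm = InstanceNorm2d(channels)
        self.mamba = MambaBlock(mamba_cfg, rng)

    def forward(self, x: Tensor) -> Tensor:
        y = ag.silu(self.norm(self.conv(x)))
        y = self.mamba(y)
        return ag.add(y, x)


class PerceptiveEncoder(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.stem = Conv2d(cfg.in_channels, cfg.base_channels, (3, 3), rng)
        self.stages = [
            EncoderStage(
                cfg.base_channels,
                KERNEL_SCHEDULE[i % len(KERNEL_SCHEDULE)],
                cfg.mamba_config(),
                rng,
            )
            for i in range(cfg.encoder_stages)
        ]

    def forward(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        """Returns the bottleneck map and one skip tensor per stage."""
        y = self.stem(x)
        skips = []
        for stage in self.stages:
            y = stage(y)
            skips.append(y)
        return y, skips


# ---------------------------------------------------------------------------
# refiner
# ---------------------------------------------------------------------------

class StructuralRefiner(Module):
    def __init__(self, kan_cfg: KANLayerConfig, rng: np.random.Generator):
        if kan_cfg.n_in != kan_cfg.n_out:
            raise ValueError("refiner KAN must preserve the channel count")
        C = kan_cfg.n_in
        self.conv = DepthwiseSeparableConv2d(C, C, (1, 3), rng)
        self.norm = SequenceNorm(C)
        self.kan = KANLinear(kan_cfg, rng)

    def forward(self, x: Tensor) -> Tensor:
        Bb, C, H, W = x.data.shape
        T = H * W
        seq = ag.reshape(ag.transpose(x, (0, 2, 3, 1)), (Bb, T, C))
        # depthwise-separable conv over the sequence, viewed as (B, C, 1, T)
        y4 = ag.reshape(ag.transpose(seq, (0, 2, 1)), (Bb, C, 1, T))
        y4 = self.conv(y4)
        y = ag.transpose(ag.reshape(y4, (Bb, C, T)), (0, 2, 1))
        y = ag.relu(self.norm(y))
        flat = ag.reshape(y, (Bb * T, C))
        refined = ag.reshape(self.kan(flat), (Bb, T, C))
        out = ag.add(refined, seq)                    # residual around the refiner
        return ag.transpose(ag.reshape(out, (Bb, H, W, C)), (0, 3, 1, 2))

    def refiner_inputs(self, x: Tensor) -> np.ndarray:
        """KAN input batch for the dynamic grid update (no graph)."""
        with ag.no_grad():
            Bb, C, H, W = x.data.shape
            T = H * W
            seq = ag.reshape(ag.transpose(x, (0, 2, 3, 1)), (Bb, T, C))
            y4 = ag.reshape(ag.transpose(seq, (0, 2, 1)), (Bb, C, 1, T))
            y4 = self.conv(y4)
            y = ag.transpose(ag.reshape(y4, (Bb, C, T)), (0, 2, 1))
            y = ag.relu(self.norm(y))
            return y.data.reshape(Bb * T, C)


# ---------------------------------------------------------------------------
# decoder
# ---------------------------------------------------------------------------

class DecoderStage(Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        self.up = ConvTranspose2d(channels, channels, (3, 3), rng)
        self.fuse = DepthwiseSeparableConv2d(2 * channels, channels, (3, 3), rng)
        self.norm = InstanceNorm2d(channels)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        y = self.up(x)
        y = ag.concat([y, skip], axis=1)
        return ag.silu(self.norm(self.fuse(y)))


class PredictionDecoder(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.stages = [DecoderStage(cfg.base_channels, rng) for _ in range(cfg.decoder_stages)]
        self.head = Conv2d(cfg.base_channels, 1, (1, 1), rng)
        self.head.bias.data[:] = cfg.output_bias_init

    def forward(self, x: Tensor, skips: list[Tensor]) -> Tensor:
        if len(skips) < len(self.stages) + 1:
            raise DimensionError(
                f"decoder needs {len(self.stages) + 1} skips, got {len(skips)}"
            )
        y = x
        # deepest skips first; the last encoder stage output is the bottleneck itself
        for i, stage in enumerate(self.stages):
            y = stage(y, skips[len(skips) - 2 - i])
        return ag.softplus(self.head(y))


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

class DistanceMapNet(Module):
    """Encoder -> refiner -> decoder; outputs strictly positive L x L maps."""

    def __init__(self, cfg: ModelConfig, seed: int | np.random.Generator = 0):
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        self.cfg = cfg
        self.encoder = PerceptiveEncoder(cfg, rng)
        self.refiner = StructuralRefiner(cfg.kan_config(), rng)
        self.decoder = PredictionDecoder(cfg, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.data.ndim != 4:
            raise DimensionError(f"expected (B, C, L, L) input, got shape {x.data.shape}")
        if x.data.shape[1] != self.cfg.in_channels:
            raise DimensionError(
                f"expected {self.cfg.in_channels} input channels, got {x.data.shape[1]}"
            )
        y, skips = self.encoder(x)
        y = self.refiner(y)
        y = self.decoder(y, skips)
        if self.cfg.symmetrize_output:
            y = ag.mul(ag.add(y, ag.transpose(y, (0, 1, 3, 2))), Tensor(0.5))
        return y

    def update_kan_grid(self, x: Tensor) -> None:
        """Dynamic mesh adjustment using the current refiner inputs for ``x``."""
        with ag.no_grad():
            enc, _ = self.encoder(x)
        batch = self.refiner.refiner_inputs(enc)
        kan_grid_update(self.refiner.kan, batch)

    def predict(self, features: PairFeatureTensor | np.ndarray) -> DistanceMap:
        arr = features.tensor if isinstance(features, PairFeatureTensor) else np.asarray(features)
        if arr.ndim != 3:
            raise DimensionError(f"expected (C, L, L) features, got {arr.shape}")
        with ag.no_grad():
            out = self.forward(Tensor(arr[None].astype(np.float64)))
        return DistanceMap(out.data[0, 0], kind="predicted")


# ---------------------------------------------------------------------------
# checkpoints: weights file + JSON config sidecar
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, net: DistanceMapNet,
                    extra: dict[str, Any] | None = None) -> None:
    path = Path(path)
    state = net.state_dict()
    knots = {"refiner_kan_knots": net.refiner.kan.knots}
    np.savez_compressed(path.with_suffix(".npz"), **state, **knots)
    sidecar = {"model": net.cfg.to_dict(), "extra": extra or {}}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> tuple[DistanceMapNet, dict[str, Any]]:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise ConfigError(f"missing config sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    cfg = ModelConfig.from_dict(sidecar["model"])
    net = DistanceMapNet(cfg, seed=0)
    with np.load(path.with_suffix(".npz")) as data:
        state = {k: data[k] for k in data.files if k != "refiner_kan_knots"}
        net.load_state_dict(state)
        net.refiner.kan.knots = data["refiner_kan_knots"]
    return net, sidecar.get("extra", {})


__all__ = [
    "ModelConfig",
    "PerceptiveEncoder",
    "StructuralRefiner",
    "PredictionDecoder",
    "DistanceMapNet",
    "save_checkpoint",
    "load_checkpoint",
    "KERNEL_SCHEDULE",
]
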