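"""Selective state-space (Mamba-style) block over flattened L x L grids.

The block normalises its input, splits it into a gating branch
(Linear -> SiLU) and a state branch (Linear -> depthwise conv along the
sequence -> SiLU -> selective SSM -> LayerNorm), fuses the two by a
Hadamard product, projects back to the input width, adds a residual
scaled by a learnable scalar s, and finishes with LayerNorm plus a
linear projection to the output width.

The SSM is a diagonal selective scan: per expanded channel d and state
lane n,  h_t = exp(Δ_t A) h_{t-1} + Δ_t B_t x_t,  y_t = C_t · h_t + D x_t,
with Δ (via softplus), B and C all linear functions of the input
(zero-order-hold discretisation of a continuous diagonal system with
negative real poles).  The 2D grid is flattened row-major into a single
length-H·W sequence for the scan.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import LayerNorm, Linear, Module, Parameter
from .scan import selective_scan


@dataclasses.dataclass
class MambaBlockConfig:
    channels: int
    state_dim: int = 4
    expand_factor: int = 2
    conv_kernel: int = 4
    residual_scale_init: float = 1.0
    out_channels: int | None = None          # default: same as channels

    def __post_init__(self) -> None:
        if min(self.channels, self.state_dim, self.expand_factor, self.conv_kernel) < 1:
            raise ValueError("all Mamba dimensions must be positive")

    @property
    def inner_dim(self) -> int:
        return self.channels * self.expand_factor

    @property
    def resolved_out_channels(self) -> int:
        return self.out_channels if self.out_channels is not None else self.channels


class MambaBlock(Module):
    def __init__(self, cfg: MambaBlockConfig, rng: np.random.Generator):
        self.cfg = cfg
        C, D, N = cfg.channels, cfg.inner_dim, cfg.state_dim

        self.norm_in = LayerNorm(C)
        self.gate_proj = Linear(C, D, rng)           # branch W2
        self.state_proj = Linear(C, D, rng)          # branch W1 entry
        self.conv_weight = Parameter(
            rng.normal(0.0, 1.0 / np.sqrt(cfg.conv_kernel), size=(D, 1, cfg.conv_kernel))
        )
        self.conv_bias = Parameter(np.zeros(D))

        # selective SSM parameters: input-dependent Δ, B, C; diagonal A < 0
        self.A_log = Parameter(np.tile(np.log(np.arange(1, N + 1, dtype=float)), (D, 1)))
        self.dt_proj = Linear(D, D, rng)
        dt_init = np.exp(
            rng.uniform(np.log(1e-3), np.log(1e-1), size=D)
        )
        self.dt_proj.bias.data = np.log(np.expm1(dt_init))   # softplus^-1
        self.B_proj = Linear(D, N, rng, bias=False)
        self.C_proj = Linear(D, N, rng, bias=False)
        self.D_skip = Parameter(np.ones(D))

        self.norm_state = LayerNorm(D)
        self.out_proj = Linear(D, C, rng)
        self.residual_scale = Parameter(np.array(cfg.residual_scale_init))
        self.norm_out = LayerNorm(C)
        self.projection = Linear(C, cfg.resolved_out_channels, rng)

    # -- state space scan --------------------------------------------------

    def ssm(self, xs: Tensor) -> Tensor:
        """Selective scan over a (B, T, D) sequence."""
        Bb, T, D = xs.data.shape
        N = self.cfg.state_dim
        delta = ag.softplus(self.dt_proj(xs))                        # (B, T, D)
        Bt = self.B_proj(xs)                                         # (B, T, N)
        Ct = self.C_proj(xs)                                         # (B, T, N)
        A = ag.neg(ag.exp(self.A_log))                               # (D, N), negative
        delta4 = ag.reshape(delta, (Bb, T, D, 1))
        abar = ag.exp(ag.mul(delta4, A))                             # (B, T, D, N)
        bx = ag.mul(
            ag.mul(delta4, ag.reshape(xs, (Bb, T, D, 1))),
            ag.reshape(Bt, (Bb, T, 1, N)),
        )
        h = selective_scan(abar, bx)                                 # (B, T, D, N)
        y = ag.reduce_sum(ag.mul(h, ag.reshape(Ct, (Bb, T, 1, N))), axis=3)
        return ag.add(y, ag.mul(xs, self.D_skip))

    def _seq_conv(self, xs: Tensor) -> Tensor:
        """Depthwise convolution along the sequence axis of (B, T, D)."""
        Bb, T, D = xs.data.shape
        x4 = ag.reshape(ag.transpose(xs, (0, 2, 1)), (Bb, D, 1, T))
        w = ag.reshape(self.conv_weight, (D, 1, self.cfg.conv_kernel))
        y = ag.depthwise_conv2d(x4, w, self.conv_bias)
        return ag.transpose(ag.reshape(y, (Bb, D, T)), (0, 2, 1))

    # -- full block --------------------------------------------------------

    def forward(self, x: Tensor) -> Tensor:
        """(B, C, H, W) -> (B, C_out, H, W); grid flattened row-major."""
        Bb, C, H, W = x.data.shape
        if C != self.cfg.channels:
            raise ValueError(f"expected {self.cfg.channels} channels, got {C}")
        seq = ag.reshape(ag.transpose(x, (0, 2, 3, 1)), (Bb, H * W, C))
        u = self.norm_in(seq)

        gate = ag.silu(self.gate_proj(u))                            # W2
        state = self.state_proj(u)
        state = ag.silu(self._seq_conv(state))
        state = self.norm_state(self.ssm(state))                     # W1
        fused = ag.mul(state, gate)
        w_out = self.out_proj(fused)                                 # (B, T, C)

        m = ag.add(w_out, ag.mul(seq, self.residual_scale))
        out = self.projection(self.norm_out(m))                      # (B, T, C_out)
        C_out = self.cfg.resolved_out_channels
        return ag.transpose(ag.reshape(out, (Bb, H, W, C_out)), (0, 3, 1, 2))


__all__ = ["MambaBlockConfig", "MambaBlock"]
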