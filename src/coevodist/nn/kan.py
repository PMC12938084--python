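"""Kolmogorov–Arnold layer: learnable univariate activations on every edge.

Each edge (p -> q) carries phi_{q,p}(z) = w_base[q,p] * silu(z) +
w_spline[q,p] * sum_g c[q,p,g] * B_g(z), with an order-k B-spline basis
on a per-input-feature knot grid.  Outputs are sums over input features.

The knot grid is not a trainable parameter: a dynamic mesh adjustment
(`kan_grid_update`) repositions knots to empirical quantiles of observed
inputs (blended with a uniform grid) and re-fits the spline coefficients
by least squares so the layer's function is preserved on the batch.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import Module, Parameter


@dataclasses.dataclass
class KANLayerConfig:
    n_in: int
    n_out: int
    grid_size: int = 5                     # G: number of grid intervals
    spline_order: int = 3                  # k
    grid_range: tuple[float, float] = (-2.0, 2.0)
    grid_update_interval: int = 200        # steps between mesh adjustments
    grid_mix: float = 0.1                  # uniform-grid blend during updates

    def __post_init__(self) -> None:
        if self.grid_size < 1 or self.spline_order < 1:
            raise ValueError("grid_size and spline_order must be >= 1")
        if not self.grid_range[0] < self.grid_range[1]:
            raise ValueError("grid_range must be an increasing interval")


def uniform_knots(grid_range: tuple[float, float], G: int, k: int, n_in: int) -> np.ndarray:
    """Extended uniform knot vector, shape (n_in, G + 2k + 1)."""
    a, b = grid_range
    h = (b - a) / G
    knots = a + h * np.arange(-k, G + k + 1)
    return np.tile(knots, (n_in, 1))


def bspline_basis(z: np.ndarray, knots: np.ndarray, k: int, with_deriv: bool = False):
    """Order-k B-spline basis values (and optionally derivatives).

    z: (M, P) already clamped into the grid interior; knots: (P, n_knots).
    Returns (M, P, n_basis) with n_basis = n_knots - k - 1.  On
    [grid_min, grid_max] the basis functions sum to one.
    """
    t = knots[None, :, :]                          # (1, P, n_knots)
    zc = z[:, :, None]                             # (M, P, 1)
    # order 0: half-open intervals [t_g, t_{g+1}) ...
    B = ((zc >= t[:, :, :-1]) & (zc < t[:, :, 1:])).astype(float)
    # ... except at the top of the interior grid, where the last interior
    # interval is right-closed (left limit), keeping partition of unity
    hi = knots[:, -(k + 1)]                        # (P,)
    at_hi = z >= hi[None, :]
    if at_hi.any():
        B[at_hi, :] = 0.0
        last_interior = knots.shape[1] - 2 - k     # index of [t_{G+k-1}, t_{G+k})
        B[at_hi, last_interior] = 1.0
    B_prev = None
    for d in range(1, k + 1):
        n = B.shape[-1] - 1
        left_den = t[:, :, d : d + n] - t[:, :, :n]
        right_den = t[:, :, d + 1 : d + 1 + n] - t[:, :, 1 : 1 + n]
        left = (zc - t[:, :, :n]) / left_den * B[..., :n]
        right = (t[:, :, d + 1 : d + 1 + n] - zc) / right_den * B[..., 1 : 1 + n]
        if d == k:
            B_prev = B
        B = left + right
    if not with_deriv:
        return B
    n = B.shape[-1]
    den1 = t[:, :, k : k + n] - t[:, :, :n]
    den2 = t[:, :, k + 1 : k + 1 + n] - t[:, :, 1 : 1 + n]
    dB = k * (B_prev[..., :n] / den1 - B_prev[..., 1 : 1 + n] / den2)
    return B, dB


class KANLinear(Module):
    def __init__(self, cfg: KANLayerConfig, rng: np.random.Generator):
        self.cfg = cfg
        G, k = cfg.grid_size, cfg.spline_order
        self.knots = uniform_knots(cfg.grid_range, G, k, cfg.n_in)   # buffer, not trained
        n_basis = G + k
        scale = 0.1 / np.sqrt(cfg.n_in)
        self.coef = Parameter(rng.normal(0.0, scale, size=(cfg.n_out, cfg.n_in, n_basis)))
        self.w_base = Parameter(rng.normal(0.0, 1.0 / np.sqrt(cfg.n_in), size=(cfg.n_out, cfg.n_in)))
        self.w_spline = Parameter(np.ones((cfg.n_out, cfg.n_in)))

    # interior interval on which the spline is evaluated (inputs clamped here)
    @property
    def grid_interior(self) -> tuple[np.ndarray, np.ndarray]:
        k = self.cfg.spline_order
        return self.knots[:, k], self.knots[:, -(k + 1)]

    def forward(self, z: Tensor) -> Tensor:
        """(M, n_in) -> (M, n_out); custom fused op with analytic gradients."""
        cfg = self.cfg
        coef, w_base, w_spline = self.coef, self.w_base, self.w_spline
        zd = z.data
        if zd.ndim != 2 or zd.shape[1] != cfg.n_in:
            raise ValueError(f"expected (M, {cfg.n_in}), got {zd.shape}")
        lo, hi = self.grid_interior
        zc = np.clip(zd, lo[None, :], hi[None, :])
        inside = ((zd >= lo[None, :]) & (zd <= hi[None, :])).astype(float)
        B, dB = bspline_basis(zc, self.knots, cfg.spline_order, with_deriv=True)

        s = ag._sigmoid(zd)
        sil = zd * s
        dsil = s + zd * s * (1.0 - s)

        sv = np.einsum("mpg,qpg->mqp", B, coef.data, optimize=True)
        out = sil @ w_base.data.T + np.einsum("mqp,qp->mq", sv, w_spline.data, optimize=True)

        def backward(g):
            if w_base.requires_grad:
                ag._accum(w_base, g.T @ sil)
            if w_spline.requires_grad:
                ag._accum(w_spline, np.einsum("mq,mqp->qp", g, sv, optimize=True))
            if coef.requires_grad:
                dcoef = np.einsum("mq,mpg->qpg", g, B, optimize=True)
                ag._accum(coef, dcoef * w_spline.data[:, :, None])
            if z.requires_grad:
                dz = dsil * (g @ w_base.data)
                dsv = np.einsum("mpg,qpg->mqp", dB, coef.data, optimize=True)
                dz_spline = np.einsum("mq,mqp,qp->mp", g, dsv, w_spline.data, optimize=True)
                ag._accum(z, dz + dz_spline * inside)

        return ag._make(out, (z, coef, w_base, w_spline), backward)

    def spline_values(self, z: np.ndarray) -> np.ndarray:
        """Per-edge spline component sum_g c[q,p,g] B_g(z_p), shape (M, n_out, n_in)."""
        lo, hi = self.grid_interior
        zc = np.clip(z, lo[None, :], hi[None, :])
        B = bspline_basis(zc, self.knots, self.cfg.spline_order)
        return np.einsum("mpg,qpg->mqp", B, self.coef.data, optimize=True)


def kan_grid_update(layer: KANLinear, batch: np.ndarray) -> None:
    """Reposition knots to empirical input quantiles and re-fit coefficients.

    Per input feature, the G+1 interior grid boundaries become a
    (1 - mix) quantile / mix uniform blend of the observed values, the
    knot vector is re-extended by k intervals on each side, and the
    spline coefficients are re-fit by least squares so the layer output
    on ``batch`` is preserved.  Features with (near-)constant inputs or
    too few samples keep their previous grid.
    """
    cfg = layer.cfg
    batch = np.asarray(batch, dtype=float)
    if batch.ndim != 2 or batch.shape[1] != cfg.n_in:
        raise ValueError(f"expected (M, {cfg.n_in}) update batch, got {batch.shape}")
    if batch.shape[0] == 0:
        raise ValueError("grid update batch is empty")
    G, k = cfg.grid_size, cfg.spline_order
    n_basis = G + k
    if batch.shape[0] < n_basis:
        return

    # observations outside the current grid were clamped on every forward
    # pass; reposition knots over the clamped distribution so the refit
    # targets stay consistent with what the layer actually computed
    lo_old, hi_old = layer.grid_interior
    batch = np.clip(batch, lo_old[None, :], hi_old[None, :])
    old_spline = layer.spline_values(batch)            # (M, n_out, n_in)
    new_knots = layer.knots.copy()
    updated_features = []
    for p in range(cfg.n_in):
        z = batch[:, p]
        zmin, zmax = float(z.min()), float(z.max())
        if zmax - zmin < 1e-8:
            continue                                   # degenerate: keep grid
        qs = np.quantile(z, np.linspace(0.0, 1.0, G + 1))
        uni = np.linspace(zmin, zmax, G + 1)
        interior = (1.0 - cfg.grid_mix) * qs + cfg.grid_mix * uni
        if np.any(np.diff(interior) <= 0):
            interior = uni
        left_h = interior[1] - interior[0]
        right_h = interior[-1] - interior[-2]
        knots = np.concatenate(
            [
                interior[0] - left_h * np.arange(k, 0, -1),
                interior,
                interior[-1] + right_h * np.arange(1, k + 1),
            ]
        )
        new_knots[p] = knots
        updated_features.append(p)
    if not updated_features:
        return

    layer.knots = new_knots
    lo, hi = layer.grid_interior
    zc = np.clip(batch, lo[None, :], hi[None, :])
    Bn = bspline_basis(zc, layer.knots, k)             # (M, n_in, n_basis)
    for p in updated_features:
        A = Bn[:, p, :]                                # (M, n_basis)
        Y = old_spline[:, :, p]                        # (M, n_out)
        sol, *_ = np.linalg.lstsq(A, Y, rcond=None)
        layer.coef.data[:, p, :] = sol.T


__all__ = ["KANLayerConfig", "KANLinear", "kan_grid_update", "bspline_basis", "uniform_knots"]
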