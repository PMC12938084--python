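"""Differentiable training objective (autodiff counterpart of metrics.inv_log_cosh_loss).

The inverse transform 100/(d + eps) is singular where the true distance
is zero — in practice exactly the self-pair diagonal of a ground-truth
map.  The training objective therefore splits the cells: off-diagonal
cells are penalised with log cosh of the inverse-distance residual
(the regression loss proper), while diagonal cells fall back to a plain
log cosh on untransformed distances, which trains the prediction toward
zero without the singularity.  Means are taken over all L^2 cells.
"""

from __future__ import annotations

import numpy as np

from ..errors import DimensionError
from . import autograd as ag
from .autograd import Tensor


def inv_log_cosh_loss_t(
    pred: Tensor, truth: np.ndarray, eps: float = 1e-8, diagonal: str = "direct"
) -> Tensor:
    """Training loss over a (B, 1, L, L) prediction against a constant truth.

    ``diagonal`` is ``"direct"`` (plain log-cosh on the raw distances for
    i == j cells; default) or ``"inverse"`` (apply the inverse transform
    everywhere, faithful to the bare formula — only usable when the
    truth has no zero entries).
    """
    truth = np.asarray(truth, dtype=np.float64)
    if truth.shape != pred.data.shape:
        raise DimensionError(f"shape mismatch {pred.data.shape} vs {truth.shape}")
    if eps <= 0:
        raise ValueError("eps must be positive")
    if diagonal not in ("direct", "inverse"):
        raise ValueError("diagonal must be 'direct' or 'inverse'")

    inv_pred = ag.div(Tensor(100.0), ag.add(pred, Tensor(eps)))
    inv_truth = Tensor(100.0 / (truth + eps))
    u_inv = ag.log_cosh(ag.add(inv_pred, ag.neg(inv_truth)))

    if diagonal == "inverse" or pred.data.ndim < 2 or pred.data.shape[-1] != pred.data.shape[-2]:
        return ag.reduce_mean(u_inv)

    L = pred.data.shape[-1]
    off_diag = 1.0 - np.eye(L)
    off_diag = off_diag.reshape((1,) * (pred.data.ndim - 2) + (L, L))
    u_dir = ag.log_cosh(ag.add(pred, Tensor(-truth)))
    total = ag.add(
        ag.reduce_sum(ag.mul(u_inv, Tensor(off_diag))),
        ag.reduce_sum(ag.mul(u_dir, Tensor(1.0 - off_diag))),
    )
    return ag.div(total, Tensor(float(pred.data.size)))


__all__ = ["inv_log_cosh_loss_t"]
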