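"""Sequential linear-recurrence (selective scan) kernels.

The state update is the diagonal discretised SSM recurrence

    h_t = Abar_t * h_{t-1} + Bx_t,

applied independently per (batch, channel, state) lane over a sequence.
Forward and adjoint passes are compiled with numba; the adjoint runs the
reverse recurrence  g_t = dL/dh_t + Abar_{t+1} * g_{t+1}  with
dAbar_t = g_t * h_{t-1} and dBx_t = g_t.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .autograd import Tensor, _accum, _make


@njit(cache=True)
def _scan_forward(abar, bx):  # pragma: no cover - exercised via selective_scan
    B, T, D, N = abar.shape
    h = np.empty((B, T, D, N))
    for b in range(B):
        for d in range(D):
            for n in range(N):
                acc = 0.0
                for t in range(T):
                    acc = abar[b, t, d, n] * acc + bx[b, t, d, n]
                    h[b, t, d, n] = acc
    return h


@njit(cache=True)
def _scan_backward(abar, h, dh):  # pragma: no cover - exercised via selective_scan
    B, T, D, N = abar.shape
    dabar = np.empty((B, T, D, N))
    dbx = np.empty((B, T, D, N))
    for b in range(B):
        for d in range(D):
            for n in range(N):
                g = 0.0
                for t in range(T - 1, -1, -1):
                    if t == T - 1:
                        g = dh[b, t, d, n]
                    else:
                        g = dh[b, t, d, n] + abar[b, t + 1, d, n] * g
                    dbx[b, t, d, n] = g
                    h_prev = h[b, t - 1, d, n] if t > 0 else 0.0
                    dabar[b, t, d, n] = g * h_prev
    return dabar, dbx


def selective_scan(abar: Tensor, bx: Tensor) -> Tensor:
    """Differentiable scan: returns h with h_t = abar_t * h_{t-1} + bx_t.

    Both inputs have shape (B, T, D, N).
    """
    if abar.data.shape != bx.data.shape:
        raise ValueError(
            f"scan operands must share a shape, got {abar.data.shape} vs {bx.data.shape}"
        )
    a = np.ascontiguousarray(abar.data)
    x = np.ascontiguousarray(bx.data)
    h = _scan_forward(a, x)

    def backward(g):
        dabar, dbx = _scan_backward(a, h, np.ascontiguousarray(g))
        _accum(abar, dabar)
        _accum(bx, dbx)

    return _make(h, (abar, bx), backward)


__all__ = ["selective_scan"]
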