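"""Numba-compiled data-movement kernels for the conv and pooling layers.

The arithmetic of the convolution stays in BLAS (one GEMM per layer); these
kernels only pack/unpack the im2col matrix and run the 2×2×2 max pooling,
which are memory-movement bound and slow as generic strided NumPy copies.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def im2col_3d(xp, k, D, H, W, xcol):
    """Pack padded (n, D+2p, H+2p, W+2p, C) into (n·D·H·W, k³·C) rows."""
    n = xp.shape[0]
    C = xp.shape[4]
    row = 0
    for i in range(n):
        for d in range(D):
            for h in range(H):
                for w in range(W):
                    col = 0
                    for a in range(k):
                        for b in range(k):
                            for c in range(k):
                                for ch in range(C):
                                    xcol[row, col] = xp[i, d + a, h + b, w + c, ch]
                                    col += 1
                    row += 1


@njit(cache=True)
def col2im_3d(dxcol, k, D, H, W, dxp):
    """Scatter-add (n·D·H·W, k³·C) gradient rows back onto the padded grid."""
    n = dxp.shape[0]
    C = dxp.shape[4]
    row = 0
    for i in range(n):
        for d in range(D):
            for h in range(H):
                for w in range(W):
                    col = 0
                    for a in range(k):
                        for b in range(k):
                            for c in range(k):
                                for ch in range(C):
                                    dxp[i, d + a, h + b, w + c, ch] += dxcol[row, col]
                                    col += 1
                    row += 1


@njit(cache=True)
def maxpool3d_fwd(x, out, idx):
    """2×2×2/stride-2 max with argmax (first maximum wins on ties)."""
    n, d2, h2, w2, C = out.shape
    for i in range(n):
        for d in range(d2):
            for h in range(h2):
                for w in range(w2):
                    for ch in range(C):
                        best = x[i, 2 * d, 2 * h, 2 * w, ch]
                        arg = 0
                        pos = 0
                        for a in range(2):
                            for b in range(2):
                                for c in range(2):
                                    v = x[i, 2 * d + a, 2 * h + b, 2 * w + c, ch]
                                    if v > best:
                                        best = v
                                        arg = pos
                                    pos += 1
                        out[i, d, h, w, ch] = best
                        idx[i, d, h, w, ch] = arg


@njit(cache=True)
def maxpool3d_bwd(grad, idx, dx):
    """Route each pooled gradient to its argmax voxel."""
    n, d2, h2, w2, C = grad.shape
    for i in range(n):
        for d in range(d2):
            for h in range(h2):
                for w in range(w2):
                    for ch in range(C):
                        arg = idx[i, d, h, w, ch]
                        a = arg // 4
                        b = (arg // 2) % 2
                        c = arg % 2
                        dx[i, 2 * d + a, 2 * h + b, 2 * w + c, ch] = grad[i, d, h, w, ch]


@njit(cache=True)
def bn_fwd_stats(x2d):
    """Per-column mean and (biased) variance in one pass; x2d is (m, C)."""
    m, C = x2d.shape
    s1 = np.zeros(C, dtype=np.float64)
    s2 = np.zeros(C, dtype=np.float64)
    for i in range(m):
        for c in range(C):
            v = x2d[i, c]
            s1[c] += v
            s2[c] += v * v
    mu = s1 / m
    var = s2 / m - mu * mu
    for c in range(C):
        if var[c] < 0.0:
            var[c] = 0.0
    return mu, var


@njit(cache=True)
def bn_apply(x2d, mu, inv, gamma, beta, xhat, out):
    m, C = x2d.shape
    for i in range(m):
        for c in range(C):
            h = (x2d[i, c] - mu[c]) * inv[c]
            xhat[i, c] = h
            out[i, c] = gamma[c] * h + beta[c]


@njit(cache=True)
def bn_bwd(grad2d, xhat, ginv, dgamma, dbeta, out, training):
    m, C = grad2d.shape
    for i in range(m):
        for c in range(C):
            g = grad2d[i, c]
            dgamma[c] += g * xhat[i, c]
            dbeta[c] += g
    if training:
        for i in range(m):
            for c in range(C):
                out[i, c] = ginv[c] * (grad2d[i, c] - dbeta[c] / m
                                       - xhat[i, c] * dgamma[c] / m)
    else:
        for i in range(m):
            for c in range(C):
                out[i, c] = ginv[c] * grad2d[i, c]
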