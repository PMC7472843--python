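"""Numba coordinate-descent kernel for the penalized weighted least squares
subproblem of the elastic-net Cox fit.

The outer IRLS loop (in :mod:`penalized`) forms weights ``w`` and a working
response ``z`` from the partial-likelihood gradient and curvature; this
kernel then minimizes

    (1/2n) sum_i w_i (z_i - W_i beta)^2
        + lam * sum_j pen_j * (alpha*|beta_j| + (1-alpha)/2 * beta_j^2)

by cyclic soft-thresholding with active-set iteration. ``pen_j`` is 0 for
unpenalized (clinical) columns and 1 for gene columns.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _one_sweep(W, w, r, beta, pen, lam, alpha, d2, n, active_only, active):
    q = W.shape[1]
    max_delta = 0.0
    for j in range(q):
        if active_only and not active[j]:
            continue
        bj = beta[j]
        num = 0.0
        for i in range(W.shape[0]):
            num += w[i] * W[i, j] * r[i]
        num = num / n + d2[j] * bj
        if pen[j]:
            thresh = abs(num) - lam * alpha
            if thresh <= 0.0:
                newb = 0.0
            else:
                sgn = 1.0 if num > 0 else -1.0
                newb = sgn * thresh / (d2[j] + lam * (1.0 - alpha))
        else:
            newb = num / d2[j] if d2[j] > 0 else bj
        delta = newb - bj
        if delta != 0.0:
            for i in range(W.shape[0]):
                r[i] -= W[i, j] * delta
            beta[j] = newb
            ad = abs(delta)
            if ad > max_delta:
                max_delta = ad
    return max_delta


@njit(cache=True)
def cd_solve(W, w, z, beta, pen, lam, alpha, tol, max_sweeps):
    """Solve the penalized WLS subproblem in place; returns sweep count."""
    n, q = W.shape
    d2 = np.zeros(q)
    for j in range(q):
        s = 0.0
        for i in range(n):
            s += w[i] * W[i, j] * W[i, j]
        d2[j] = s / n
    r = z - W @ beta
    active = np.zeros(q, dtype=np.bool_)
    sweeps = 0
    while sweeps < max_sweeps:
        delta = _one_sweep(W, w, r, beta, pen, lam, alpha, d2, n, False, active)
        sweeps += 1
        if delta < tol:
            break
        for j in range(q):
            active[j] = (not pen[j]) or beta[j] != 0.0
        while sweeps < max_sweeps:
            delta = _one_sweep(W, w, r, beta, pen, lam, alpha, d2, n, True, active)
            sweeps += 1
            if delta < tol:
                break
    return sweeps
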