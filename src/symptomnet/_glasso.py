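"""Coordinate-descent graphical lasso kernels (numba).

Solves, for a correlation matrix R and penalty lam >= 0,

    minimize over K > 0:   -log det K + tr(R K) + lam * sum_{i != j} |K_ij|

by Friedman-style block coordinate descent on the working covariance W. The
diagonal is unpenalized, so W_ii = R_ii at the solution. The kernels keep
(W, B) state across calls, which makes warm-started penalty paths cheap.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def glasso_cd(R, lam, W, B, tol, max_iter, inner_tol, inner_max):
    """One glasso solve; W (working covariance) and B (per-column lasso
    coefficients) are updated in place. Returns (n_sweeps, converged)."""
    p = R.shape[0]
    for j in range(p):
        W[j, j] = R[j, j]
    offmean = 0.0
    cnt = 0
    for i in range(p):
        for j in range(p):
            if i != j:
                offmean += abs(R[i, j])
                cnt += 1
    offmean = offmean / cnt if cnt > 0 else 1.0
    thr = tol * max(offmean, 1e-12)
    converged = False
    sweeps = 0
    for it in range(max_iter):
        sweeps = it + 1
        delta = 0.0
        for j in range(p):
            # lasso subproblem for column j over variables k != j
            for _ in range(inner_max):
                dmax = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    r = R[k, j]
                    for l in range(p):
                        if l != j and l != k:
                            r -= W[k, l] * B[l, j]
                    bold = B[k, j]
                    if r > lam:
                        bnew = (r - lam) / W[k, k]
                    elif r < -lam:
                        bnew = (r + lam) / W[k, k]
                    else:
                        bnew = 0.0
                    if bnew != bold:
                        B[k, j] = bnew
                        d = abs(bnew - bold)
                        if d > dmax:
                            dmax = d
                if dmax < inner_tol:
                    break
            for k in range(p):
                if k == j:
                    continue
                s = 0.0
                for l in range(p):
                    if l != j:
                        s += W[k, l] * B[l, j]
                d = abs(s - W[k, j])
                if d > delta:
                    delta = d
                W[k, j] = s
                W[j, k] = s
        if delta < thr:
            converged = True
            break
    return sweeps, converged


@njit(cache=True)
def precision_from_state(W, B):
    """Recover the symmetric precision matrix from the (W, B) state."""
    p = W.shape[0]
    K = np.zeros((p, p))
    for j in range(p):
        s = W[j, j]
        for l in range(p):
            if l != j:
                s -= W[l, j] * B[l, j]
        kjj = 1.0 / s
        K[j, j] = kjj
        for k in range(p):
            if k != j:
                K[k, j] = -B[k, j] * kjj
    for i in range(p):
        for j in range(i + 1, p):
            v = 0.5 * (K[i, j] + K[j, i])
            K[i, j] = v
            K[j, i] = v
    return K


def init_state(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fresh (W, B) state: diagonal working covariance, zero coefficients."""
    p = R.shape[0]
    W = np.diag(np.diag(R)).astype(float)
    B = np.zeros((p, p))
    return W, B


@njit(cache=True)
def ebic_path(R, lams, n, gamma, tol, max_iter, inner_tol, inner_max):
    """Warm-started penalty path with EBIC scoring done in-kernel.

    Returns (best_index, K_best, ebic_scores, n_unconverged). Edge counting
    uses the partial-correlation zero threshold 1e-8.
    """
    p = R.shape[0]
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for j in range(p):
        W[j, j] = R[j, j]
    n_lam = lams.shape[0]
    scores = np.empty(n_lam)
    best = -1
    best_score = np.inf
    K_best = np.zeros((p, p))
    bad = 0
    logp4g = 4.0 * gamma * np.log(p)
    logn = np.log(n)
    for li in range(n_lam):
        sweeps, converged = glasso_cd(R, lams[li], W, B, tol, max_iter,
                                      inner_tol, inner_max)
        if not converged:
            bad += 1
            scores[li] = np.inf
            continue
        K = precision_from_state(W, B)
        # log det via Cholesky
        L = np.linalg.cholesky(K)
        logdet = 0.0
        for i in range(p):
            logdet += 2.0 * np.log(L[i, i])
        tr = 0.0
        for i in range(p):
            for j in range(p):
                tr += R[i, j] * K[j, i]
        E = 0
        for i in range(p):
            for j in range(i + 1, p):
                w = -K[i, j] / np.sqrt(K[i, i] * K[j, j])
                if abs(w) >= 1e-8:
                    E += 1
        score = -n * (logdet - tr) + E * logn + E * logp4g
        scores[li] = score
        if score < best_score:
            best_score = score
            best = li
            K_best = K.copy()
    return best, K_best, scores, bad
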