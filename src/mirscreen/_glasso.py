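"""Block-coordinate-descent kernel for the graphical lasso.

Solves max_Theta  log det Theta - tr(S Theta) - lam * sum_{i!=j} |Theta_ij|
(diagonal unpenalized) by cycling over columns of the working covariance
W; each column update solves an l1-regularized quadratic subproblem by
coordinate descent, warm-started from the previous sweep.  The working
covariance keeps its diagonal fixed at diag(S) (unpenalized-diagonal
convention), and each exact column update increases log det W, which is
the solver's monotone surrogate objective.

Compiled with numba; explicit loops on purpose.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["glasso_cd"]


@njit(cache=False)
def _soft(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


@njit(cache=False)
def glasso_cd(S, Lam, tol, max_iter, inner_tol, inner_max, W0, B0, warm):
    """Run block coordinate descent; returns (W, B, W_path, B_path, n_sweeps, converged).

    Lam is a full matrix of per-entry penalties (diagonal ignored), which
    also covers the support-constrained MLE refit (0 on the support, a
    huge value elsewhere).

    B[:, j] holds the lasso coefficients of column j's subproblem (entry j
    itself is zero).  W_path / B_path store the state after every sweep so
    the caller can reconstruct the precision-matrix trajectory.
    """
    p = S.shape[0]
    W = S.copy()
    B = np.zeros((p, p))
    if warm:
        for i in range(p):
            for j in range(p):
                W[i, j] = W0[i, j]
                B[i, j] = B0[i, j]
        for j in range(p):
            W[j, j] = S[j, j]
    W_path = np.zeros((max_iter, p, p))
    B_path = np.zeros((max_iter, p, p))

    off_mean = 0.0
    if p > 1:
        for i in range(p):
            for j in range(p):
                if i != j:
                    off_mean += abs(S[i, j])
        off_mean /= p * (p - 1)
    thr = tol * max(off_mean, 1e-12)

    idx = np.empty(p - 1, np.int64)
    V = np.empty((p - 1, p - 1))
    s12 = np.empty(p - 1)
    lam_col = np.empty(p - 1)
    beta = np.empty(p - 1)
    c = np.empty(p - 1)

    n_sweeps = 0
    converged = False
    for it in range(max_iter):
        max_delta = 0.0
        total_delta = 0.0
        for j in range(p):
            k = 0
            for i in range(p):
                if i != j:
                    idx[k] = i
                    k += 1
            for a in range(p - 1):
                s12[a] = S[idx[a], j]
                lam_col[a] = Lam[idx[a], j]
                beta[a] = B[idx[a], j]
                for b in range(p - 1):
                    V[a, b] = W[idx[a], idx[b]]
            # c = V @ beta (warm start residual cache)
            for a in range(p - 1):
                acc = 0.0
                for b in range(p - 1):
                    acc += V[a, b] * beta[b]
                c[a] = acc
            for _ in range(inner_max):
                inner_delta = 0.0
                for a in range(p - 1):
                    vaa = V[a, a]
                    if vaa <= 0.0:
                        continue
                    r = s12[a] - (c[a] - vaa * beta[a])
                    bnew = _soft(r, lam_col[a]) / vaa
                    d = bnew - beta[a]
                    if d != 0.0:
                        for b in range(p - 1):
                            c[b] += V[b, a] * d
                        beta[a] = bnew
                        if abs(d) > inner_delta:
                            inner_delta = abs(d)
                if inner_delta < inner_tol:
                    break
            for a in range(p - 1):
                old = W[idx[a], j]
                new = c[a]
                total_delta += abs(new - old)
                if abs(new - old) > max_delta:
                    max_delta = abs(new - old)
                W[idx[a], j] = new
                W[j, idx[a]] = new
                B[idx[a], j] = beta[a]
        for a in range(p):
            for b in range(p):
                W_path[it, a, b] = W[a, b]
                B_path[it, a, b] = B[a, b]
        n_sweeps = it + 1
        mean_delta = total_delta / max(p * (p - 1), 1)
        if mean_delta <= thr:
            converged = True
            break
    return W, B, W_path[:n_sweeps], B_path[:n_sweeps], n_sweeps, converged
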