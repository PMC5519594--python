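"""Independent basic constant-penalty ALM robust PCA, used only as a cross-check.

Deliberately self-contained: it shares no code with the package solver.
One proximal alternation per multiplier update with the penalty held
constant (the two-block ADMM form, which provably converges to the
global optimum of the convex program), its own SVD call and its own soft
threshold — so agreement between the two solvers is evidence rather than
tautology.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg


def rpca_alm_oracle(
    X: np.ndarray,
    lam: float | None = None,
    mu: float = 1.0,
    tol: float = 1e-12,
    max_iter: int = 60000,
) -> tuple[np.ndarray, np.ndarray]:
    """min ||R||_* + lam ||E||_1 s.t. X = R + E; returns (R, E).

    Stops when the R iterate stabilises (relative change below `tol`),
    which at constant penalty certifies genuine convergence rather than
    the artificial feasibility produced by a rapidly growing penalty.
    """
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    if lam is None:
        lam = 1.0 / np.sqrt(max(m, n))
    norm_fro = max(np.linalg.norm(X), 1e-30)
    Y = np.zeros_like(X)
    E = np.zeros_like(X)
    R = np.zeros_like(X)
    for k in range(max_iter):
        U, s, Vt = scipy.linalg.svd(X - E + Y / mu, full_matrices=False)
        s_shrunk = np.where(s > 1.0 / mu, s - 1.0 / mu, 0.0)
        R_new = (U * s_shrunk) @ Vt
        T = X - R_new + Y / mu
        E = np.where(T > lam / mu, T - lam / mu, np.where(T < -lam / mu, T + lam / mu, 0.0))
        Y = Y + mu * (X - R_new - E)
        done = k > 100 and np.linalg.norm(R_new - R) / norm_fro < tol
        R = R_new
        if done:
            break
    return R, E
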