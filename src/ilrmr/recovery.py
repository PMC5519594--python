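"""Weighted robust-PCA solver via the augmented Lagrange multiplier method.

The recovery model decomposes the (possibly masked) association matrix X
into a low-rank score matrix R and a sparse error E:

    min  ||R||_*  +  lambda * || W o (X - R) ||_1     s.t.  X = R + E

where ||.||_* is the nuclear norm, o the Hadamard product and W a
nonnegative confidence matrix: the larger W(i,j), the more the solver
is penalised for explaining entry (i,j) as error.  With W all-ones the
model is standard robust PCA.

The solver is the exact ALM scheme: each augmented-Lagrangian subproblem
is solved by alternating the two proximal maps —

    R <- svt(X - E + Y/mu, 1/mu)                      (nuclear norm)
    E <- shrink(X - R + Y/mu, lambda * W / mu)        (weighted l1)

— to an inner stationarity tolerance before the multiplier update
Y <- Y + mu (X - R - E) and penalty growth mu <- rho * mu.  An inexact
variant (one alternation per multiplier update) is available as a
config switch.  The solver is fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import (
    AssociationMatrix,
    FamilyAssignment,
    RecoveryResult,
    SimilarityMatrix,
    WeightMatrix,
)
from .similarity import (
    disease_cosine_similarity,
    family_matrix,
    integrate_disease_similarity,
    integrate_mirna_similarity,
    mirna_cosine_similarity,
)
from .weighting import build_weights, penalty_weights

__all__ = ["SolverConfig", "shrink", "svt", "ilrmr_recover", "predict_scores"]


@dataclass
class SolverConfig:
    """Parameters of the ALM solver.

    lambda_ : sparsity weight; default 1/sqrt(max(m, n)) (set when None).
    mu0     : initial penalty; default 1.25 / sigma_1(X) (set when None).
    rho     : penalty growth factor per outer iteration.
    mu_max_factor : cap on the penalty, as a multiple of mu0.  Rapid
              uncapped growth freezes the iterates at a feasible but
              slightly suboptimal point; the cap keeps them polishing.
              The default cap is effectively inactive at typical sizes;
              `high_accuracy()` lowers it for solver cross-checks.
    tol     : feasibility tolerance on ||X - R - E||_F / ||X||_F.
    inner_tol : stationarity tolerance of the inner alternation.
    max_iter  : outer (multiplier-update) iteration cap.
    method  : "exact" solves each subproblem to inner_tol; "inexact"
              performs a single alternation per multiplier update.
    """

    lambda_: float | None = None
    mu0: float | None = None
    rho: float = 1.5
    mu_max_factor: float = 1e7
    tol: float = 1e-7
    inner_tol: float = 1e-6
    max_iter: int = 500
    inner_max_iter: int = 100
    method: str = "exact"

    @classmethod
    def high_accuracy(cls, **overrides) -> "SolverConfig":
        """Slow-growth, tightly converged settings for numerical comparisons."""
        base = dict(rho=1.05, mu_max_factor=50.0, tol=1e-9, inner_tol=1e-8,
                    max_iter=5000, inner_max_iter=200)
        base.update(overrides)
        return cls(**base)

    def __post_init__(self) -> None:
        if self.lambda_ is not None and self.lambda_ <= 0:
            raise ValueError("lambda must be positive")
        if self.rho <= 1:
            raise ValueError("rho must exceed 1")
        if self.mu_max_factor < 1:
            raise ValueError("mu_max_factor must be >= 1")
        if self.tol <= 0 or self.inner_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if self.method not in ("exact", "inexact"):
            raise ValueError("method must be 'exact' or 'inexact'")


def shrink(value, threshold):
    """Soft-thresholding (l1 proximal map): sign(v) * max(|v| - t, 0)."""
    threshold = np.asarray(threshold)
    if (threshold < 0).any():
        raise ValueError("shrink threshold must be nonnegative")
    value = np.asarray(value, dtype=float)
    return np.sign(value) * np.maximum(np.abs(value) - threshold, 0.0)


def svt(matrix: np.ndarray, tau: float) -> np.ndarray:
    """Singular value thresholding (nuclear-norm proximal map)."""
    if tau < 0:
        raise ValueError("svt threshold must be nonnegative")
    U, s, Vt = np.linalg.svd(np.asarray(matrix, dtype=float), full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    keep = s > 0
    return (U[:, keep] * s[keep]) @ Vt[keep]


def _as_array(X) -> np.ndarray:
    if isinstance(X, AssociationMatrix):
        return X.values.astype(float)
    return np.asarray(X, dtype=float)


def ilrmr_recover(
    X, W: WeightMatrix | np.ndarray | None = None, config: SolverConfig | None = None
) -> RecoveryResult:
    """Solve the weighted low-rank recovery problem.

    Parameters
    ----------
    X : AssociationMatrix or real matrix to decompose.
    W : nonnegative weights of the same shape; None means all-ones
        (plain robust PCA).  An identically-zero W is replaced by
        all-ones with a warning, since it would leave E unconstrained.
    config : SolverConfig; None uses defaults.
    """
    cfg = config or SolverConfig()
    Xa = _as_array(X)
    if Xa.ndim != 2:
        raise ValueError("input must be a 2-d matrix")
    m, n = Xa.shape

    if W is None:
        Wa = np.ones((m, n))
    else:
        Wa = W.values if isinstance(W, WeightMatrix) else np.asarray(W, dtype=float)
        if Wa.shape != Xa.shape:
            raise ValueError(f"weight shape {Wa.shape} does not match X shape {Xa.shape}")
        if (Wa < 0).any():
            raise ValueError("weights must be nonnegative")
        if not Wa.any():
            warnings.warn("weight matrix is identically zero; falling back to all-ones")
            Wa = np.ones((m, n))

    lam = cfg.lambda_ if cfg.lambda_ is not None else 1.0 / np.sqrt(max(m, n))

    normX = np.linalg.norm(Xa)
    if normX == 0:
        return RecoveryResult(
            scores=np.zeros((m, n)),
            residual=np.zeros((m, n)),
            converged=True,
            iterations=0,
            objective_trace=[0.0],
            lambda_used=lam,
        )

    sigma1 = np.linalg.norm(Xa, 2)
    mu = cfg.mu0 if cfg.mu0 is not None else 1.25 / sigma1
    mu_max = mu * cfg.mu_max_factor
    Y = Xa / max(sigma1, np.abs(Xa).max() / lam)
    R = np.zeros((m, n))
    E = np.zeros((m, n))
    trace: list[float] = []
    converged = False
    it = 0

    for it in range(1, cfg.max_iter + 1):
        thresh = lam * Wa / mu
        if cfg.method == "exact":
            for _ in range(cfg.inner_max_iter):
                R_new = svt(Xa - E + Y / mu, 1.0 / mu)
                E_new = shrink(Xa - R_new + Y / mu, thresh)
                dR = np.linalg.norm(R_new - R) / normX
                dE = np.linalg.norm(E_new - E) / normX
                R, E = R_new, E_new
                if dR < cfg.inner_tol and dE < cfg.inner_tol:
                    break
        else:
            R = svt(Xa - E + Y / mu, 1.0 / mu)
            E = shrink(Xa - R + Y / mu, thresh)

        residual = Xa - R - E
        Y = Y + mu * residual
        mu = min(mu * cfg.rho, mu_max)

        trace.append(float(np.linalg.norm(R, "nuc") + lam * np.abs(Wa * E).sum()))
        if np.linalg.norm(residual) / normX <= cfg.tol:
            converged = True
            break

    return RecoveryResult(
        scores=R,
        residual=E,
        converged=converged,
        iterations=it,
        objective_trace=trace,
        lambda_used=lam,
    )


def integrated_similarities(
    assoc: AssociationMatrix,
    sim_mir_fun: SimilarityMatrix,
    sim_dd_phe: SimilarityMatrix,
    fams: FamilyAssignment | None,
    use_family_and_cosine: bool = True,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Integrated miRNA and disease similarities for a training matrix.

    With `use_family_and_cosine` False the externally supplied functional
    and semantic similarities are used as-is (the ablation setting).
    The cosine terms are always computed from `assoc` itself, so passing
    a masked training matrix keeps held-out edges out of their own scores.
    """
    sim_mir_fun = sim_mir_fun.reordered(list(assoc.mirna_ids))
    sim_dd_phe = sim_dd_phe.reordered(list(assoc.disease_ids))
    if not use_family_and_cosine:
        sim_mir = SimilarityMatrix(sim_mir_fun.values, list(sim_mir_fun.ids), "mirna_integrated")
        sim_dd = SimilarityMatrix(sim_dd_phe.values, list(sim_dd_phe.ids), "disease_integrated")
        return sim_mir, sim_dd
    fam = family_matrix(fams or FamilyAssignment.empty(), list(assoc.mirna_ids))
    sim_mir = integrate_mirna_similarity(sim_mir_fun, mirna_cosine_similarity(assoc), fam)
    sim_dd = integrate_disease_similarity(sim_dd_phe, disease_cosine_similarity(assoc))
    return sim_mir, sim_dd


def predict_scores(
    assoc: AssociationMatrix,
    sim_mir_fun: SimilarityMatrix,
    sim_dd_phe: SimilarityMatrix,
    fams: FamilyAssignment | None = None,
    config: SolverConfig | None = None,
    use_weights: bool = True,
    use_family_and_cosine: bool = True,
) -> RecoveryResult:
    """End-to-end pipeline: similarities -> weights -> weighted recovery.

    Returns a RecoveryResult whose `scores` entry (i, j) is the predicted
    association strength of miRNA i with disease j; ranking unknown pairs
    by descending score prioritises candidate associations.

    The confidence matrix W is converted into the l1 penalty weight via
    `weighting.penalty_weights` ((1+W) on observed associations,
    1/(1+W) on unknown pairs) before entering the solver.
    """
    sim_mir, sim_dd = integrated_similarities(
        assoc, sim_mir_fun, sim_dd_phe, fams, use_family_and_cosine
    )
    if use_weights:
        W = build_weights(sim_mir, sim_dd, assoc)
        penalty = penalty_weights(W, assoc)
    else:
        penalty = None
    result = ilrmr_recover(assoc, penalty, config)
    result.mirna_ids = list(assoc.mirna_ids)
    result.disease_ids = list(assoc.disease_ids)
    return result
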