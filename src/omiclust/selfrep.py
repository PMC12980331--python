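"""Per-view ADMM solver for sparse self-representation.

Each view's samples are expressed as sparse linear combinations of the other
samples, X = XZ + E with diag(Z) = 0, with an l1 penalty on both Z and the
error E. Two couplings enter through the shrinkage threshold of the Z
update: a cross-view exclusivity term (weighted by the other views' |Z|)
that pushes the supports of different views apart, and an embedding
distance term that discourages linking samples far apart in the current
spectral embedding F.

The constrained problem is split with an auxiliary copy C of Z, dual
variables Q1 (for X - XC - E) and Q2 (for C - Z), and an increasing
penalty mu.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "SelfRepState",
    "soft_threshold",
    "embedding_distance",
    "update_Z",
    "update_E",
    "update_C",
    "update_duals",
    "admm_solve",
    "factor_gram",
]


@dataclass
class SelfRepState:
    """ADMM iterates for one view."""

    Z: np.ndarray        # n x n, zero diagonal
    E: np.ndarray        # d x n, shaped like X - XC
    C: np.ndarray        # n x n auxiliary copy of Z
    Q1: np.ndarray       # dual for X - XC - E (d x n)
    Q2: np.ndarray       # dual for C - Z (n x n)
    mu: float

    @classmethod
    def zeros(cls, d: int, n: int, mu0: float) -> "SelfRepState":
        return cls(Z=np.zeros((n, n)), E=np.zeros((d, n)), C=np.zeros((n, n)),
                   Q1=np.zeros((d, n)), Q2=np.zeros((n, n)), mu=float(mu0))


def soft_threshold(A: np.ndarray, tau) -> np.ndarray:
    """Elementwise shrinkage sign(a) * max(|a| - tau, 0).

    tau may be a scalar or a matrix of A's shape; negative thresholds are
    rejected since shrinkage is undefined for them.
    """
    A = np.asarray(A, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("soft_threshold requires nonnegative thresholds")
    return np.sign(A) * np.maximum(np.abs(A) - tau, 0.0)


def embedding_distance(F: np.ndarray) -> np.ndarray:
    """Pairwise half squared distances D[i,j] = 0.5 ||f_i - f_j||^2 between
    rows of the embedding F; symmetric with zero diagonal."""
    F = np.asarray(F, dtype=float)
    sq = np.sum(F * F, axis=1)
    D = 0.5 * (sq[:, None] + sq[None, :] - 2.0 * (F @ F.T))
    D = np.maximum(D, 0.0)
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return D


def update_Z(state: SelfRepState, other_Zs: Sequence[np.ndarray], D: np.ndarray,
             xi1: float, xi2: float, xi3: float) -> np.ndarray:
    """Shrink C + Q2/mu with the combined elementwise threshold
    (xi1*1 + xi2*sum_w |Z_w| + xi3*D)/mu, then zero the diagonal."""
    n = state.C.shape[0]
    thr = xi1 * np.ones((n, n))
    for Zw in other_Zs:
        thr += xi2 * np.abs(Zw)
    thr += xi3 * D
    Zhat = soft_threshold(state.C + state.Q2 / state.mu, thr / state.mu)
    np.fill_diagonal(Zhat, 0.0)
    return Zhat


def update_E(state: SelfRepState, X: np.ndarray, XC: Optional[np.ndarray] = None) -> np.ndarray:
    """E = shrink(X - XC + Q1/mu, 1/mu)."""
    if XC is None:
        XC = X @ state.C
    return soft_threshold(X - XC + state.Q1 / state.mu, 1.0 / state.mu)


def factor_gram(X: np.ndarray):
    """Cholesky factorization of (X'X + I), cached once per view."""
    n = X.shape[1]
    return cho_factor(X.T @ X + np.eye(n))


def update_C(state: SelfRepState, X: np.ndarray, gram_factor) -> np.ndarray:
    """Solve (X'X + I) C = X'(X - E + Q1/mu) + Z - Q2/mu (diag(Z) is 0)."""
    rhs = X.T @ (X - state.E + state.Q1 / state.mu) + state.Z - state.Q2 / state.mu
    if not np.all(np.isfinite(rhs)):
        raise FloatingPointError("non-finite right-hand side in C update")
    return cho_solve(gram_factor, rhs)


def update_duals(state: SelfRepState, X: np.ndarray, rho: float, mu_max: float,
                 XC: Optional[np.ndarray] = None) -> tuple[np.ndarray, np.ndarray, float]:
    """Ascent on both duals, then geometric penalty growth capped at mu_max."""
    if XC is None:
        XC = X @ state.C
    Q1 = state.Q1 + state.mu * (X - XC - state.E)
    Q2 = state.Q2 + state.mu * (state.C - state.Z)
    mu = min(state.mu * rho, mu_max)
    return Q1, Q2, mu


def admm_solve(X: np.ndarray, other_Zs: Sequence[np.ndarray], F: np.ndarray,
               xi1: float, xi2: float, xi3: float, config,
               state: Optional[SelfRepState] = None, gram_factor=None,
               D: Optional[np.ndarray] = None) -> tuple[SelfRepState, int]:
    """Run the inner ADMM loop for one view.

    Iterates Z, E, C, duals, mu until the representation constraint residual
    ||X - XC - E||_inf drops below config.eps or T1 iterations pass. A
    caller may pass a warm state and a cached Cholesky factor of (X'X + I).
    Returns the final state (diag(Z) exactly zero) and the iteration count.
    """
    d, n = X.shape
    if state is None:
        state = SelfRepState.zeros(d, n, config.mu0)
    else:
        state.mu = float(config.mu0)
    if gram_factor is None:
        gram_factor = factor_gram(X)
    if D is None:
        D = embedding_distance(F)

    n_iter = 0
    for it in range(1, config.T1 + 1):
        n_iter = it
        state.Z = update_Z(state, other_Zs, D, xi1, xi2, xi3)
        XC = X @ state.C
        state.E = update_E(state, X, XC)
        state.C = update_C(state, X, gram_factor)
        XC = X @ state.C
        state.Q1, state.Q2, state.mu = update_duals(state, X, config.rho,
                                                    config.mu_max, XC)
        for nm, M in (("Z", state.Z), ("E", state.E), ("C", state.C)):
            if not np.all(np.isfinite(M)):
                raise FloatingPointError(f"non-finite {nm} at inner iteration {it}")
        resid = np.max(np.abs(X - XC - state.E)) if X.size else 0.0
        if resid < config.eps:
            break
    return state, n_iter
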