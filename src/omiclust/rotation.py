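"""Spectral rotation: alternating solver for the continuous indicator F,
the discrete indicator G, and the orthonormal rotation R.

The subproblem minimizes Tr(F'LF) + eta ||F - GR||_F^2 subject to F >= 0
(with F'F = I enforced softly through a sigma penalty), R'R = I, and G a
one-1-per-row indicator. F follows a nonnegative multiplicative update
built from the positive/negative split of L; G assigns each sample to its
nearest row of R; R is the orthogonal Procrustes solution for fixed F, G.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EmbeddingState",
    "split_pos_neg",
    "update_F",
    "update_G",
    "update_R",
    "rotation_solve",
]

_DENOM_FLOOR = 1e-12
# zero is an absorbing state of the multiplicative F update; keeping
# iterates strictly positive lets a deflated indicator column regrow
_F_FLOOR = 1e-8


@dataclass
class EmbeddingState:
    F: np.ndarray   # n x c, nonnegative soft indicator
    R: np.ndarray   # c x c orthonormal
    G: np.ndarray   # n x c binary indicator, one 1 per row
    n_iter: int = 0


def split_pos_neg(L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split L = L_plus - L_minus with both parts nonnegative:
    L_plus = (|L| + L)/2, L_minus = (|L| - L)/2."""
    A = np.abs(L)
    return 0.5 * (A + L), 0.5 * (A - L)


def update_F(F: np.ndarray, L_plus: np.ndarray, L_minus: np.ndarray,
             G: np.ndarray, R: np.ndarray, eta: float, sigma: float) -> np.ndarray:
    """One multiplicative update of the nonnegative soft indicator.

    F <- F * (L_minus F + (eta GR)^+ + sigma F) /
             (L_plus F + (eta GR)^- + eta F + sigma F F'F)
    with the denominator floored; preserves nonnegativity elementwise.
    """
    GR = eta * (G @ R)
    GR_plus, GR_minus = split_pos_neg(GR)
    num = L_minus @ F + GR_plus + sigma * F
    den = L_plus @ F + GR_minus + eta * F + sigma * (F @ (F.T @ F))
    Fn = F * (num / np.maximum(den, _DENOM_FLOOR))
    if not np.all(np.isfinite(Fn)):
        raise FloatingPointError("non-finite F in multiplicative update")
    return Fn


def update_G(F: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Assign each sample i to argmin_k ||f_i - r_k||^2 over rows r_k of R
    (ties break to the smallest k); returns the binary indicator."""
    n, c = F.shape
    # ||f_i - r_k||^2 = ||f_i||^2 - 2 f_i.r_k + ||r_k||^2
    d2 = (np.sum(F * F, axis=1)[:, None] - 2.0 * F @ R.T
          + np.sum(R * R, axis=1)[None, :])
    k = np.argmin(d2, axis=1)
    G = np.zeros((n, c))
    G[np.arange(n), k] = 1.0
    return G


def update_R(F: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Orthogonal Procrustes solution R = U V' for G'F = U S V'; falls back
    to the identity (with a warning) when G'F is identically zero.

    When G has empty clusters, their rows of G'F are zero, so the
    corresponding rows of R do not affect the objective and the SVD leaves
    them arbitrary. Among the equally optimal solutions we point each such
    row at the worst-fit sample (re-orthonormalized against the determined
    rows), which lets an emptied cluster recapture members in the next G
    update instead of staying dead.
    """
    M = G.T @ F
    if not M.any():
        warnings.warn("G'F is all-zero; rotation reset to identity", stacklevel=2)
        return np.eye(F.shape[1])
    U, _, Vt = np.linalg.svd(M)
    R = U @ Vt
    empty = np.flatnonzero(G.sum(axis=0) == 0)
    if empty.size:
        R = _retarget_empty_rows(R, F, G, empty)
    return R


def _retarget_empty_rows(R: np.ndarray, F: np.ndarray, G: np.ndarray,
                         empty: np.ndarray) -> np.ndarray:
    """Replace the free rows of an optimal R by unit vectors aimed at the
    samples farthest from their assigned rows, keeping R orthonormal."""
    R = R.copy()
    assigned = np.argmax(G, axis=1)
    resid = np.sum((F - R[assigned]) ** 2, axis=1)
    order = np.argsort(resid)[::-1]
    kept = [k for k in range(R.shape[0]) if k not in set(empty)]
    for k in empty:
        for i in order:
            v = F[i].astype(float).copy()
            for j in kept:
                v -= (v @ R[j]) * R[j]
            nv = np.linalg.norm(v)
            if nv > 1e-8:
                R[k] = v / nv
                kept.append(k)
                break
        else:
            kept.append(k)  # no usable direction; keep the SVD's row
    return R


def rotation_solve(L: np.ndarray, F0: np.ndarray, R0: np.ndarray,
                   eta: float, sigma: float, config,
                   G0: np.ndarray | None = None) -> EmbeddingState:
    """Alternate F -> G -> R until the rotation stabilizes.

    Stops when the spectral norm of R_{t+1} - R_t falls below config.eps or
    after config.T2 iterations. F0 must be positive (zero entries are fixed
    points of the multiplicative update) and R0 orthonormal.
    """
    F = np.asarray(F0, dtype=float).copy()
    R = np.asarray(R0, dtype=float).copy()
    n, c = F.shape
    G = np.zeros((n, c)) if G0 is None else np.asarray(G0, dtype=float).copy()
    L_plus, L_minus = split_pos_neg(L)

    n_iter = 0
    for it in range(1, config.T2 + 1):
        n_iter = it
        F = np.maximum(update_F(F, L_plus, L_minus, G, R, eta, sigma), _F_FLOOR)
        G = update_G(F, R)
        R_new = update_R(F, G)
        dR = np.linalg.norm(R_new - R, 2)
        R = R_new
        if dR < config.eps:
            break
    if (G.sum(axis=0) == 0).any():
        warnings.warn("rotation left empty cluster(s) in G", stacklevel=2)
    return EmbeddingState(F=F, R=R, G=G, n_iter=n_iter)
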