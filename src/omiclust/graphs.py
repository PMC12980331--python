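"""Graph Laplacians from self-representations and base partitions, and
self-weighted ensemble coefficients.

A view's affinity is the symmetrized absolute self-representation
S = (|Z| + |Z'|)/2; a base partition contributes the co-membership matrix
S_p = Y_p Y_p'. Each base clustering is weighted by beta_p = 1/(2 Tr(F'L_pF)),
so partitions agreeing with the current embedding F (small trace) receive
large weight without any extra tuning parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GraphLaplacian",
    "affinity_from_Z",
    "graph_laplacian",
    "base_graph",
    "compute_beta",
    "combine_laplacian",
]

EPS_TR = 1e-8  # floor on Tr(F'L_pF) so perfect agreement keeps beta finite


@dataclass
class GraphLaplacian:
    L: np.ndarray
    S: np.ndarray
    kind: str = "view"   # "view" | "base"


def affinity_from_Z(Z: np.ndarray, signed: bool = False) -> np.ndarray:
    """Symmetric nonnegative affinity from a self-representation matrix.

    Default is (|Z| + |Z'|)/2 which guarantees a positive-semidefinite
    Laplacian; signed=True keeps (Z + Z')/2 for cross-checking.
    """
    Z = np.asarray(Z, dtype=float)
    if signed:
        return 0.5 * (Z + Z.T)
    return 0.5 * (np.abs(Z) + np.abs(Z.T))


def graph_laplacian(S: np.ndarray, kind: str = "view") -> GraphLaplacian:
    """Unnormalized Laplacian L = D - S with D the diagonal of row sums."""
    S = np.asarray(S, dtype=float)
    L = np.diag(S.sum(axis=1)) - S
    return GraphLaplacian(L=L, S=S, kind=kind)


def base_graph(base) -> GraphLaplacian:
    """Co-membership graph S_p = Y_p Y_p' of a base partition (diagonal 1s
    included; self-loops cancel in L_p = D_p - S_p)."""
    Y = np.asarray(base.Y, dtype=float)
    S = Y @ Y.T
    return graph_laplacian(S, kind="base")


def compute_beta(F: np.ndarray, base_laplacians: Sequence[GraphLaplacian],
                 eps_tr: float = EPS_TR) -> np.ndarray:
    """Self-derived ensemble weights beta_p = 1/(2 Tr(F'L_pF)), the trace
    floored at eps_tr."""
    F = np.asarray(F, dtype=float)
    beta = np.empty(len(base_laplacians))
    for p, gl in enumerate(base_laplacians):
        tr = float(np.trace(F.T @ gl.L @ F))
        beta[p] = 1.0 / (2.0 * max(tr, eps_tr))
    return beta


def combine_laplacian(view_laplacians: Sequence[GraphLaplacian],
                      base_laplacians: Sequence[GraphLaplacian],
                      beta: np.ndarray, xi3: float, delta: float) -> np.ndarray:
    """L = xi3 (sum_v L_v + delta sum_p beta_p L_p); delta = 0 drops the
    ensemble term entirely."""
    n = view_laplacians[0].L.shape[0]
    L = np.zeros((n, n))
    for gl in view_laplacians:
        L += gl.L
    if delta != 0 and base_laplacians:
        for b, gl in zip(np.asarray(beta, dtype=float), base_laplacians):
            L += delta * b * gl.L
    L *= xi3
    return 0.5 * (L + L.T)
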