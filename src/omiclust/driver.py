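"""Outer alternating loop: parameter schedule, ensemble weights, per-view
ADMM, Laplacian assembly and spectral rotation, with the co-clustering
stopping rule.

Per outer iteration t the regularization weights follow the schedule
xi1 = nu**(1-t) (sparsity, decaying), xi2 = alpha (exclusivity, constant),
xi3 = beta_sched * nu**(t-1) (graph smoothness, growing), with nu = 1.2:
early iterations emphasize sparse self-representation, later ones the
cluster structure. The loop stops when the co-clustering matrix GG' stops
changing between consecutive iterations, or after T iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .graphs import (affinity_from_Z, base_graph, combine_laplacian,
                     compute_beta, graph_laplacian)
from .io import BaseClustering, ClusteringResult, Config, MultiOmicsDataset
from .rotation import rotation_solve
from .selfrep import SelfRepState, admm_solve, embedding_distance, factor_gram

logger = logging.getLogger("omiclust")

__all__ = ["Schedule", "schedule_at", "fit", "fit_two_step", "grid_search"]


@dataclass
class Schedule:
    t: int
    xi1: float
    xi2: float
    xi3: float


def schedule_at(t: int, config: Config) -> Schedule:
    """Weights at 1-based outer iteration t: xi1 = nu^(1-t), xi2 = alpha,
    xi3 = beta_sched * nu^(t-1)."""
    nu = config.nu
    return Schedule(t=t, xi1=nu ** (1 - t), xi2=config.alpha,
                    xi3=config.beta_sched * nu ** (t - 1))


def _init_embedding(n: int, c: int, rng: np.random.Generator):
    F = rng.uniform(0.0, 1.0, size=(n, c))
    F /= np.linalg.norm(F, axis=0, keepdims=True)
    A = rng.standard_normal((c, c))
    Q, _ = np.linalg.qr(A)
    return F, Q


def _objective(states, Zs, F, G, R, L, sched, eta) -> float:
    """Full joint objective at the end of an outer iteration."""
    obj = 0.0
    V = len(Zs)
    for v in range(V):
        obj += np.abs(states[v].E).sum() + sched.xi1 * np.abs(Zs[v]).sum()
        for w in range(V):
            if w != v:
                obj += sched.xi2 * np.abs(Zs[v] * Zs[w]).sum()
    obj += float(np.trace(F.T @ L @ F))
    obj += eta * float(np.sum((F - G @ R) ** 2))
    return obj


def _outer_loop(dataset: MultiOmicsDataset, bases: Sequence[BaseClustering],
                config: Config):
    n = dataset.n_samples
    V = dataset.n_views
    c = config.c
    if c > n:
        raise ValueError(f"c={c} exceeds the number of samples n={n}")

    Xs = [v.values for v in dataset.views]
    rng = np.random.default_rng(config.seed)
    F, R = _init_embedding(n, c, rng)
    G = np.zeros((n, c))

    base_Ls = [base_graph(b) for b in bases]
    delta = config.delta if bases else 0.0

    grams = [factor_gram(X) for X in Xs]
    states = [SelfRepState.zeros(X.shape[0], n, config.mu0) for X in Xs]

    co_prev = None
    trace: list[dict] = []
    beta = np.zeros(len(bases))
    n_iter = 0

    for t in range(1, config.T + 1):
        n_iter = t
        sched = schedule_at(t, config)

        if bases:
            beta = compute_beta(F, base_Ls, eps_tr=config.eps_tr)

        D = embedding_distance(F)
        for v in range(V):
            others = [states[w].Z for w in range(V) if w != v]
            states[v], inner = admm_solve(
                Xs[v], others, F, sched.xi1, sched.xi2, sched.xi3,
                config, state=states[v], gram_factor=grams[v], D=D)
            if not np.all(np.isfinite(states[v].Z)):
                raise FloatingPointError(f"non-finite Z at outer iteration {t}, view {v}")

        Zs = [s.Z for s in states]
        view_Ls = [graph_laplacian(affinity_from_Z(Z)) for Z in Zs]
        L = combine_laplacian(view_Ls, base_Ls, beta, sched.xi3, delta)

        emb = rotation_solve(L, F, R, config.eta, config.sigma, config, G0=G)
        F, R, G = emb.F, emb.R, emb.G

        obj = _objective(states, Zs, F, G, R, L, sched, config.eta)
        trace.append({"t": t, "objective": obj, "xi1": sched.xi1,
                      "xi3": sched.xi3, "beta": beta.tolist(),
                      "rotation_iters": emb.n_iter})
        logger.info("outer t=%d objective=%.6g rotation_iters=%d beta=%s",
                    t, obj, emb.n_iter, np.round(beta, 4).tolist())

        co = G @ G.T
        if co_prev is not None and np.max(np.abs(co - co_prev)) < config.gtol:
            break
        co_prev = co

    return F, R, G, beta, trace, n_iter, [s.Z for s in states]


def fit(dataset: MultiOmicsDataset, bases: Sequence[BaseClustering],
        config: Config) -> ClusteringResult:
    """One-step multi-omics clustering: the discrete indicator G is produced
    inside the joint optimization, labels are its row argmax."""
    F, R, G, beta, trace, n_iter, Zs = _outer_loop(dataset, list(bases), config)
    labels = np.argmax(G, axis=1)
    return ClusteringResult(labels=labels, G=G, F=F, R=R, beta=beta,
                            objective_trace=trace, n_iter=n_iter,
                            sample_ids=list(dataset.sample_ids), Z_views=Zs)


def fit_two_step(dataset: MultiOmicsDataset, bases: Sequence[BaseClustering],
                 config: Config) -> ClusteringResult:
    """Two-step variant: same pipeline, but the final labels come from
    k-means (10 seeded restarts) on the rows of the continuous indicator F
    instead of the jointly learned G."""
    from sklearn.cluster import KMeans

    F, R, G, beta, trace, n_iter, Zs = _outer_loop(dataset, list(bases), config)
    km = KMeans(n_clusters=config.c, n_init=10,
                random_state=int(config.seed) % (2 ** 31)).fit(F)
    labels = np.asarray(km.labels_)
    G2 = np.zeros_like(G)
    G2[np.arange(len(labels)), labels] = 1.0
    return ClusteringResult(labels=labels, G=G2, F=F, R=R, beta=beta,
                            objective_trace=trace, n_iter=n_iter,
                            sample_ids=list(dataset.sample_ids), Z_views=Zs)


def grid_search(dataset: MultiOmicsDataset, bases: Sequence[BaseClustering],
                config: Config, grid: dict[str, Sequence[float]],
                truth: Optional[np.ndarray] = None,
                stability_seeds: Sequence[int] = (0, 1, 2)) -> tuple[Config, list[dict]]:
    """Sweep hyperparameter grids, scoring each cell by NMI against truth
    when given, otherwise by mean pairwise NMI across reruns with different
    seeds (stability). Returns the best config and the score table."""
    import itertools

    from .metrics import nmi

    names = list(grid)
    table: list[dict] = []
    best_cfg, best_score = config, -np.inf
    for combo in itertools.product(*(grid[k] for k in names)):
        cfg = config.with_(**dict(zip(names, combo)))
        if truth is not None:
            score = nmi(fit(dataset, bases, cfg).labels, truth)
        else:
            runs = [fit(dataset, bases, cfg.with_(seed=s)).labels
                    for s in stability_seeds]
            pairs = [nmi(a, b) for i, a in enumerate(runs) for b in runs[i + 1:]]
            score = float(np.mean(pairs))
        table.append({**dict(zip(names, combo)), "score": score})
        if score > best_score:
            best_cfg, best_score = cfg, score
    return best_cfg, table
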