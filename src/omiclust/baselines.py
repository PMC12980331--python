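"""Built-in base-clustering providers: spectral clustering, k-means, and a
compact similarity-network-fusion (SNF) implementation.

Each provider is a pure function of (data, parameters, seed) and returns a
hard partition as a BaseClustering indicator matrix, ready to feed the
ensemble term of the main solver or to serve as a standalone baseline.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np

from .io import BaseClustering, MultiOmicsDataset, OmicsView, zscore_features

__all__ = [
    "spectral_cluster",
    "kmeans_cluster",
    "snf_fuse",
    "snf_affinity",
    "local_scaling_affinity",
]


def _samples_matrix(data: Union[OmicsView, np.ndarray]) -> np.ndarray:
    """Samples-as-rows matrix from a view (features x samples) or an array
    already in samples x features orientation."""
    if isinstance(data, OmicsView):
        return data.values.T
    return np.asarray(data, dtype=float)


def _hard(labels: np.ndarray, name: str,
          sample_ids: Optional[Sequence[str]]) -> BaseClustering:
    return BaseClustering.from_labels(labels.tolist(), name=name,
                                      sample_ids=sample_ids)


# ---------------------------------------------------------------------------
# spectral clustering with local-scaling affinity
# ---------------------------------------------------------------------------

def local_scaling_affinity(X: np.ndarray, K: int = 15) -> np.ndarray:
    """Gaussian k-NN affinity with per-sample local-scaling bandwidths:
    W_ij = exp(-d_ij^2 / (s_i s_j)) with s_i the distance to the K-th
    neighbour, kept on the union of k-NN edges and symmetrized."""
    from scipy.spatial.distance import squareform, pdist

    n = X.shape[0]
    K = min(K, n - 1)
    d = squareform(pdist(X))
    order = np.sort(d, axis=1)
    s = order[:, K]                       # K-th nearest (column 0 is self)
    s = np.maximum(s, 1e-12)
    W = np.exp(-(d ** 2) / (s[:, None] * s[None, :]))
    np.fill_diagonal(W, 0.0)
    # sparsify to union of k-NN edges
    keep = np.zeros_like(W, dtype=bool)
    nn = np.argsort(d, axis=1)[:, 1:K + 1]
    rows = np.repeat(np.arange(n), nn.shape[1])
    keep[rows, nn.ravel()] = True
    keep |= keep.T
    W = np.where(keep, W, 0.0)
    return 0.5 * (W + W.T)


def _spectral_on_affinity(W: np.ndarray, c: int, seed: int) -> np.ndarray:
    from sklearn.cluster import SpectralClustering

    sc = SpectralClustering(n_clusters=c, affinity="precomputed",
                            assign_labels="kmeans", n_init=10,
                            random_state=int(seed) % (2 ** 31))
    return np.asarray(sc.fit_predict(W))


def spectral_cluster(data: Union[OmicsView, np.ndarray], c: int, seed: int = 0,
                     K: int = 15, name: Optional[str] = None) -> BaseClustering:
    """Normalized-cuts spectral clustering of one view on a local-scaling
    Gaussian k-NN affinity; deterministic given the seed."""
    X = _samples_matrix(data)
    n = X.shape[0]
    nm = name or (f"spectral-{data.name}" if isinstance(data, OmicsView) else "spectral")
    sids = data.sample_ids if isinstance(data, OmicsView) else None
    if c >= n:
        return _hard(np.arange(n), nm, sids)
    W = local_scaling_affinity(X, K=K)
    return _hard(_spectral_on_affinity(W, c, seed), nm, sids)


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------

def kmeans_cluster(data: Union[OmicsView, MultiOmicsDataset, np.ndarray],
                   c: int, seed: int = 0,
                   name: str = "kmeans") -> BaseClustering:
    """Lloyd's k-means with 10 seeded restarts; a MultiOmicsDataset is
    z-scored per feature and concatenated across views first."""
    from sklearn.cluster import KMeans

    if isinstance(data, MultiOmicsDataset):
        X = np.vstack([zscore_features(v).values for v in data.views]).T
        sids = data.sample_ids
    else:
        X = _samples_matrix(data)
        sids = data.sample_ids if isinstance(data, OmicsView) else None
    c = min(c, X.shape[0])
    km = KMeans(n_clusters=c, n_init=10, random_state=int(seed) % (2 ** 31)).fit(X)
    return _hard(np.asarray(km.labels_), name, sids)


# ---------------------------------------------------------------------------
# compact SNF
# ---------------------------------------------------------------------------

def _snf_kernel(X: np.ndarray, K: int, mu: float) -> np.ndarray:
    """Scaled-exponential similarity kernel: bandwidth at pair (i,j) is the
    average of the mean distances to each sample's K nearest neighbours and
    the pair's own distance."""
    from scipy.spatial.distance import squareform, pdist

    n = X.shape[0]
    K = min(K, n - 1)
    d = squareform(pdist(X))
    srt = np.sort(d, axis=1)
    T = srt[:, 1:K + 1].mean(axis=1)
    eps = (T[:, None] + T[None, :] + d) / 3.0
    eps = np.maximum(eps, 1e-12)
    W = np.exp(-(d ** 2) / (2.0 * (mu * eps) ** 2))
    return 0.5 * (W + W.T)


def _row_normalize(W: np.ndarray) -> np.ndarray:
    """Full-graph transition matrix P with mass 1/2 on the diagonal and the
    rest spread proportionally to off-diagonal similarities."""
    P = W.copy()
    np.fill_diagonal(P, 0.0)
    rs = P.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    P = P / (2.0 * rs)
    np.fill_diagonal(P, 0.5)
    return P


def _local_transition(W: np.ndarray, K: int) -> np.ndarray:
    """Sparse k-NN transition matrix used as the diffusion operator."""
    n = W.shape[0]
    K = min(K, n - 1)
    S = np.zeros_like(W)
    Woff = W.copy()
    np.fill_diagonal(Woff, -np.inf)
    nn = np.argsort(Woff, axis=1)[:, ::-1][:, :K]
    rows = np.repeat(np.arange(n), K)
    S[rows, nn.ravel()] = W[rows, nn.ravel()]
    rs = S.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    return S / rs


def snf_affinity(dataset: MultiOmicsDataset, K: int = 20, t_snf: int = 20,
                 mu: float = 0.5) -> np.ndarray:
    """Fuse the per-view sample-similarity networks by cross-diffusion.

    Per view: scaled-exponential kernel affinity, a full transition matrix P
    and a k-NN local transition S; then t_snf rounds of
    P_v <- S_v (mean of the other views' P) S_v', renormalized and
    symmetrized each round; the fused network is the average of the final
    per-view matrices. Requires at least two views.
    """
    if dataset.n_views < 2:
        raise ValueError("similarity network fusion needs at least two views")
    Xs = [zscore_features(v).values.T for v in dataset.views]
    Ws = [_snf_kernel(X, K, mu) for X in Xs]
    Ps = [_row_normalize(W) for W in Ws]
    Ss = [_local_transition(W, K) for W in Ws]
    V = len(Ps)
    for _ in range(t_snf):
        new = []
        for v in range(V):
            other = sum(Ps[w] for w in range(V) if w != v) / (V - 1)
            P = Ss[v] @ other @ Ss[v].T
            P = _row_normalize(0.5 * (P + P.T))
            new.append(P)
        Ps = new
    W = sum(Ps) / V
    W = 0.5 * (W + W.T)
    return W


def snf_fuse(dataset: MultiOmicsDataset, c: int, seed: int = 0, K: int = 20,
             t_snf: int = 20, mu: float = 0.5,
             name: str = "snf") -> BaseClustering:
    """SNF baseline: fuse the views' similarity networks, then spectral
    clustering of the fused network into c clusters."""
    W = snf_affinity(dataset, K=K, t_snf=t_snf, mu=mu)
    Wc = W.copy()
    np.fill_diagonal(Wc, 0.0)
    labels = _spectral_on_affinity(Wc, c, seed)
    return _hard(labels, name, dataset.sample_ids)
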