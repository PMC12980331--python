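"""Domain containers, delimited-table I/O, configuration and run logging.

Feature tables are stored features x samples (each view ``X^{(v)}`` is a
``d_v x n`` matrix over a shared sample set); label tables are two-column
``sample_id, cluster``. Readers auto-detect comma vs tab delimiters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("omiclust")

__all__ = [
    "OmicsView",
    "MultiOmicsDataset",
    "BaseClustering",
    "Config",
    "ClusteringResult",
    "read_view",
    "align_views",
    "read_labels",
    "write_labels",
    "labels_for_samples",
    "pca_preprocess",
    "prepare_views",
    "unit_norm_samples",
    "zscore_features",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class OmicsView:
    """One omics layer: a ``d_v x n`` real matrix over named samples."""

    name: str
    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = list(map(str, self.feature_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        d, n = self.values.shape
        if n < 2:
            raise ValueError(f"view {self.name!r}: need at least 2 samples, got {n}")
        if d < 1:
            raise ValueError(f"view {self.name!r}: need at least 1 feature")
        if len(self.feature_ids) != d or len(self.sample_ids) != n:
            raise ValueError(f"view {self.name!r}: id lists do not match matrix shape")
        if len(set(self.sample_ids)) != n:
            raise ValueError(f"view {self.name!r}: duplicate sample IDs")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"view {self.name!r}: non-finite value at feature "
                f"{self.feature_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsView":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OmicsView(
            name=self.name,
            values=self.values[:, idx],
            feature_ids=list(self.feature_ids),
            sample_ids=list(sample_ids),
        )


@dataclass
class MultiOmicsDataset:
    """V aligned views over one shared, ordered sample-ID list."""

    views: list[OmicsView]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if not self.views:
            raise ValueError("dataset needs at least one view")
        for v in self.views:
            if v.sample_ids != self.sample_ids:
                raise ValueError(
                    f"view {v.name!r} sample IDs differ from the dataset's shared order"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_views(self) -> int:
        return len(self.views)


@dataclass
class BaseClustering:
    """A hard base partition encoded as a binary indicator matrix Y (n x c_p)."""

    name: str
    Y: np.ndarray
    sample_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y)
        if self.Y.ndim != 2:
            raise ValueError("Y must be 2-D")
        if not set(np.unique(self.Y)).issubset({0, 1}):
            raise ValueError("Y must be binary")
        if not np.all(self.Y.sum(axis=1) == 1):
            raise ValueError("each row of Y must contain exactly one 1")
        if (self.Y.sum(axis=0) == 0).any():
            warnings.warn(f"base clustering {self.name!r} has empty clusters", stacklevel=2)

    @property
    def c_p(self) -> int:
        return self.Y.shape[1]

    @property
    def labels(self) -> np.ndarray:
        """0-based hard labels (argmax over indicator columns)."""
        return np.argmax(self.Y, axis=1)

    @classmethod
    def from_labels(cls, labels: Sequence, name: str = "base",
                    sample_ids: Optional[Sequence[str]] = None) -> "BaseClustering":
        """Build an indicator matrix, mapping distinct labels to columns in
        first-appearance order."""
        labels = list(labels)
        order: dict = {}
        for lab in labels:
            if lab not in order:
                order[lab] = len(order)
        Y = np.zeros((len(labels), len(order)), dtype=int)
        for i, lab in enumerate(labels):
            Y[i, order[lab]] = 1
        return cls(name=name, Y=Y,
                   sample_ids=None if sample_ids is None else list(map(str, sample_ids)))


@dataclass
class Config:
    """Hyperparameters and schedule constants for a clustering run.

    alpha is the exclusivity weight (xi2), beta_sched scales the Laplacian
    weight xi3 = beta_sched * nu**(t-1), delta balances base-clustering
    Laplacians against view Laplacians, eta weighs the rotation term
    ||F - GR||^2 and sigma penalizes deviation from F'F = I.
    """

    c: int = 2
    alpha: float = 0.1
    beta_sched: float = 3.0
    delta: float = 10.0
    eta: float = 1.0
    sigma: float = 100.0
    nu: float = 1.2
    rho: float = 1.2
    eps: float = 2e-4
    T: int = 10
    T1: int = 30
    T2: int = 3000
    mu0: float = 0.1
    mu_max: float = 1e8
    seed: int = 0
    pca_components: Optional[int] = None
    gtol: float = 0.05
    eps_tr: float = 1e-8

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValueError("c must be >= 2")
        if self.nu <= 1 or self.rho <= 1:
            raise ValueError("nu and rho must exceed 1")
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        for nm in ("alpha", "beta_sched", "delta", "sigma"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be nonnegative")

    def with_(self, **kw) -> "Config":
        return replace(self, **kw)


@dataclass
class ClusteringResult:
    """Final partition plus the embedding state and per-iteration diagnostics."""

    labels: np.ndarray
    G: np.ndarray
    F: np.ndarray
    R: np.ndarray
    beta: np.ndarray
    objective_trace: list[dict] = field(default_factory=list)
    n_iter: int = 0
    sample_ids: Optional[list[str]] = None
    Z_views: Optional[list[np.ndarray]] = None  # final per-view self-representations

    @property
    def n_clusters_populated(self) -> int:
        return int(len(np.unique(self.labels)))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    # engine="python" with sep=None sniffs comma vs tab
    return pd.read_csv(path, sep=None, engine="python", index_col=0)


def _check_header_unique(path) -> None:
    # pandas mangles duplicate column names on read, so inspect the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    sep = "\t" if "\t" in header else ","
    ids = header.split(sep)[1:]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate sample IDs in header")


def read_view(path, name: str) -> OmicsView:
    """Read a features x samples numeric table (first row sample IDs,
    first column feature IDs; comma or tab delimited)."""
    _check_header_unique(path)
    df = _read_table(path)
    cols = [str(c) for c in df.columns]
    body = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(body.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{path}: non-numeric or missing value at feature "
            f"{df.index[i]!r}, sample {cols[j]!r}"
        )
    return OmicsView(name=name, values=body.to_numpy(dtype=float),
                     feature_ids=[str(f) for f in df.index], sample_ids=cols)


def align_views(views: Sequence[OmicsView]) -> MultiOmicsDataset:
    """Restrict all views to their common sample IDs, ordered as in the
    first view. Idempotent; dropped IDs are logged."""
    views = list(views)
    common = set(views[0].sample_ids)
    for v in views[1:]:
        common &= set(v.sample_ids)
    if not common:
        raise ValueError("views share no sample IDs")
    order = [s for s in views[0].sample_ids if s in common]
    dropped = sorted(set().union(*(v.sample_ids for v in views)) - common)
    if dropped:
        logger.info("align_views: dropped %d sample(s): %s", len(dropped), dropped)
    aligned = [v if v.sample_ids == order else v.subset_samples(order) for v in views]
    return MultiOmicsDataset(views=aligned, sample_ids=order)


def read_labels(path, name: Optional[str] = None) -> BaseClustering:
    """Read a two-column sample_id/cluster table into a base clustering.

    Distinct cluster values map to indicator columns in first-appearance
    order; duplicate sample rows are an error.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=0)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected exactly two columns, got {df.shape[1]}")
    sids = df.iloc[:, 0].astype(str).tolist()
    if len(set(sids)) != len(sids):
        dup = next(s for s in sids if sids.count(s) > 1)
        raise ValueError(f"{path}: duplicate sample row {dup!r}")
    return BaseClustering.from_labels(df.iloc[:, 1].tolist(),
                                      name=name or str(path), sample_ids=sids)


def labels_for_samples(bc: BaseClustering, sample_ids: Sequence[str]) -> BaseClustering:
    """Reorder a base clustering's rows to match a dataset's sample order."""
    if bc.sample_ids is None:
        if bc.Y.shape[0] != len(sample_ids):
            raise ValueError("base clustering size does not match dataset")
        return bc
    pos = {s: i for i, s in enumerate(bc.sample_ids)}
    missing = [s for s in sample_ids if s not in pos]
    if missing:
        raise ValueError(f"base clustering {bc.name!r} lacks samples: {missing}")
    idx = [pos[s] for s in sample_ids]
    return BaseClustering(name=bc.name, Y=bc.Y[idx], sample_ids=list(sample_ids))


def write_labels(result, path, sample_ids: Optional[Sequence[str]] = None) -> None:
    """Write final labels as a two-column TSV, 1-based cluster numbers."""
    if isinstance(result, ClusteringResult):
        labels = result.labels
        sample_ids = sample_ids or result.sample_ids
    else:
        labels = np.asarray(result)
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(len(labels))]
    pd.DataFrame({"sample_id": list(sample_ids),
                  "cluster": np.asarray(labels) + 1}).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def zscore_features(view: OmicsView) -> OmicsView:
    """Z-score each feature across samples; zero-variance features are
    dropped with a warning."""
    mu = view.values.mean(axis=1, keepdims=True)
    sd = view.values.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    if not keep.all():
        warnings.warn(
            f"view {view.name!r}: dropping {int((~keep).sum())} zero-variance feature(s)",
            stacklevel=2,
        )
    vals = (view.values[keep] - mu[keep]) / sd[keep]
    return OmicsView(name=view.name, values=vals,
                     feature_ids=[f for f, k in zip(view.feature_ids, keep) if k],
                     sample_ids=list(view.sample_ids))


def unit_norm_samples(view: OmicsView) -> OmicsView:
    """Scale each sample column to unit Euclidean norm, so mean-separated
    clusters present as directions (near-rank-1 subspaces) to the
    self-representation solver."""
    vals = view.values / np.maximum(np.linalg.norm(view.values, axis=0), 1e-12)
    return OmicsView(name=view.name, values=vals,
                     feature_ids=list(view.feature_ids),
                     sample_ids=list(view.sample_ids))


def prepare_views(dataset: MultiOmicsDataset, k: Optional[int],
                  seed: int = 0) -> MultiOmicsDataset:
    """Standard preprocessing ahead of the solver: z-score + PCA to k
    components per view (skipped when k is None), then unit-norm samples."""
    views = []
    for v in dataset.views:
        if k is not None:
            v = pca_preprocess(v, min(k, v.n_features, v.n_samples), seed=seed)
        views.append(unit_norm_samples(v))
    return MultiOmicsDataset(views=views, sample_ids=list(dataset.sample_ids))


def pca_preprocess(view: OmicsView, k: int, seed: int = 0) -> OmicsView:
    """Z-score features then project samples onto the top-k principal axes.

    Returns a new view with k "PC" features. Each component's sign is fixed
    so its largest-magnitude loading is positive, making the output
    deterministic across SVD implementations.
    """
    from sklearn.decomposition import PCA

    zs = zscore_features(view)
    d, n = zs.values.shape
    if not (1 <= k <= min(d, n)):
        raise ValueError(f"k={k} out of range [1, {min(d, n)}]")
    pca = PCA(n_components=k, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(zs.values.T)          # n x k
    flip = np.sign(pca.components_[np.arange(k),
                                   np.argmax(np.abs(pca.components_), axis=1)])
    flip[flip == 0] = 1.0
    scores = scores * flip
    return OmicsView(name=view.name, values=scores.T,
                     feature_ids=[f"PC{i + 1}" for i in range(k)],
                     sample_ids=list(view.sample_ids))
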