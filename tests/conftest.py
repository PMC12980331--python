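import numpy as np
import pytest

from omiclust.io import MultiOmicsDataset, OmicsView


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_blob_view(name, n_per_cluster, c, d, effect, seed, sd=1.0):
    """Mean-shifted Gaussian blob view with a planted partition."""
    rng = np.random.default_rng(seed)
    n = n_per_cluster * c
    truth = np.repeat(np.arange(c), n_per_cluster)
    means = rng.normal(0, effect, size=(d, c))
    vals = means[:, truth] + rng.normal(0, sd, size=(d, n))
    view = OmicsView(name=name, values=vals,
                     feature_ids=[f"{name}_f{i}" for i in range(d)],
                     sample_ids=[f"S{i}" for i in range(n)])
    return view, truth


def make_two_subspace_data(n_per=15, d=20, dim=3, seed=0):
    """Noiseless unit-norm columns drawn from two independent subspaces."""
    rng = np.random.default_rng(seed)
    U1 = np.linalg.qr(rng.standard_normal((d, dim)))[0]
    U2 = np.linalg.qr(rng.standard_normal((d, dim)))[0]
    X = np.hstack([U1 @ rng.standard_normal((dim, n_per)),
                   U2 @ rng.standard_normal((dim, n_per))])
    X /= np.linalg.norm(X, axis=0)
    truth = np.repeat([0, 1], n_per)
    return X, truth


@pytest.fixture
def blob_dataset():
    views, truth = [], None
    for i, name in enumerate(("methylation", "miRNA", "mRNA")):
        v, truth = make_blob_view(name, n_per_cluster=15, c=3, d=40,
                                  effect=3.0, seed=100 + i)
        views.append(v)
    return MultiOmicsDataset(views=views, sample_ids=views[0].sample_ids), truth
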