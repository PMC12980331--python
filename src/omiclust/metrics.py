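"""Clustering-agreement metrics: NMI, ARI and contingency reports."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.metrics.cluster import contingency_matrix

__all__ = ["AgreementReport", "nmi", "ari", "agreement_report"]


def _check(a, b):
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("empty label vectors")
    return a, b


def nmi(a, b, average_method: str = "geometric") -> float:
    """Normalized mutual information between two partitions.

    Default normalization is the geometric mean sqrt(H(a)H(b)) (the usual
    convention in multi-view clustering); other variants ("arithmetic",
    "min", "max") are selectable for cross-checking. Two single-cluster
    partitions score 1, a single-cluster vs a split partition scores 0.
    """
    a, b = _check(a, b)
    return float(normalized_mutual_info_score(a, b, average_method=average_method))


def ari(a, b) -> float:
    """Adjusted Rand index (pair-counting agreement, chance-corrected)."""
    a, b = _check(a, b)
    return float(adjusted_rand_score(a, b))


@dataclass
class AgreementReport:
    nmi: float
    ari: float
    contingency: np.ndarray
    # reserved for merging survival endpoints computed by external tools
    logrank_neglog10_p: Optional[float] = None
    cox_c_index: Optional[float] = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"nmi": self.nmi, "ari": self.ari,
             "contingency": self.contingency.tolist()}
        if self.logrank_neglog10_p is not None:
            d["logrank_neglog10_p"] = self.logrank_neglog10_p
        if self.cox_c_index is not None:
            d["cox_c_index"] = self.cox_c_index
        d.update(self.extras)
        return d


def agreement_report(a, b) -> AgreementReport:
    """NMI + ARI + contingency table; invariant to label renaming."""
    a, b = _check(a, b)
    return AgreementReport(nmi=nmi(a, b), ari=ari(a, b),
                           contingency=contingency_matrix(a, b))
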