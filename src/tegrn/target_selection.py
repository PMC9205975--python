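"""Candidate-gene selection by intersecting two pattern clusterings.

Rhythm-gene candidates are genes whose temporal expression pattern matches a
reference gene (classically AANAT, the rate-limiting melatonin-synthesis
enzyme with a sharp night peak). Two clusterings of per-gene z-scored
profiles are run — fuzzy c-means and average-linkage agglomerative
clustering under cosine distance — and the candidate set is the intersection
of the two clusters that contain the reference gene. Using the intersection
makes the selection robust to the idiosyncrasies of either method.

Profiles are z-scored per gene before clustering so that pattern (phase and
shape), not amplitude, drives the grouping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering

__all__ = [
    "ClusterAssignment",
    "zscore_profiles",
    "fuzzy_cmeans_cluster",
    "cosine_cluster",
    "select_by_reference",
]

DEFAULT_N_CLUSTERS = 12


@dataclass
class ClusterAssignment:
    """Hard labels (and, for fuzzy methods, the membership matrix).

    ``labels`` maps gene name -> integer cluster id; for fuzzy methods the
    hard label is the argmax membership and ``membership`` rows sum to 1.
    """

    labels: pd.Series
    method: str
    n_clusters: int
    membership: pd.DataFrame | None = None
    objective_history: list[float] = field(default_factory=list)

    def members(self, cluster: int) -> set[str]:
        return set(self.labels.index[self.labels == cluster])

    def cluster_of(self, gene: str) -> int:
        if gene not in self.labels.index:
            raise KeyError(f"gene {gene!r} not present in clustering")
        return int(self.labels.loc[gene])


def zscore_profiles(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score; raises on zero-variance genes (filter them first)."""
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=0)
    if np.any(sd == 0):
        bad = matrix.index[sd == 0].tolist()
        raise ValueError(f"zero-variance profiles cannot be z-scored: {bad}")
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def fuzzy_cmeans_cluster(
    matrix: pd.DataFrame,
    n_clusters: int = DEFAULT_N_CLUSTERS,
    fuzzifier: float = 2.0,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 1000,
) -> ClusterAssignment:
    """Fuzzy c-means (Bezdek) on per-gene z-scored profiles.

    Memberships u_ic weight each gene's contribution to each cluster centre
    by u^m (m = ``fuzzifier`` > 1); the update alternates centres and
    memberships until the largest membership change falls below ``tol``.
    The objective Σ u^m ||x − c||² is non-increasing across iterations.
    """
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must be > 1")
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if len(matrix) < n_clusters:
        raise ValueError("need at least n_clusters genes")

    if n_clusters == 1:
        u = pd.DataFrame(np.ones((len(matrix), 1)), index=matrix.index)
        labels = pd.Series(0, index=matrix.index)
        return ClusterAssignment(labels, "fuzzy_cmeans", 1, membership=u)

    x = zscore_profiles(matrix).to_numpy()
    n, _ = x.shape
    rng = np.random.default_rng(seed)
    u = rng.random((n, n_clusters))
    u /= u.sum(axis=1, keepdims=True)

    history: list[float] = []
    converged = False
    for _ in range(max_iter):
        um = u**fuzzifier
        centers = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        history.append(float((um * d2).sum()))
        d2 = np.maximum(d2, 1e-300)  # genes coincident with a centre
        inv = d2 ** (-1.0 / (fuzzifier - 1.0))
        new_u = inv / inv.sum(axis=1, keepdims=True)
        if np.max(np.abs(new_u - u)) < tol:
            u = new_u
            converged = True
            break
        u = new_u
    if not converged:
        warnings.warn(
            f"fuzzy c-means did not converge in {max_iter} iterations; "
            "returning best-so-far memberships",
            UserWarning,
            stacklevel=2,
        )
    labels = pd.Series(np.argmax(u, axis=1), index=matrix.index)
    membership = pd.DataFrame(u, index=matrix.index)
    return ClusterAssignment(
        labels, "fuzzy_cmeans", n_clusters, membership=membership, objective_history=history
    )


def cosine_cluster(matrix: pd.DataFrame, n_clusters: int = DEFAULT_N_CLUSTERS) -> ClusterAssignment:
    """Average-linkage agglomerative clustering under cosine distance."""
    if len(matrix) < n_clusters:
        raise ValueError("need at least n_clusters genes")
    x = zscore_profiles(matrix).to_numpy()
    norms = np.linalg.norm(x, axis=1)
    if np.any(norms == 0):
        bad = matrix.index[norms == 0].tolist()
        raise ValueError(f"zero-norm profiles have no cosine direction: {bad}")
    if n_clusters == len(matrix):
        labels = pd.Series(np.arange(len(matrix)), index=matrix.index)
    else:
        model = AgglomerativeClustering(
            n_clusters=n_clusters, metric="cosine", linkage="average"
        )
        labels = pd.Series(model.fit_predict(x), index=matrix.index)
    return ClusterAssignment(labels, "cosine_agglomerative", n_clusters)


def select_by_reference(
    assign_a: ClusterAssignment, assign_b: ClusterAssignment, reference_gene: str
) -> set[str]:
    """Genes in both methods' reference-gene clusters (reference included)."""
    cluster_a = assign_a.members(assign_a.cluster_of(reference_gene))
    cluster_b = assign_b.members(assign_b.cluster_of(reference_gene))
    return cluster_a & cluster_b
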