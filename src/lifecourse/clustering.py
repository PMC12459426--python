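"""Hierarchical, partitional and consensus clustering of selected terms.

The primary grouping is UPGMA (average-linkage agglomerative clustering) on
cosine distances, cut into k = 5 flat clusters by default.  Cluster-number
diagnostics (Calinski-Harabasz, silhouette, gap statistic) are always
available alongside; the cut itself stays a user choice.

Robustness of a cut is quantified by consensus clustering: alternative
algorithms (single/complete linkage, K-means, Gaussian mixtures) each
produce k clusters, and the consensus matrix records the fraction of
methods co-assigning each term pair.  A term's consensus score is its mean
co-clustering frequency with the other members of its reference cluster.

K-means and Gaussian mixtures operate on L2-normalized embedding vectors
(so Euclidean geometry approximates cosine geometry); hierarchical methods
operate on the cosine-distance matrix directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score
from sklearn.mixture import GaussianMixture

from .similarity import DistanceMatrix

__all__ = [
    "ClusterAssignment",
    "upgma_cluster",
    "hierarchical_cluster",
    "cluster_number_diagnostics",
    "ConsensusMatrix",
    "consensus_from_assignments",
    "consensus_cluster",
]

DEFAULT_K = 5
CONSENSUS_METHODS = ("single", "complete", "kmeans", "gmm")


@dataclass
class ClusterAssignment:
    """Flat clustering of terms plus the agglomeration tree that produced it."""

    terms: list[str]
    labels: np.ndarray  # cluster ids 1..k
    linkage_matrix: np.ndarray | None = None

    @property
    def k(self) -> int:
        return len(np.unique(self.labels))

    def as_dict(self) -> dict[str, int]:
        return {t: int(c) for t, c in zip(self.terms, self.labels)}

    def members(self, cluster: int) -> list[str]:
        return [t for t, c in zip(self.terms, self.labels) if c == cluster]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.terms, "cluster": self.labels.astype(int)})

    def to_newick(self) -> str:
        """Dendrogram in Newick form (requires the linkage tree)."""
        if self.linkage_matrix is None:
            raise ValueError("no linkage tree stored")
        tree = to_tree(self.linkage_matrix)

        def render(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.terms[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return render(tree, tree.dist) + ";"


def hierarchical_cluster(distance: DistanceMatrix, k: int, method: str) -> ClusterAssignment:
    """Agglomerative clustering of a cosine-distance matrix, flat cut at k."""
    n = len(distance.terms)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    Z = linkage(squareform(distance.values, checks=True), method=method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterAssignment(list(distance.terms), labels, Z)


def upgma_cluster(distance: DistanceMatrix, k: int = DEFAULT_K) -> ClusterAssignment:
    """UPGMA (average linkage) on average cosine distances, cut into k."""
    return hierarchical_cluster(distance, k, method="average")


# ---------------------------------------------------------------------------
# Cluster-number diagnostics
# ---------------------------------------------------------------------------

def _within_dispersion(x: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for c in np.unique(labels):
        pts = x[labels == c]
        w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return w


def cluster_number_diagnostics(
    embeddings: np.ndarray,
    k_range=range(2, 9),
    n_ref: int = 50,
    seed: int = 0,
    n_init: int = 10,
) -> pd.DataFrame:
    """Compactness/separation indices per candidate cluster number.

    K-means (seeded, ``n_init`` restarts) partitions the L2-normalized
    vectors at each k; reported are the Calinski-Harabasz index, the
    silhouette score (cosine metric), and the gap statistic with ``n_ref``
    reference datasets drawn uniformly inside the data's bounding box.
    """
    x = np.asarray(embeddings, dtype=float)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-norm embedding row")
    xn = x / norms
    if np.allclose(xn, xn[0]):
        raise ValueError("degenerate input: all points identical")
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    lo, hi = xn.min(axis=0), xn.max(axis=0)
    refs = [rng.uniform(lo, hi, size=xn.shape) for _ in range(n_ref)]

    rows = []
    for k in k_range:
        if not 2 <= k <= n - 1:
            raise ValueError(f"k={k} outside [2, n-1]")
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(xn)
        labels = km.labels_
        ch = calinski_harabasz_score(xn, labels)
        sil = silhouette_score(xn, labels, metric="cosine")
        log_wk = np.log(_within_dispersion(xn, labels))
        ref_logs = []
        for b, ref in enumerate(refs):
            rkm = KMeans(n_clusters=k, n_init=1, random_state=seed + b + 1).fit(ref)
            ref_logs.append(np.log(_within_dispersion(ref, rkm.labels_)))
        gap = float(np.mean(ref_logs) - log_wk)
        rows.append((k, float(ch), float(sil), gap))
    return pd.DataFrame(rows, columns=["k", "calinski_harabasz", "silhouette", "gap_statistic"])


# ---------------------------------------------------------------------------
# Consensus clustering
# ---------------------------------------------------------------------------

@dataclass
class ConsensusMatrix:
    """Term-pair co-clustering frequencies across clustering methods."""

    terms: list[str]
    values: np.ndarray  # symmetric, diagonal 1, entries in [0, 1]
    n_methods: int

    def per_term_scores(self, reference: ClusterAssignment) -> pd.Series:
        """Mean co-clustering frequency with the reference cluster's other members.

        Singleton clusters get score 1 (a term always co-clusters with itself).
        """
        idx = {t: i for i, t in enumerate(self.terms)}
        scores = {}
        for c in np.unique(reference.labels):
            members = reference.members(int(c))
            for t in members:
                others = [idx[m] for m in members if m != t]
                scores[t] = float(self.values[idx[t], others].mean()) if others else 1.0
        return pd.Series(scores, name="consensus_score")


def consensus_from_assignments(
    terms: list[str], assignments: list[np.ndarray]
) -> ConsensusMatrix:
    """Co-membership frequency over a list of flat label vectors.

    Invariant to label permutation within any assignment (only co-membership
    matters).
    """
    if not assignments:
        raise ValueError("need at least one assignment")
    n = len(terms)
    acc = np.zeros((n, n))
    for labels in assignments:
        labels = np.asarray(labels)
        if labels.shape != (n,):
            raise ValueError("assignment length mismatch")
        acc += (labels[:, None] == labels[None, :]).astype(float)
    values = acc / len(assignments)
    np.fill_diagonal(values, 1.0)
    return ConsensusMatrix(list(terms), values, len(assignments))


def consensus_cluster(
    embeddings: np.ndarray,
    distance: DistanceMatrix,
    k: int = DEFAULT_K,
    methods=CONSENSUS_METHODS,
    reference: ClusterAssignment | None = None,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[ConsensusMatrix, pd.Series]:
    """Consensus matrix + per-term scores across alternative clusterings.

    Hierarchical methods cluster the cosine-distance matrix; K-means and
    Gaussian mixtures cluster L2-normalized embedding rows (seeded,
    ``n_init`` restarts).  A method that fails to produce k non-empty
    clusters is excluded with a warning.  The per-term score is computed
    against ``reference`` (UPGMA at the same k when not given).
    """
    if len(methods) < 2:
        raise ValueError("need at least 2 methods for a consensus")
    x = np.asarray(embeddings, dtype=float)
    if x.shape[0] != len(distance.terms):
        raise ValueError("embeddings and distance matrix disagree on n terms")
    xn = x / np.linalg.norm(x, axis=1, keepdims=True)

    assignments = []
    for method in methods:
        try:
            if method in ("single", "complete", "average"):
                labels = hierarchical_cluster(distance, k, method).labels
            elif method == "kmeans":
                labels = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(xn).labels_
            elif method == "gmm":
                gm = GaussianMixture(
                    n_components=k,
                    n_init=n_init,
                    random_state=seed,
                    covariance_type="diag",
                    reg_covar=1e-4,
                ).fit(xn)
                labels = gm.predict(xn)
            else:
                raise ValueError(f"unknown consensus method: {method!r}")
        except ValueError:
            raise
        except Exception as exc:  # numerical failure of one method
            warnings.warn(f"consensus method {method!r} failed and was excluded: {exc}")
            continue
        if len(np.unique(labels)) != k:
            warnings.warn(
                f"consensus method {method!r} produced "
                f"{len(np.unique(labels))} != {k} clusters; excluded"
            )
            continue
        assignments.append(np.asarray(labels))

    if not assignments:
        raise RuntimeError("no consensus method produced a valid assignment")
    consensus = consensus_from_assignments(list(distance.terms), assignments)
    if reference is None:
        reference = upgma_cluster(distance, k)
    scores = consensus.per_term_scores(reference)
    return consensus, scores
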