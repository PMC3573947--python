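"""Unsupervised structure: hierarchical clustering and PCA.

Samples are clustered on their beta profiles with complete linkage over
the cosine distance d(x, y) = 1 - x.y / (|x||y|); the two-group cut of
the dendrogram is compared against case/control labels.  Ordination uses
per-probe median centering, k-nearest-neighbour imputation of missing
values (neighbours are probes, Euclidean over shared samples) and
standard principal components with a deterministic sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.impute import KNNImputer


@dataclass
class Dendrogram:
    """Agglomeration result with a two-group cut."""

    linkage: np.ndarray          # scipy linkage matrix (merge pairs + heights)
    sample_ids: list[str]        # leaf labels in input (sorted) order
    leaf_order: list[str]        # labels in dendrogram display order
    two_group_labels: pd.Series  # sample_id -> cluster {1, 2}

    def to_newick(self) -> str:
        """Serialize with branch lengths derived from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});" \
            if not tree.is_leaf() else f"({self.sample_ids[tree.id]}:0);"


def cosine_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Condensed pairwise cosine distances; errors on zero-norm rows."""
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        raise ValueError("zero-norm sample vector: cosine distance undefined")
    return pdist(X, metric="cosine")


def hclust_cosine_complete(beta_sub: pd.DataFrame) -> Dendrogram:
    """Complete-linkage clustering of samples on cosine distance.

    ``beta_sub`` is samples x selected probes.  Samples are ordered
    lexicographically by id before agglomeration so that ties in the
    distance matrix break deterministically.
    """
    if beta_sub.shape[0] < 2:
        raise ValueError("need >= 2 samples to cluster")
    if beta_sub.isna().all(axis=1).any():
        raise ValueError("a sample is entirely missing")
    ordered = beta_sub.sort_index()
    X = ordered.to_numpy(dtype=float)
    d = cosine_distance_matrix(X)
    Z = hierarchy.linkage(d, method="complete")
    cut = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    leaves = hierarchy.leaves_list(Z)
    ids = list(ordered.index)
    return Dendrogram(
        linkage=Z,
        sample_ids=ids,
        leaf_order=[ids[i] for i in leaves],
        two_group_labels=pd.Series(cut, index=ids, name="cluster"),
    )


def kmeans_two_group(beta_sub: pd.DataFrame, k: int = 2, seed: int = 0,
                     medians: bool = False) -> pd.Series:
    """K-means (or K-medians) partition of samples, fixed seed."""
    X = beta_sub.to_numpy(dtype=float)
    if medians:
        # Lloyd iterations with medians and L1 assignment
        rng = np.random.default_rng(seed)
        centers = X[rng.choice(len(X), size=k, replace=False)]
        labels = np.zeros(len(X), dtype=int)
        for _ in range(100):
            dist = np.abs(X[:, None, :] - centers[None]).sum(axis=2)
            new = dist.argmin(axis=1)
            if (new == labels).all() and _ > 0:
                break
            labels = new
            for j in range(k):
                if (labels == j).any():
                    centers[j] = np.median(X[labels == j], axis=0)
        return pd.Series(labels + 1, index=beta_sub.index, name="cluster")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    return pd.Series(km.fit_predict(X) + 1, index=beta_sub.index, name="cluster")


@dataclass
class PcaResult:
    scores: pd.DataFrame             # samples x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame           # probes x components


def pca_median_knn(
    beta: pd.DataFrame,
    k: int = 10,
    n_components: int | None = None,
    neighbor_axis: str = "probes",
) -> PcaResult:
    """PCA after per-probe median centering and kNN imputation.

    ``beta`` is probes x samples.  Missing values are imputed from the
    ``k`` nearest probes (rows; Euclidean over shared samples) by their
    mean — ``neighbor_axis='samples'`` switches to sample-wise
    neighbours.  Component signs are fixed by making each component's
    largest-magnitude loading positive.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if beta.isna().all(axis=1).any():
        raise ValueError("a probe is missing in all samples")
    centered = beta.sub(beta.median(axis=1, skipna=True), axis=0)
    X = centered.to_numpy(dtype=float)
    if np.isnan(X).any():
        imputer = KNNImputer(n_neighbors=k)
        if neighbor_axis == "probes":
            X = imputer.fit_transform(X)        # rows are probes
        elif neighbor_axis == "samples":
            X = imputer.fit_transform(X.T).T
        else:
            raise ValueError(f"unknown neighbor_axis {neighbor_axis!r}")
    n_samples = X.shape[1]
    n_comp = n_components or min(n_samples, X.shape[0])
    pca = PCA(n_components=min(n_comp, n_samples, X.shape[0]))
    scores = pca.fit_transform(X.T)             # samples x comps
    loadings = pca.components_.T                # probes x comps
    # deterministic sign: largest |loading| positive per component
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(scores.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=beta.columns, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=pd.DataFrame(loadings, index=beta.index, columns=comp_names),
    )
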