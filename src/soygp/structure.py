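"""Population structure: PCA, Euclidean genetic distance, UPGMA, TP ranking.

Distances are plain Euclidean distances on the 0/1/2 dosage vectors — the
convention under which the germplasm panels separate into cultivated and
wild clusters — and the average-linkage (UPGMA) dendrogram and the
distance-ranked training-set construction both run on that matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .geno import GenotypeMatrix


@dataclass
class DistanceMatrix:
    """Symmetric Euclidean distance matrix with sample labels."""

    sample_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal not zero")

    def index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in ids], dtype=np.intp)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)


def _require_complete(g: GenotypeMatrix) -> np.ndarray:
    if np.isnan(g.dosage).any():
        raise ValueError("matrix contains missing values: impute first")
    return g.dosage


def pca(g: GenotypeMatrix, n_components: int = 10):
    """Principal components of the per-marker mean-centered dosage matrix.

    Centering only, no unit-variance scaling (the common convention for
    dosage PCA).  Returns (scores DataFrame indexed by sample id with
    columns PC1.., explained-variance fractions).
    """
    X = _require_complete(g)
    n_components = min(n_components, min(X.shape))
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)  # sklearn centers columns
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=g.sample_ids, columns=cols),
        model.explained_variance_ratio_.copy(),
    )


def pairwise_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Euclidean distances d(a,b) = sqrt(Σ_j (x_aj − x_bj)²) on dosages."""
    X = _require_complete(g)
    return DistanceMatrix(g.sample_ids, squareform(pdist(X, metric="euclidean")))


def group_distance(
    d: DistanceMatrix,
    panels: pd.Series,
    a: str,
    b: str,
    method: str = "mean",
) -> float:
    """Aggregate distance between two panels.

    "mean": mean of all between-group pairwise distances (default —
    symmetric and robust).  Panels must be non-empty and disjoint.
    """
    ia = d.index(panels.index[panels == a])
    ib = d.index(panels.index[panels == b])
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("empty group")
    if set(ia) & set(ib):
        raise ValueError("groups overlap")
    if method != "mean":
        raise ValueError(f"unknown method {method!r}")
    return float(d.values[np.ix_(ia, ib)].mean())


def group_distance_centroid(
    g: GenotypeMatrix, panels: pd.Series, a: str, b: str
) -> float:
    """Euclidean distance between panel mean-dosage vectors (centroid option)."""
    X = _require_complete(g)
    ia = g.sample_index(panels.index[panels == a])
    ib = g.sample_index(panels.index[panels == b])
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("empty group")
    return float(np.linalg.norm(X[ia].mean(0) - X[ib].mean(0)))


def upgma_cluster(d: DistanceMatrix):
    """Average-linkage agglomeration; returns (scipy linkage, newick string).

    Node heights are half the merge distance (the classic ultrametric
    convention), so leaf-to-root path lengths are equal; branch lengths in
    the newick output are differences of those heights, rooted at the final
    merge.
    """
    if len(d.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    if np.isnan(d.values).any():
        raise ValueError("NaN distances")
    Z = hierarchy.linkage(squareform(d.values, checks=False), method="average")
    tree = hierarchy.to_tree(Z)

    def newick(node, parent_height):
        height = node.dist / 2.0
        bl = parent_height - height
        if node.is_leaf():
            return f"{d.sample_ids[node.id]}:{bl:.6g}"
        left = newick(node.left, height)
        right = newick(node.right, height)
        return f"({left},{right}):{bl:.6g}"

    root_h = tree.dist / 2.0
    inner = f"({newick(tree.left, root_h)},{newick(tree.right, root_h)});"
    return Z, inner


def cut_clusters(d: DistanceMatrix, k: int) -> pd.Series:
    """Cut the UPGMA tree into k flat clusters (labels 1..k)."""
    Z, _ = upgma_cluster(d)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=d.sample_ids, name="cluster")


def rank_by_distance(d: DistanceMatrix, candidates, target) -> list:
    """Order candidates by mean distance to the target set, ascending.

    This is the distance-based training-set construction: the first s
    entries of the returned list form the size-s training set closest to
    the target (breeding) population.  Ties break by sample id.
    """
    candidates = list(candidates)
    target = list(target)
    if not target:
        raise ValueError("empty target set")
    if set(candidates) & set(target):
        raise ValueError("candidates and target must be disjoint")
    it = d.index(target)
    scores = {c: float(d.values[d.index([c])[0], it].mean()) for c in candidates}
    return sorted(candidates, key=lambda c: (scores[c], str(c)))
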