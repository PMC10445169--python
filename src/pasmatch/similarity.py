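"""Sample-to-sample molecular similarity from PAS profiles.

Similarity between two samples is the Pearson correlation of their PAS vectors
over a selected pathway panel.  Samples are clustered agglomeratively on the
distance 1 - PCC (sign-preserving, matching a blue/yellow correlation heatmap),
average linkage by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import UndefinedStatisticError, ValidationError
from .pas import PASMatrix

__all__ = ["SimilarityMatrix", "ClusterResult", "pearson", "similarity_matrix", "cluster_samples", "cut_clusters"]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric sample x sample Pearson-correlation matrix with unit diagonal."""

    pcc: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.pcc.index)


@dataclass(frozen=True)
class ClusterResult:
    """Agglomerative clustering of samples on distance 1 - PCC."""

    leaf_order: list[str]
    linkage: np.ndarray  # scipy linkage matrix (merge tree with heights)
    newick: str
    method: str


def pearson(u: Sequence[float], v: Sequence[float]) -> float:
    """Product-moment correlation of two equally long, non-constant vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValidationError("vectors must have equal length")
    if u.size < 3:
        raise ValidationError("correlation requires at least 3 observations")
    if np.ptp(u) == 0 or np.ptp(v) == 0:
        raise UndefinedStatisticError("Pearson correlation is undefined for a constant vector")
    r = float(np.corrcoef(u, v)[0, 1])
    return max(-1.0, min(1.0, r))


def similarity_matrix(pas: PASMatrix, pathways: Iterable[str] | None = None) -> SimilarityMatrix:
    """Pairwise sample PCC over the PAS vectors of the given pathway panel.

    Samples whose PAS vector is constant over the panel have no defined
    correlation; they are dropped with a warning.
    """
    scores = pas.scores
    if pathways is not None:
        pathways = list(pathways)
        missing = [p for p in pathways if p not in scores.index]
        if missing:
            raise ValidationError(f"pathways absent from PAS matrix: {missing}")
        scores = scores.loc[pathways]
    if scores.shape[0] < 3:
        raise ValidationError("similarity needs at least 3 selected pathways")
    if scores.shape[1] < 2:
        raise ValidationError("similarity needs at least 2 samples")

    constant = scores.columns[scores.std(axis=0, ddof=0) == 0].tolist()
    if constant:
        warnings.warn(f"excluding sample(s) with constant PAS vector: {constant}", stacklevel=2)
        scores = scores.drop(columns=constant)
        if scores.shape[1] < 2:
            raise ValidationError("fewer than 2 samples remain after dropping constant PAS vectors")

    mat = np.corrcoef(scores.to_numpy(dtype=float).T)
    np.fill_diagonal(mat, 1.0)
    mat = np.clip((mat + mat.T) / 2.0, -1.0, 1.0)
    return SimilarityMatrix(pcc=pd.DataFrame(mat, index=scores.columns, columns=scores.columns))


def _to_newick(node: hierarchy.ClusterNode, labels: list[str], parent_height: float) -> str:
    length = max(parent_height - node.dist, 0.0)
    if node.is_leaf():
        return f"{labels[node.id]}:{length:.6g}"
    left = _to_newick(node.get_left(), labels, node.dist)
    right = _to_newick(node.get_right(), labels, node.dist)
    return f"({left},{right}):{length:.6g}"


def cluster_samples(sim: SimilarityMatrix, method: str = "average") -> ClusterResult:
    """Hierarchical clustering of samples on 1 - PCC; returns leaf order and merge tree."""
    if method not in {"average", "complete", "single"}:
        raise ValidationError(f"unsupported linkage method {method!r}")
    n = len(sim.sample_ids)
    if n < 2:
        raise ValidationError("clustering needs at least 2 samples")
    dist = 1.0 - sim.pcc.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    if not np.isfinite(dist).all():
        raise ValidationError("non-finite distance in similarity matrix")
    condensed = squareform(np.maximum(dist, 0.0), checks=False)
    z = hierarchy.linkage(condensed, method=method)
    leaves = hierarchy.leaves_list(z)
    labels = sim.sample_ids
    tree = hierarchy.to_tree(z)
    root_str = _to_newick(tree, labels, tree.dist)
    newick = root_str.rsplit(":", 1)[0] + ";"  # root carries no branch length
    return ClusterResult(leaf_order=[labels[i] for i in leaves], linkage=z, newick=newick, method=method)


def cut_clusters(result: ClusterResult, sim: SimilarityMatrix, n_clusters: int) -> pd.Series:
    """Cut the merge tree into ``n_clusters`` flat clusters (sample -> cluster id)."""
    assignments = hierarchy.fcluster(result.linkage, t=n_clusters, criterion="maxclust")
    return pd.Series(assignments, index=sim.sample_ids, name="cluster")
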