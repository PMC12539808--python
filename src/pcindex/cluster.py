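"""Hierarchical clustering of species by their index component variables.

Species are grouped by the oriented, min-max scaled variables the index is
built from (the matrix after transform/scale/orient, before interaction),
using agglomerative clustering on pairwise distances — the same procedure
as R's hclust.  The within-cluster sum of squares (WSS) curve over cuts of
one dendrogram supports an elbow choice of k; cluster profiles summarise
which threats characterise each group and how the taxonomic classes
distribute over them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .variables import ValidationError

__all__ = ["ClusterAssignment", "hierarchical_cluster", "wss_curve",
           "cluster_profile", "suggest_elbow"]


@dataclass
class ClusterAssignment:
    """Species-to-cluster labels from one dendrogram cut.

    Cluster ids 1..k are canonical: clusters are ordered by their centroid,
    compared lexicographically over the variable columns (so the labelling
    does not depend on species order; exact centroid ties — measure zero
    for continuous data — fall back to cluster size, largest first).
    """

    labels: pd.Series
    k: int
    linkage_method: str
    distance_metric: str
    merge_tree: np.ndarray  # scipy linkage matrix

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def _linkage(X: pd.DataFrame, linkage: str, metric: str) -> np.ndarray:
    if linkage == "ward" and metric != "euclidean":
        raise ValidationError("ward linkage requires the euclidean metric")
    D = ssd.pdist(X.to_numpy(dtype=float), metric=metric)
    return sch.linkage(D, method=linkage)


def _canonical_labels(raw: np.ndarray, X: pd.DataFrame) -> pd.Series:
    """Relabel clusters 1..k by lexicographic centroid order."""
    arr = X.to_numpy(dtype=float)
    ids = np.unique(raw)
    keyed = []
    for cid in ids:
        mask = raw == cid
        centroid = tuple(np.round(arr[mask].mean(axis=0), 12))
        keyed.append((centroid, -int(mask.sum()), cid))
    keyed.sort()
    remap = {cid: rank + 1 for rank, (_, _, cid) in enumerate(keyed)}
    return pd.Series([remap[c] for c in raw], index=X.index, name="cluster")


def hierarchical_cluster(
    X: pd.DataFrame, k: int, linkage: str = "complete", metric: str = "euclidean"
) -> ClusterAssignment:
    """Agglomerative clustering cut to exactly k clusters.

    ``X`` is the species x variable matrix of oriented scaled values (use
    ``PCIResults.scaled_variables``).  Complete linkage on Euclidean
    distances by default; ward is available.  Deterministic: scipy's merge
    order plus canonical centroid-ordered relabelling.
    """
    n = X.shape[0]
    if k < 1 or k > n:
        raise ValidationError(f"k must be in 1..{n}, got {k}")
    if not np.isfinite(X.to_numpy(dtype=float)).all():
        raise ValidationError("clustering requires finite values")
    Z = _linkage(X, linkage, metric)
    raw = sch.fcluster(Z, t=k, criterion="maxclust")
    got = len(np.unique(raw))
    if got != k:
        raise ValidationError(
            f"dendrogram cut produced {got} clusters instead of {k} "
            "(tied merge heights); choose a different k"
        )
    return ClusterAssignment(
        labels=_canonical_labels(raw, X),
        k=k,
        linkage_method=linkage,
        distance_metric=metric,
        merge_tree=Z,
    )


def _wss(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for cid in np.unique(labels):
        pts = X[labels == cid]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def wss_curve(
    X: pd.DataFrame, k_max: int, linkage: str = "complete", metric: str = "euclidean"
) -> pd.DataFrame:
    """Within-cluster sum of squares for k = 1..k_max cuts of one dendrogram.

    WSS(k) is the sum over clusters of squared Euclidean distances to the
    cluster centroid; it is non-increasing in k along cuts of a single
    tree, and the elbow of the curve guides the choice of k.
    """
    n = X.shape[0]
    if k_max < 1 or k_max > n:
        raise ValidationError(f"k_max must be in 1..{n}")
    Z = _linkage(X, linkage, metric)
    arr = X.to_numpy(dtype=float)
    rows = []
    for k in range(1, k_max + 1):
        labels = sch.fcluster(Z, t=k, criterion="maxclust")
        rows.append({"k": k, "wss": _wss(arr, labels)})
    return pd.DataFrame(rows).set_index("k")


def suggest_elbow(wss: pd.DataFrame) -> int:
    """Advisory elbow: the k maximising distance to the chord from k=1 to k_max.

    A kneedle-style heuristic only — inspect the curve; the choice of k is
    the analyst's.
    """
    k = wss.index.to_numpy(dtype=float)
    w = wss["wss"].to_numpy(dtype=float)
    if len(k) < 3:
        return int(k[-1])
    # normalised chord distance
    k_n = (k - k[0]) / (k[-1] - k[0])
    rng = w[0] - w[-1]
    w_n = (w - w[-1]) / rng if rng > 0 else np.zeros_like(w)
    dist = np.abs(w_n - (1 - k_n))
    return int(k[np.argmax(dist)])


def cluster_profile(
    assignment: ClusterAssignment,
    X: pd.DataFrame,
    class_labels: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Summarise each cluster: variable distributions and class composition.

    Returns
    -------
    profiles : DataFrame
        Per (cluster, variable): mean, median, sd, n.
    contingency : DataFrame or None
        cluster x class species counts (margins preserved), if class
        labels were given.
    """
    labels = assignment.labels.reindex(X.index)
    if labels.isna().any():
        raise ValidationError("assignment does not cover all rows of X")
    rows = []
    for cid, idx in X.groupby(labels).groups.items():
        sub = X.loc[idx]
        for col in X.columns:
            v = sub[col]
            rows.append(
                {
                    "cluster": cid,
                    "variable": col,
                    "mean": float(v.mean()),
                    "median": float(v.median()),
                    "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan,
                    "n": len(v),
                }
            )
    profiles = pd.DataFrame(rows).set_index(["cluster", "variable"])
    contingency = None
    if class_labels is not None:
        cls = pd.Series(class_labels).reindex(X.index).astype(str)
        contingency = pd.crosstab(labels, cls)
        contingency.index.name = "cluster"
    return profiles, contingency
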