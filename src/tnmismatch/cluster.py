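"""Ward clustering of discretized residuals, model-order selection, labeling.

Participants are clustered on their {-1, 0, +1} residual codes with Ward's
minimum-variance agglomeration on Euclidean distances.  The number of
clusters is chosen two ways: the k maximizing mean silhouette width, and the
elbow of the within-cluster sum-of-squares curve, formalized as the k
maximizing the second difference WSS(k-1) - 2 WSS(k) + WSS(k+1).

Clusters are then named with the mismatch taxonomy using the *continuous*
residuals: the cluster with the smallest mean absolute residual is
``canonical``; others are ``resilient`` (mean residual > 0) or
``susceptible`` (< 0), qualified ``limbic`` or ``cortical`` by whichever
region class carries the larger mean residual magnitude.  When two cortical
clusters share a direction the larger-magnitude one is ``high``, the other
``low``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .mismatch import ResidualSet
from .rois import RoiMeta

__all__ = ["ClusterSolution", "ward_cluster", "select_k", "label_archetypes", "embed_pca"]


@dataclass
class ClusterSolution:
    """A cut of the Ward tree plus diagnostics and archetype names."""

    k: int
    labels: pd.Series  # participant -> 0-based cluster index
    linkage: np.ndarray  # scipy linkage matrix
    silhouette_by_k: dict = field(default_factory=dict)
    wss_by_k: dict = field(default_factory=dict)
    archetype_names: dict = field(default_factory=dict)  # cluster index -> name
    mean_residual_profiles: pd.DataFrame | None = None  # cluster x ROI

    @property
    def archetype_labels(self) -> pd.Series:
        """Per-participant archetype names (requires labeled clusters)."""
        if not self.archetype_names:
            raise ValueError("archetype names not assigned; run label_archetypes")
        return self.labels.map(self.archetype_names).rename("archetype")


def _as_matrix(discretized) -> tuple[np.ndarray, pd.Index]:
    if isinstance(discretized, pd.DataFrame):
        return discretized.to_numpy(dtype=float), discretized.index
    arr = np.asarray(discretized, dtype=float)
    return arr, pd.RangeIndex(arr.shape[0])


def ward_cluster(discretized, k: int) -> ClusterSolution:
    """Ward agglomeration of the discretized matrix, cut at ``k`` clusters.

    Cluster indices are 0-based and ordered by first occurrence in the input,
    so the partition is deterministic under a fixed row order and invariant
    (up to renaming) under row permutation.
    """
    X, index = _as_matrix(discretized)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n} rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("discretized matrix contains non-finite entries")
    Z = linkage(X, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = _relabel_first_occurrence(raw)
    return ClusterSolution(k=int(labels.max() + 1),
                           labels=pd.Series(labels, index=index, name="cluster"),
                           linkage=Z)


def _relabel_first_occurrence(raw: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.empty(raw.shape, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def _wss(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        total += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return total


def select_k(discretized, k_range: tuple[int, int] = (2, 10)):
    """Choose the number of clusters by silhouette and by the WSS elbow.

    Returns ``(k_silhouette, k_elbow, diagnostics)`` where diagnostics is a
    DataFrame with one row per k (silhouette, wss).  Ties go to the smallest
    k.  Refuses degenerate input (all rows identical).
    """
    X, _ = _as_matrix(discretized)
    n = X.shape[0]
    kmin, kmax = int(k_range[0]), int(k_range[1])
    if kmin < 2:
        raise ValueError("k_range must start at 2 or more (silhouette undefined at k=1)")
    if kmax > n - 1:
        raise ValueError(f"k_range upper bound {kmax} exceeds n-1={n - 1}")
    if np.all(X == X[0]):
        raise ValueError("all rows identical; cluster-number selection is undefined")
    Z = linkage(X, method="ward")
    # WSS needs flanking values for the second difference at the range edges
    ks_wss = range(max(kmin - 1, 1), min(kmax + 1, n) + 1)
    wss = {k: _wss(X, fcluster(Z, t=k, criterion="maxclust")) for k in ks_wss}
    sil = {}
    for k in range(kmin, kmax + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        if np.unique(labels).size < 2:
            sil[k] = np.nan
            continue
        sil[k] = float(silhouette_score(X, labels, metric="euclidean"))
    k_sil = min((k for k in sil if not np.isnan(sil[k])),
                key=lambda k: (-sil[k], k))
    elbow = {
        k: wss[k - 1] - 2.0 * wss[k] + wss[k + 1]
        for k in range(kmin, kmax + 1)
        if k - 1 in wss and k + 1 in wss
    }
    k_elbow = min(elbow, key=lambda k: (-elbow[k], k))
    diag = pd.DataFrame(
        {
            "k": list(range(kmin, kmax + 1)),
            "silhouette": [sil.get(k, np.nan) for k in range(kmin, kmax + 1)],
            "wss": [wss.get(k, np.nan) for k in range(kmin, kmax + 1)],
            "elbow_curvature": [elbow.get(k, np.nan) for k in range(kmin, kmax + 1)],
        }
    )
    return int(k_sil), int(k_elbow), diag


def label_archetypes(solution: ClusterSolution, rset: ResidualSet,
                     rois: list[RoiMeta]) -> ClusterSolution:
    """Assign mismatch archetype names to clusters from continuous residuals."""
    resid = rset.residuals
    labels = solution.labels
    classes = pd.Series({r.roi_id: r.region_class for r in rois}).reindex(resid.columns)
    profiles = resid.groupby(labels).mean()  # cluster x ROI
    profiles.index.name = "cluster"
    solution.mean_residual_profiles = profiles

    stats = []
    for c in profiles.index:
        prof = profiles.loc[c]
        stats.append(
            {
                "cluster": c,
                "mean_abs": float(prof.abs().mean()),
                "overall": float(prof.mean()),
                "limbic": float(prof[classes == "limbic"].mean()),
                "cortical": float(prof[classes == "cortical"].mean()),
            }
        )
    stats = pd.DataFrame(stats).set_index("cluster")

    names: dict[int, str] = {}
    canonical = int(stats["mean_abs"].idxmin())
    names[canonical] = "canonical"
    rest = stats.drop(index=canonical)
    base: dict[int, tuple[str, str, float]] = {}
    for c, row in rest.iterrows():
        direction = "resilient" if row["overall"] > 0 else "susceptible"
        locus = "limbic" if abs(row["limbic"]) > abs(row["cortical"]) else "cortical"
        magnitude = abs(row["limbic"]) if locus == "limbic" else abs(row["cortical"])
        base[int(c)] = (locus, direction, magnitude)
    groups: dict[tuple[str, str], list[int]] = {}
    for c, (locus, direction, _) in base.items():
        groups.setdefault((locus, direction), []).append(c)
    for (locus, direction), members in groups.items():
        if len(members) == 1:
            names[members[0]] = f"{locus}_{direction}"
        elif locus == "cortical" and len(members) == 2:
            hi, lo = sorted(members, key=lambda c: -base[c][2])
            names[hi] = f"high_cortical_{direction}"
            names[lo] = f"low_cortical_{direction}"
        else:
            ranked = sorted(members, key=lambda c: -base[c][2])
            for rank, c in enumerate(ranked, start=1):
                names[c] = f"{locus}_{direction}_{rank}"
    solution.archetype_names = names
    return solution


def embed_pca(discretized, n_components: int = 2) -> pd.DataFrame:
    """Principal-component scores of the (column-centered) discretized matrix.

    Component signs are fixed by making the largest-magnitude loading of each
    component positive, so the embedding is deterministic.
    """
    X, index = _as_matrix(discretized)
    if X.size == 0:
        raise ValueError("empty matrix")
    n_components = int(n_components)
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1
    return pd.DataFrame(scores, index=index,
                        columns=[f"PC{j + 1}" for j in range(n_components)])
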