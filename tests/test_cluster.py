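import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tnmismatch import (
    embed_pca,
    label_archetypes,
    select_k,
    ward_cluster,
)
from tnmismatch.mismatch import ResidualSet
from tnmismatch.rois import generate_roi_metadata


def greedy_minimum_variance_merges(X):
    """Independent oracle: exhaustive greedy Ward agglomeration.

    At each step every cluster pair's exact increase in total within-cluster
    sum of squares is evaluated and the minimum (ties: smallest indices) is
    merged.  Returns the list of partitions after each merge.
    """
    clusters = [[i] for i in range(len(X))]
    partitions = []
    while len(clusters) > 1:
        best = None
        for (i, a), (j, b) in itertools.combinations(enumerate(clusters), 2):
            ma, mb = X[a].mean(axis=0), X[b].mean(axis=0)
            cost = len(a) * len(b) / (len(a) + len(b)) * float(((ma - mb) ** 2).sum())
            if best is None or cost < best[0] - 1e-12:
                best = (cost, i, j)
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
        partitions.append(frozenset(frozenset(c) for c in clusters))
    return partitions


def scipy_partitions(X):
    from scipy.cluster.hierarchy import fcluster, linkage

    Z = linkage(X, method="ward")
    out = []
    for k in range(len(X) - 1, 0, -1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        groups = {}
        for idx, lab in enumerate(labels):
            groups.setdefault(lab, []).append(idx)
        out.append(frozenset(frozenset(g) for g in groups.values()))
    return out


@pytest.mark.parametrize("seed,n,p", [(0, 6, 3), (1, 7, 4), (2, 8, 5),
                                      (3, 8, 2), (4, 5, 6), (5, 8, 8)])
def test_ward_matches_exhaustive_greedy_agglomeration(seed, n, p):
    X = np.random.default_rng(seed).normal(size=(n, p))
    assert scipy_partitions(X) == greedy_minimum_variance_merges(X)


def test_two_separated_clouds_recovered_at_k2():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 0.1, (10, 4))
    b = rng.normal(8, 0.1, (10, 4))
    sol = ward_cluster(np.vstack([a, b]), k=2)
    labels = sol.labels.to_numpy()
    assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
    assert labels[0] != labels[10]


def test_identical_rows_merge_at_zero_height():
    X = np.ones((6, 3))
    sol = ward_cluster(X, k=3)
    assert np.allclose(sol.linkage[:, 2], 0.0)
    assert sol.labels.notna().all()


def test_partition_invariant_to_row_permutation():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(40, 6))
    perm = rng.permutation(40)
    ref = ward_cluster(X, k=4).labels.to_numpy()
    permuted = ward_cluster(X[perm], k=4).labels.to_numpy()
    unpermuted = np.empty(40, dtype=int)
    unpermuted[perm] = permuted
    assert adjusted_rand_score(ref, unpermuted) == 1.0


def test_k_out_of_range_rejected():
    X = np.random.default_rng(0).normal(size=(5, 2))
    with pytest.raises(ValueError, match="out of range"):
        ward_cluster(X, k=6)


def test_select_k_finds_two_separated_blobs():
    rng = np.random.default_rng(1)
    X = np.vstack([rng.normal(0, 1, (30, 5)), rng.normal(20, 1, (30, 5))])
    k_sil, k_elbow, diag = select_k(X, (2, 8))
    assert k_sil == 2 and k_elbow == 2
    assert set(diag["k"]) == set(range(2, 9))


def test_select_k_input_validation():
    X = np.random.default_rng(0).normal(size=(20, 3))
    with pytest.raises(ValueError, match="silhouette undefined"):
        select_k(X, (1, 5))
    with pytest.raises(ValueError, match="exceeds n-1"):
        select_k(X, (2, 30))
    with pytest.raises(ValueError, match="identical"):
        select_k(np.ones((20, 3)), (2, 5))


def _residual_set_with_cluster_means(mean_map, rois, n_per=10, seed=0):
    """Residual matrix with prescribed (limbic, cortical) means per cluster."""
    rng = np.random.default_rng(seed)
    roi_ids = [r.roi_id for r in rois]
    is_limbic = np.array([r.region_class == "limbic" for r in rois])
    is_cortical = np.array([r.region_class == "cortical" for r in rois])
    rows, labels = [], []
    for c, (limbic_mean, cortical_mean) in mean_map.items():
        base = np.zeros(len(rois))
        base[is_limbic] = limbic_mean
        base[is_cortical] = cortical_mean
        for _ in range(n_per):
            rows.append(base + rng.normal(0, 0.002, len(rois)))
            labels.append(c)
    resid = pd.DataFrame(rows, columns=roi_ids)
    from tnmismatch.cluster import ClusterSolution

    sol = ClusterSolution(k=len(mean_map),
                          labels=pd.Series(labels, index=resid.index),
                          linkage=np.empty((0, 4)))
    return ResidualSet(fits=[], residuals=resid), sol


def test_archetype_naming_follows_residual_geometry():
    rois = generate_roi_metadata()
    rset, sol = _residual_set_with_cluster_means(
        {
            0: (0.02, 0.01),    # near-zero -> canonical
            1: (0.15, 0.03),    # positive, limbic-dominant -> limbic resilient
            2: (-0.04, -0.12),  # negative, cortical-dominant -> cortical susceptible
            3: (0.03, 0.20),    # strong positive cortical -> high
            4: (0.02, 0.10),    # weaker positive cortical -> low
        },
        rois,
    )
    sol = label_archetypes(sol, rset, rois)
    assert sol.archetype_names[0] == "canonical"
    assert sol.archetype_names[1] == "limbic_resilient"
    assert sol.archetype_names[2] == "cortical_susceptible"
    assert sol.archetype_names[3] == "high_cortical_resilient"
    assert sol.archetype_names[4] == "low_cortical_resilient"
    assert list(sol.archetype_names.values()).count("canonical") == 1


def test_pca_embedding_is_centred_and_rank_aware():
    rng = np.random.default_rng(2)
    u = rng.normal(size=(30, 1))
    v = rng.normal(size=(1, 8))
    scores = embed_pca(u @ v, n_components=2)
    assert scores["PC2"].var() < 1e-20 * max(scores["PC1"].var(), 1.0) + 1e-12
    centered = embed_pca(rng.normal(size=(25, 6)), n_components=3)
    assert np.allclose(centered.mean(axis=0), 0, atol=1e-9)


def test_pca_separates_planted_archetypes(default_residuals, default_cohort):
    scores = embed_pca(default_residuals.discretized)
    labels = default_cohort["labels"]
    centroids = scores.groupby(labels.to_numpy()).mean()
    spread = scores.groupby(labels.to_numpy()).std().mean().mean()
    dists = [
        np.linalg.norm(centroids.iloc[i] - centroids.iloc[j])
        for i, j in itertools.combinations(range(len(centroids)), 2)
    ]
    assert np.mean(dists) > spread
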