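"""Consensus profile groups from repeated map retraining.

The trained map is carved into k groups by k-means on the node weights;
children inherit their BMU node's group.  Because the map and the k-means
solution both vary run to run (initialization jitter, clustering seeds),
the whole procedure is repeated many times (default 1,000), cluster labels
are aligned to the first run's centroids by optimal assignment, and each
child receives the modal cluster across repetitions together with a
consistency score (modal share) and a per-child chi-square test of whether
the assignment counts depart from uniform (a "clear" modal cluster).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .cohort import CohortMatrix
from .som import SOMConfig, TrainedSOM, train_som


def cluster_nodes(
    weights: np.ndarray, k: int, seed: int = 0, n_restarts: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """k-means on node weights: k-means++ seeding, best of ``n_restarts``.

    Returns (node_labels, centroids).
    """
    weights = np.asarray(weights, dtype=float)
    if k < 1 or k > weights.shape[0]:
        raise ValueError(f"k={k} out of range for {weights.shape[0]} nodes")
    n_distinct = np.unique(weights, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(
            f"k={k} exceeds the {n_distinct} distinct weight vectors")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                random_state=seed % (2**32))
    labels = km.fit_predict(weights)
    return labels, km.cluster_centers_


def assign_children(node_labels: np.ndarray, bmu: np.ndarray) -> np.ndarray:
    """Each child's cluster is its BMU node's cluster."""
    return np.asarray(node_labels)[np.asarray(bmu)]


def align_labels(reference_centroids: np.ndarray,
                 centroids: np.ndarray) -> np.ndarray:
    """Permutation mapping each new cluster to a reference cluster.

    Minimizes the total Euclidean distance between matched centroid pairs
    (optimal assignment); ``perm[j]`` is the reference label for new
    cluster j.
    """
    ref = np.asarray(reference_centroids, float)
    cen = np.asarray(centroids, float)
    if ref.shape != cen.shape:
        raise ValueError(
            f"centroid shapes differ: {ref.shape} vs {cen.shape}")
    cost = cdist(ref, cen)
    row, col = linear_sum_assignment(cost)
    perm = np.empty(len(ref), dtype=int)
    perm[col] = row
    return perm


def modal_clarity_test(counts_row: np.ndarray, k: int | None = None
                       ) -> tuple[float, float]:
    """Pearson goodness-of-fit of a child's assignment counts vs uniform.

    Expectation n_iterations / k on k - 1 degrees of freedom; a small p
    means the child has a clear modal cluster rather than sitting on a
    boundary.
    """
    counts = np.asarray(counts_row, dtype=float)
    if k is None:
        k = len(counts)
    n = counts.sum()
    expected = n / k
    stat = float(((counts - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(stat, df=k - 1))
    return stat, p


@dataclass
class ConsensusResult:
    k: int
    n_iterations: int
    assignment_counts: np.ndarray          # child x cluster
    modal_cluster: np.ndarray              # per child, 0-based
    consistency: np.ndarray                # per child, modal share
    clarity_stat: np.ndarray
    clarity_p: np.ndarray
    reference_centroids: np.ndarray        # cluster x measure (node-weight space)
    reference_som: TrainedSOM | None = None
    child_ids: list = field(default_factory=list)

    def per_child_table(self) -> pd.DataFrame:
        idx = pd.Index(self.child_ids or range(len(self.modal_cluster)),
                       name="child_id")
        return pd.DataFrame(
            {"modal_cluster": self.modal_cluster + 1,
             "consistency": self.consistency,
             "clarity_stat": self.clarity_stat,
             "clarity_p": self.clarity_p},
            index=idx)


def consensus(
    data: CohortMatrix | np.ndarray,
    som_config: SOMConfig | None = None,
    k: int = 4,
    n_iterations: int = 1000,
    seed: int = 0,
    kmeans_seed: int | None = None,
) -> ConsensusResult:
    """Repeat train-cluster-assign ``n_iterations`` times and aggregate.

    Iteration 1 defines the reference centroids; each later iteration
    retrains the map with fresh jitter and clustering seeds derived from
    the master seed, reclusters the nodes, aligns its cluster labels to
    the reference by optimal centroid matching, and increments each
    child's assignment count.  Passing ``kmeans_seed`` freezes the
    clustering seed across iterations (with zero init jitter this makes
    every iteration identical).
    """
    if som_config is None:
        som_config = SOMConfig(init_jitter_sd=0.05)
    rng = np.random.default_rng(seed)
    n_children = (len(data.child_ids) if isinstance(data, CohortMatrix)
                  else np.asarray(data).shape[0])
    counts = np.zeros((n_children, k), dtype=int)
    reference_centroids = None
    reference_som = None
    for it in range(n_iterations):
        som_seed = int(rng.integers(0, 2**31 - 1))
        km_seed = (int(rng.integers(0, 2**31 - 1))
                   if kmeans_seed is None else kmeans_seed)
        som = train_som(data, replace(som_config, seed=som_seed))
        node_labels, centroids = cluster_nodes(som.weights, k, seed=km_seed)
        if reference_centroids is None:
            reference_centroids = centroids
            reference_som = som
            aligned = node_labels
        else:
            perm = align_labels(reference_centroids, centroids)
            aligned = perm[node_labels]
        child_labels = assign_children(aligned, som.bmu)
        counts[np.arange(n_children), child_labels] += 1

    modal = counts.argmax(axis=1)
    consistency = counts.max(axis=1) / n_iterations
    clar = np.array([modal_clarity_test(row, k) for row in counts])
    return ConsensusResult(
        k=k, n_iterations=n_iterations, assignment_counts=counts,
        modal_cluster=modal, consistency=consistency,
        clarity_stat=clar[:, 0], clarity_p=clar[:, 1],
        reference_centroids=reference_centroids,
        reference_som=reference_som,
        child_ids=(data.child_ids if isinstance(data, CohortMatrix) else []),
    )


def cluster_profile_table(
    data: CohortMatrix,
    modal_cluster: np.ndarray,
    labels: pd.DataFrame | None = None,
    k: int | None = None,
) -> pd.DataFrame:
    """Per-cluster n, gender counts, and mean/sd of every measure (z units).

    Empty clusters appear with n = 0 and undefined (NaN) means.
    """
    modal = np.asarray(modal_cluster)
    if k is None:
        k = int(modal.max()) + 1
    rows = {}
    X = data.scores
    for c in range(k):
        sel = modal == c
        row = {"n": int(sel.sum())}
        if labels is not None and "gender" in labels:
            g = labels.loc[sel, "gender"]
            row["male"] = int((g == "male").sum())
            row["female"] = int((g == "female").sum())
        for m in data.measures:
            vals = X.loc[sel, m]
            row[f"{m}_mean"] = float(vals.mean()) if sel.any() else np.nan
            row[f"{m}_sd"] = float(vals.std(ddof=1)) if sel.sum() > 1 else np.nan
        rows[c + 1] = row
    out = pd.DataFrame(rows).T
    out.index.name = "cluster"
    return out
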