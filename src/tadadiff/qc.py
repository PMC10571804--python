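"""Replicate quality control and gene clustering.

Samples are compared by pairwise correlation of their occupancy tracks and
grouped by average-linkage hierarchical clustering on distance ``1 - r``;
replicates of the same (condition) group should cluster together. Genes are
partitioned into k groups (default 3) by k-means on their per-condition mean
occupancy, for downstream enrichment lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .occupancy import DegenerateSampleError
from .simulate import CONDITIONS


class ConfigError(ValueError):
    pass


@dataclass
class SampleClustering:
    correlation: pd.DataFrame   # pairwise Pearson (or Spearman) r
    linkage: np.ndarray         # scipy linkage matrix, average on 1 - r
    leaf_order: list            # deterministic dendrogram leaf labels
    labels: pd.Series           # flat grouping at n_groups clusters


def sample_correlation_cluster(tracks: pd.DataFrame, method: str = "pearson",
                               n_groups: int = 2) -> SampleClustering:
    """Correlate occupancy tracks pairwise and cluster samples.

    ``method`` is "pearson" (default; log-ratio occupancy is already
    variance-stabilized) or "spearman". Distance is ``1 - r`` with
    average linkage; leaf order is scipy's deterministic ordering.
    """
    if tracks.shape[1] < 2:
        raise ConfigError("need at least two samples to cluster")
    sd = tracks.std(axis=0)
    flat = sd[sd < 1e-12]
    if len(flat):
        raise DegenerateSampleError(
            f"constant occupancy track(s): {', '.join(flat.index)}"
        )
    corr = tracks.corr(method=method)
    dist = squareform(np.clip(1.0 - corr.to_numpy(), 0.0, None), checks=False)
    Z = linkage(dist, method="average")
    order = [tracks.columns[i] for i in leaves_list(Z)]
    labels = pd.Series(fcluster(Z, t=n_groups, criterion="maxclust"),
                       index=tracks.columns, name="cluster")
    return SampleClustering(corr, Z, order, labels)


def gene_kmeans(gene_table: pd.DataFrame, k: int = 3, seed: int = 0,
                n_init: int = 50) -> pd.Series:
    """k-means on per-condition mean occupancy, canonically relabeled.

    Uses k-means++ with ``n_init`` restarts under a fixed seed. Cluster ids
    are relabeled 0..k-1 by *descending* cluster mean occupancy so that
    labels are stable across runs and platforms. Genes with incomplete
    occupancy vectors are dropped from the clustering.
    """
    feat_cols = [f"mean_{c}" for c in CONDITIONS if f"mean_{c}" in gene_table.columns]
    if not feat_cols:
        raise ConfigError("gene table lacks per-condition mean_* columns")
    X = gene_table[feat_cols].dropna()
    if k < 1 or k > len(X):
        raise ConfigError(f"k={k} invalid for {len(X)} complete genes")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                random_state=seed % (2**31)).fit(X.to_numpy())
    # canonical order: cluster 0 = highest mean occupancy
    order = np.argsort(-km.cluster_centers_.mean(axis=1), kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return pd.Series(remap[km.labels_], index=X.index, name="cluster")
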