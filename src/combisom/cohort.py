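"""Sample-space similarity analysis on metagene portraits.

Pairwise Pearson correlation between flattened per-sample portraits of
one modality yields a heatmap-ready matrix; a top-k correlation graph
with a seeded force-directed layout gives the similarity network; and
hierarchical clustering of the portraits, cut at the number of
annotated groups, is compared against the annotation with the adjusted
Rand index.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

logger = logging.getLogger(__name__)

__all__ = [
    "portrait_correlation_matrix",
    "similarity_network",
    "group_agreement",
]


def portrait_correlation_matrix(
    decomposed_modality: np.ndarray, sample_ids: Sequence[str]
) -> pd.DataFrame:
    """Pearson correlation between all pairs of sample portraits.

    A zero-variance portrait yields a NaN row/column with a warning;
    the diagonal is exactly 1 for valid samples.
    """
    mat = np.asarray(decomposed_modality, dtype=float)
    if mat.shape[1] < 2:
        raise ValueError("need at least two samples")
    sds = mat.std(axis=0)
    degenerate = sds == 0
    if degenerate.any():
        logger.warning(
            "%d zero-variance portrait(s): %s",
            int(degenerate.sum()),
            ", ".join(np.asarray(sample_ids)[degenerate][:10]),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat, rowvar=False)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    np.fill_diagonal(corr, np.where(degenerate, np.nan, 1.0))
    corr = (corr + corr.T) / 2.0  # enforce exact symmetry
    return pd.DataFrame(corr, index=list(sample_ids), columns=list(sample_ids))


def similarity_network(
    corr: pd.DataFrame, k: int = 3, seed: int = 0
) -> tuple[nx.Graph, dict[str, np.ndarray]]:
    """Top-k correlation graph plus a seeded spring layout.

    Each sample is connected to its k most-correlated neighbours (ties
    broken by sample order); edges are undirected, so a node can end up
    with more than k incident edges.
    """
    n = corr.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the sample count {n}")
    samples = list(corr.index)
    g = nx.Graph()
    g.add_nodes_from(samples)
    c = corr.to_numpy(copy=True)
    np.fill_diagonal(c, -np.inf)
    c = np.where(np.isnan(c), -np.inf, c)
    for i, s in enumerate(samples):
        # stable: sort by (-corr, neighbour order)
        order = sorted(range(n), key=lambda j: (-c[i, j], j))
        for j in order[:k]:
            if np.isfinite(c[i, j]):
                g.add_edge(s, samples[j], weight=float(c[i, j]))
    pos = nx.spring_layout(g, seed=seed)
    return g, pos


def group_agreement(
    corr: pd.DataFrame, groups: Mapping[str, Sequence[str]]
) -> tuple[pd.DataFrame, float]:
    """Agreement between portrait clusters and annotated groups.

    Average-linkage hierarchical clustering on correlation distance
    (1 - r), cut at the number of annotated groups, compared with the
    annotation by the adjusted Rand index (1 = identical partitions,
    ~0 = random).  Returns (contingency table, ARI).
    """
    label_of = {s: g for g, members in groups.items() for s in members}
    samples = [s for s in corr.index if s in label_of]
    if len(samples) < 2:
        raise ValueError("need at least two annotated samples")
    sub = corr.loc[samples, samples].to_numpy()
    if np.isnan(sub).any():
        raise ValueError("correlation matrix contains NaN for annotated samples")
    dist = 1.0 - sub
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    n_groups = len({label_of[s] for s in samples})
    clusters = hierarchy.fcluster(z, t=n_groups, criterion="maxclust")
    truth = [label_of[s] for s in samples]
    ari = float(adjusted_rand_score(truth, clusters))
    table = pd.crosstab(
        pd.Series(truth, index=samples, name="group"),
        pd.Series(clusters, index=samples, name="cluster"),
    )
    return table, ari
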