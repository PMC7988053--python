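"""Sample clustering and heatmap probe ranking."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .types import BetaMatrix


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix over samples
    labels: pd.Series  # flat cluster label per sample, k = number of groups
    sample_ids: list[str]

    def leaves(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.sample_ids[i] for i in order]


def cluster_samples(
    matrix: BetaMatrix,
    probe_subset=None,
    n_clusters: int | None = None,
) -> ClusterResult:
    """Ward-linkage agglomerative clustering of samples on beta values.

    Euclidean distances over the chosen probes (all probes by default);
    flat labels are cut at ``n_clusters`` (default: the number of sample
    groups in the sheet).
    """
    values = matrix.values
    if probe_subset is not None:
        subset = values.index.intersection(pd.Index(list(probe_subset)))
        if len(subset) == 0:
            raise ValueError("probe_subset shares no probes with the matrix")
        values = values.loc[subset]
    if values.shape[1] < 2:
        raise ValueError("clustering needs at least 2 samples")
    X = values.to_numpy(dtype=float).T
    Z = hierarchy.linkage(X, method="ward")
    k = n_clusters or matrix.samples["group"].nunique()
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(flat, index=list(values.columns), name="cluster")
    return ClusterResult(Z, labels, list(values.columns))


def top_dmp_heatmap_order(dmp_sets: list[pd.DataFrame], n: int = 1000) -> list[str]:
    """Top probes across comparisons for heatmap display.

    Ranked by minimum q across comparisons, ties broken by maximum
    |delta beta| and then lexicographically by probe id, so the order is
    deterministic.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    pool = pd.concat(dmp_sets, ignore_index=True)
    if pool.empty:
        raise ValueError("no DMPs in any input set")
    ranked = (
        pool.assign(abs_delta=pool["delta_beta"].abs())
        .groupby("probe_id")
        .agg(min_q=("q", "min"), max_abs_delta=("abs_delta", "max"))
        .sort_values(
            ["min_q", "max_abs_delta", "probe_id"],
            ascending=[True, False, True],
            kind="mergesort",
        )
    )
    return list(ranked.index[:n])
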