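"""Mean between-community connectivity per subject.

At K=5 the 10 unordered community pairs form the subnetwork test family;
within-community means are computed alongside but flagged separately and
excluded from the default family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ocsnet.community import Partition
from ocsnet.connectome import ConnectivityMatrix

__all__ = ["SubnetworkConnectivity", "between_subnetwork_means", "subnetwork_table"]


@dataclass(frozen=True)
class SubnetworkConnectivity:
    """Unordered community-pair -> mean edge weight; plus within-community means."""

    pair_means: dict[tuple[int, int], float]
    within_means: dict[int, float]
    K: int

    def __post_init__(self) -> None:
        if len(self.pair_means) != self.K * (self.K - 1) // 2:
            raise ValueError("expected K(K-1)/2 between-community pairs")


def between_subnetwork_means(
    w: ConnectivityMatrix, p: Partition
) -> SubnetworkConnectivity:
    """Mean of w_ij over i in community a, j in community b, per unordered pair.

    Each undirected edge is counted once. Within-community means (each
    undirected edge within block a counted once, diagonal excluded) are
    returned alongside.
    """
    memb = p.reordered(list(w.node_labels)).membership if p.node_labels != w.node_labels else p.membership
    K = int(memb.max()) + 1
    if K < 2:
        raise ValueError("between-subnetwork means need at least 2 communities")
    onehot = np.eye(K)[memb]
    block_sum = onehot.T @ w.w @ onehot
    sizes = onehot.sum(axis=0)
    pair_means: dict[tuple[int, int], float] = {}
    within_means: dict[int, float] = {}
    for a in range(K):
        n_within_edges = sizes[a] * (sizes[a] - 1) / 2
        within_means[a] = float(block_sum[a, a] / 2 / n_within_edges) if n_within_edges else 0.0
        for b in range(a + 1, K):
            pair_means[(a, b)] = float(block_sum[a, b] / (sizes[a] * sizes[b]))
    return SubnetworkConnectivity(pair_means, within_means, K)


def subnetwork_table(
    per_subject: dict[str, SubnetworkConnectivity], include_within: bool = True
) -> pd.DataFrame:
    """Long table: subject_id, community_a, community_b, mean_connectivity, within."""
    rows = []
    for sid, sc in per_subject.items():
        for (a, b), v in sorted(sc.pair_means.items()):
            rows.append((sid, a, b, v, False))
        if include_within:
            for a, v in sorted(sc.within_means.items()):
                rows.append((sid, a, a, v, True))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "community_a", "community_b", "mean_connectivity", "within"],
    )
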