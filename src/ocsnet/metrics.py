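"""Weighted graph measures at global, subnetwork and nodal scale.

Definitions follow the standard weighted-network conventions (Rubinov &
Sporns): modularity Q with a resolution parameter, participation
coefficient, within-module degree Z-score with population SD, Onnela
weighted clustering, inverse-weight shortest-path length / global
efficiency, and small-worldness sigma against weight-shuffled nulls.
The thalamic summary applies the study's bilateral-averaging rule: a
left/right node pair assigned to the same community contributes its mean,
a split pair contributes both sides separately (8 pairs with one split
pair yields nine node values).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from ocsnet.community import Partition
from ocsnet.connectome import ConnectivityMatrix

__all__ = [
    "GlobalMetrics",
    "ThalamicNodeSet",
    "modularity",
    "participation_coefficients",
    "within_module_z",
    "weighted_clustering",
    "path_length_efficiency",
    "small_worldness",
    "thalamic_summary",
    "global_metrics",
    "all_partitions",
    "exact_max_modularity",
    "weight_shuffle_null",
]


@dataclass(frozen=True)
class GlobalMetrics:
    """Whole-brain summary of one subject's weighted connectome."""

    avg_pc: float
    Q: float
    sigma: float
    C: float
    L: float
    E_glob: float


@dataclass(frozen=True)
class ThalamicNodeSet:
    """Eight bilateral thalamic-subregion node pairs (label_left, label_right)."""

    pairs: tuple[tuple[str, str, str], ...]  # (subregion, left_label, right_label)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(tuple(p) for p in self.pairs))
        if len(self.pairs) != 8:
            raise ValueError("expected exactly 8 bilateral thalamic pairs")


def _membership_for(w: ConnectivityMatrix, p: Partition) -> np.ndarray:
    if p.node_labels == w.node_labels:
        return p.membership
    return p.reordered(list(w.node_labels)).membership


def modularity(w: ConnectivityMatrix, p: Partition, gamma: float = 1.0) -> float:
    """Newman modularity of partition ``p`` at resolution ``gamma``.

    Q = (1/2W) sum_ij [w_ij - gamma * s_i s_j / 2W] delta(m_i, m_j),
    with 2W the total weight over ordered node pairs.
    """
    memb = _membership_for(w, p)
    W = w.w
    two_w = W.sum()
    if two_w == 0:
        raise ValueError("modularity undefined for an empty (all-zero) graph")
    s = W.sum(axis=1)
    k = memb.max() + 1
    onehot = np.eye(k)[memb]  # N x K
    within = np.trace(onehot.T @ W @ onehot)
    strength_m = s @ onehot  # total strength per module
    return float(within / two_w - gamma * np.sum((strength_m / two_w) ** 2))


def participation_coefficients(w: ConnectivityMatrix, p: Partition) -> np.ndarray:
    """pc_i = 1 - sum_m (kappa_im / s_i)^2; zero-strength nodes get pc=0."""
    memb = _membership_for(w, p)
    onehot = np.eye(memb.max() + 1)[memb]
    kappa = w.w @ onehot  # N x K strength into each module
    s = kappa.sum(axis=1)
    pc = np.zeros(w.n_nodes)
    pos = s > 0
    pc[pos] = 1.0 - np.sum((kappa[pos] / s[pos, None]) ** 2, axis=1)
    return pc


def within_module_z(w: ConnectivityMatrix, p: Partition) -> np.ndarray:
    """Within-module degree Z-score with population (N-denominator) SD.

    Degenerate modules (singletons, or zero SD of within-module strength)
    yield z = 0 for their members.
    """
    memb = _membership_for(w, p)
    n = w.n_nodes
    z = np.zeros(n)
    kappa_own = np.array(
        [w.w[i, memb == memb[i]].sum() for i in range(n)]
    )
    for m in range(memb.max() + 1):
        idx = np.flatnonzero(memb == m)
        if idx.size < 2:
            continue
        vals = kappa_own[idx]
        sd = vals.std()  # ddof=0
        if sd < 1e-12:
            continue
        z[idx] = (vals - vals.mean()) / sd
    return z


def weighted_clustering(w: ConnectivityMatrix) -> float:
    """Mean Onnela weighted clustering coefficient.

    Weights are normalized by the maximum weight; a node's coefficient is
    the sum of geometric-mean triangle intensities over k_i(k_i-1), where
    k_i counts nonzero-weight neighbors. Nodes with k_i < 2 contribute 0.
    """
    if w.n_nodes < 3:
        raise ValueError("clustering needs at least 3 nodes")
    W = w.w
    wmax = W.max()
    if wmax == 0:
        return 0.0
    m = np.cbrt(W / wmax)
    triangles = np.diagonal(m @ m @ m)  # 2 * sum of cube-root triangle products
    k = np.count_nonzero(W, axis=1)
    c = np.zeros(w.n_nodes)
    ok = k >= 2
    c[ok] = triangles[ok] / (k[ok] * (k[ok] - 1))
    return float(c.mean())


def path_length_efficiency(w: ConnectivityMatrix) -> tuple[float, float]:
    """Characteristic path length and global efficiency on lengths 1/w.

    Dijkstra all-pairs shortest paths; L is the mean finite off-diagonal
    distance, E_glob the mean of 1/d over distinct pairs (unreachable pairs
    contribute 0 efficiency).
    """
    W = w.w
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), 0.0)
    d = shortest_path(csr_matrix(lengths), method="D", directed=False)
    off = ~np.eye(w.n_nodes, dtype=bool)
    finite = np.isfinite(d) & off
    L = float(d[finite].mean()) if finite.any() else np.inf
    inv = np.zeros_like(d)
    inv[finite] = 1.0 / d[finite]
    E = float(inv[off].mean()) if off.any() else 0.0
    return L, E


def weight_shuffle_null(w: ConnectivityMatrix, rng: np.random.Generator) -> ConnectivityMatrix:
    """Null network preserving the off-diagonal weight multiset.

    Upper-triangle weights are permuted uniformly and mirrored, keeping
    symmetry and the zero diagonal (and hence total weight and density).
    """
    n = w.n_nodes
    iu = np.triu_indices(n, k=1)
    vals = rng.permutation(w.w[iu])
    out = np.zeros_like(w.w)
    out[iu] = vals
    out += out.T
    return ConnectivityMatrix(out, w.node_labels)


def small_worldness(
    w: ConnectivityMatrix,
    n_rand: int = 10,
    null: Callable[[ConnectivityMatrix, np.random.Generator], ConnectivityMatrix] = weight_shuffle_null,
    seed: int = 0,
) -> float:
    """sigma = (C / C_rand) / (L / L_rand), nulls averaged over ``n_rand``."""
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    C = weighted_clustering(w)
    L, _ = path_length_efficiency(w)
    rng = np.random.default_rng(seed)
    c_rand = np.empty(n_rand)
    l_rand = np.empty(n_rand)
    for i in range(n_rand):
        g = null(w, rng)
        c_rand[i] = weighted_clustering(g)
        l_rand[i], _ = path_length_efficiency(g)
    if c_rand.mean() == 0 or l_rand.mean() == 0:
        raise ValueError("degenerate null networks (zero clustering or path length)")
    return float((C / c_rand.mean()) / (L / l_rand.mean()))


def global_metrics(
    w: ConnectivityMatrix,
    p: Partition,
    gamma: float = 1.05,
    n_rand: int = 10,
    seed: int = 0,
) -> GlobalMetrics:
    """All global measures of one subject against a (consensus) partition."""
    pc = participation_coefficients(w, p)
    L, E = path_length_efficiency(w)
    return GlobalMetrics(
        avg_pc=float(pc.mean()),
        Q=modularity(w, p, gamma=gamma),
        sigma=small_worldness(w, n_rand=n_rand, seed=seed),
        C=weighted_clustering(w),
        L=L,
        E_glob=E,
    )


def thalamic_summary(
    node_values: dict[str, float],
    node_set: ThalamicNodeSet,
    p: Partition,
) -> dict[str, float]:
    """Bilateral averaging of a nodal metric over the thalamic pairs.

    Pairs whose left and right nodes share a community contribute one value
    (the mean, keyed by subregion); split pairs contribute both sides
    separately (keyed subregion_L / subregion_R). With 7 same-community
    pairs and 1 split pair this yields the study's nine node values.
    """
    out: dict[str, float] = {}
    for subregion, left, right in node_set.pairs:
        for lab in (left, right):
            if lab not in node_values:
                raise KeyError(f"thalamic node {lab} missing from node metrics")
            if lab not in p.node_labels:
                raise KeyError(f"thalamic node {lab} missing from partition")
        if p.community_of(left) == p.community_of(right):
            out[subregion] = (node_values[left] + node_values[right]) / 2.0
        else:
            out[f"{subregion}_L"] = node_values[left]
            out[f"{subregion}_R"] = node_values[right]
    return out


def all_partitions(items: Sequence[int]) -> Iterator[np.ndarray]:
    """Every set partition of ``items`` as canonical membership arrays.

    Enumerates restricted-growth strings; for n=8 there are 4140 partitions
    (the Bell number B_8). Intended for exact modularity maximization on
    tiny graphs.
    """
    n = len(items)
    a = np.zeros(n, dtype=int)
    while True:
        yield a.copy()
        # increment restricted growth string
        for i in range(n - 1, 0, -1):
            if a[i] <= a[:i].max():
                a[i] += 1
                a[i + 1 :] = 0
                break
        else:
            return


def exact_max_modularity(
    w: ConnectivityMatrix, gamma: float = 1.0
) -> tuple[float, Partition]:
    """Exhaustive maximum of Q over all set partitions (tiny graphs only)."""
    if w.n_nodes > 12:
        raise ValueError("exhaustive search is limited to <= 12 nodes")
    best_q = -np.inf
    best = None
    for memb in all_partitions(range(w.n_nodes)):
        p = Partition(w.node_labels, memb)
        q = modularity(w, p, gamma=gamma)
        if q > best_q:
            best_q, best = q, p
    return float(best_q), best
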