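"""Group-level inference on directed connectivity matrices.

The network-based statistic (NBS) thresholds edge-wise two-sample
t-statistics, finds connected components among the suprathreshold edges
(positive and negative contrasts separately), and assigns each component a
family-wise p-value from the permutation null distribution of the maximal
component size.  Node strength comparisons test in-strength (column sums)
and out-strength (row sums) per node with the same permutation machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc

from .entropy import adjust_pvalues, hedges_g, permutation_diff_means

__all__ = [
    "NBSResult",
    "edge_tstats",
    "network_based_statistic",
    "strength_comparison",
]


@dataclass
class NBSComponent:
    """One suprathreshold connected component (a set of directed edges)."""

    edges: list[tuple[int, int]]
    sign: int           # +1: group1 > group2, -1: converse
    size: int           # edge count
    p_value: float
    nodes: list[int] = field(default_factory=list)


@dataclass
class NBSResult:
    threshold: float
    components: list[NBSComponent]
    n_permutations: int
    seed: int
    t_matrix: np.ndarray

    @property
    def significant(self) -> list[NBSComponent]:
        return [c for c in self.components if c.p_value < 0.05]


def _stack(group: Sequence[np.ndarray]) -> np.ndarray:
    arr = np.asarray(group, dtype=float)
    if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
        raise ValueError("each group must be a sequence of square matrices")
    return arr


def edge_tstats(
    group1: Sequence[np.ndarray], group2: Sequence[np.ndarray]
) -> np.ndarray:
    """Pooled-variance two-sample t per directed off-diagonal edge.

    Positive values mean the edge is stronger in the first group.  Edges
    with zero variance in both groups get t = 0 (with a warning).
    """
    a, b = _stack(group1), _stack(group2)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("groups have different matrix shapes")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 matrices per group")
    t = _edge_tstats_arrays(a, b, warn=True)
    np.fill_diagonal(t, 0.0)
    return t


def _edge_tstats_arrays(a: np.ndarray, b: np.ndarray, warn: bool = False) -> np.ndarray:
    na, nb = a.shape[0], b.shape[0]
    mean_diff = a.mean(axis=0) - b.mean(axis=0)
    s2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / (
        na + nb - 2
    )
    se = np.sqrt(s2 * (1.0 / na + 1.0 / nb))
    zero = se == 0
    if warn and np.any(zero & (mean_diff == 0)):
        warnings.warn(
            "edges with zero variance in both groups; t set to 0",
            RuntimeWarning,
            stacklevel=3,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, mean_diff / np.where(zero, 1.0, se))
    return t


def _components_from_mask(mask: np.ndarray) -> list[tuple[list[tuple[int, int]], list[int]]]:
    """Connected components of the undirected graph spanned by masked edges.

    An edge in either direction links its endpoints; the returned edge
    lists keep the original directed edges.
    """
    n = mask.shape[0]
    und = mask | mask.T
    if not und.any():
        return []
    n_comp, labels = _cc(csr_matrix(und), directed=False)
    out = []
    src, dst = np.nonzero(mask)
    for c in range(n_comp):
        members = np.nonzero(labels == c)[0]
        if members.size < 2:
            continue
        member_set = set(members.tolist())
        edges = [
            (int(i), int(j))
            for i, j in zip(src, dst)
            if int(i) in member_set and int(j) in member_set
        ]
        if edges:
            out.append((edges, members.tolist()))
    return out


def _max_component_size(mask: np.ndarray) -> int:
    comps = _components_from_mask(mask)
    return max((len(e) for e, _ in comps), default=0)


def network_based_statistic(
    group1: Sequence[np.ndarray],
    group2: Sequence[np.ndarray],
    t_threshold: float = 4.5,
    n_perm: int = 10_000,
    seed: int = 0,
) -> NBSResult:
    """NBS with separate positive and negative contrasts.

    Suprathreshold edge sets (t > threshold, t < -threshold) are disjoint
    by construction; each contrast gets its own null distribution of the
    maximal component edge count under whole-subject label permutation.
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if t_threshold <= 0:
        raise ValueError("t_threshold must be positive")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} < 100 gives unstable p-values",
            RuntimeWarning,
            stacklevel=2,
        )
    a, b = _stack(group1), _stack(group2)
    na = a.shape[0]
    t_obs = edge_tstats(a, b)
    observed = {
        +1: _components_from_mask(t_obs > t_threshold),
        -1: _components_from_mask(t_obs < -t_threshold),
    }
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b], axis=0)
    n_tot = pooled.shape[0]
    null_max = {+1: np.zeros(n_perm), -1: np.zeros(n_perm)}
    for p in range(n_perm):
        idx = rng.permutation(n_tot)
        pa, pb = pooled[idx[:na]], pooled[idx[na:]]
        t_perm = _edge_tstats_arrays(pa, pb)
        np.fill_diagonal(t_perm, 0.0)
        null_max[+1][p] = _max_component_size(t_perm > t_threshold)
        null_max[-1][p] = _max_component_size(t_perm < -t_threshold)
    components: list[NBSComponent] = []
    for sign in (+1, -1):
        for edges, nodes in observed[sign]:
            size = len(edges)
            exceed = int(np.sum(null_max[sign] >= size))
            components.append(
                NBSComponent(
                    edges=edges,
                    sign=sign,
                    size=size,
                    p_value=(1 + exceed) / (n_perm + 1),
                    nodes=nodes,
                )
            )
    components.sort(key=lambda c: (-c.size, c.p_value))
    return NBSResult(
        threshold=float(t_threshold),
        components=components,
        n_permutations=n_perm,
        seed=seed,
        t_matrix=t_obs,
    )


def strength_comparison(
    group1: Sequence[np.ndarray],
    group2: Sequence[np.ndarray],
    direction: str = "out",
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
):
    """Per-node strength comparison between groups.

    In-strength is the column sum of a directed matrix, out-strength the
    row sum.  Returns (raw p, FDR-adjusted p, rejection mask, Hedges' g)
    arrays over nodes; constant-strength nodes get p = 1 and g = 0.
    """
    if direction not in {"in", "out"}:
        raise ValueError("direction must be 'in' or 'out'")
    a, b = _stack(group1), _stack(group2)
    axis = 1 if direction == "in" else 2
    sa = a.sum(axis=axis)  # subjects x nodes
    sb = b.sum(axis=axis)
    n_nodes = sa.shape[1]
    rng = np.random.default_rng(seed)
    p = np.ones(n_nodes)
    g = np.zeros(n_nodes)
    for j in range(n_nodes):
        if sa[:, j].std() == 0 and sb[:, j].std() == 0 and sa[:, j].mean() == sb[:, j].mean():
            continue
        p[j] = permutation_diff_means(sa[:, j], sb[:, j], n_perm, rng)
        try:
            g[j] = hedges_g(sa[:, j], sb[:, j])
        except ValueError:
            g[j] = 0.0
    p_adj, rejected = adjust_pvalues(p, method="fdr_bh", alpha=alpha)
    return p, p_adj, rejected, g
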