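"""Shannon entropy estimation and permutation-based group statistics.

Per-component entropies are estimated by default as histogram differential
entropy in nats (plug-in discrete entropy over equal-width bins plus the
log bin width).  Because the component time courses are temporally
independent by construction, the subject-level joint entropy is exactly
the sum of the per-component entropies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EntropyProfile",
    "GroupComparison",
    "shannon_entropy",
    "entropy_profiles",
    "permutation_diff_means",
    "hedges_g",
    "adjust_pvalues",
    "compare_groups",
]


@dataclass
class EntropyProfile:
    """Per-component entropies of one subject; ``joint`` is their exact sum."""

    subject_id: str
    per_component: np.ndarray
    joint: float = 0.0

    def __post_init__(self) -> None:
        self.per_component = np.asarray(self.per_component, dtype=float)
        if not np.isfinite(self.per_component).all():
            raise ValueError("entropies must be finite")
        self.joint = float(np.sum(self.per_component))


@dataclass
class GroupComparison:
    """Dimension-wise permutation comparison of two groups of profiles."""

    statistic: np.ndarray          # mean(group1) - mean(group2) per dimension
    p_values: np.ndarray           # raw permutation p per dimension
    p_adjusted: np.ndarray
    adjust_method: str
    rejected: np.ndarray           # boolean mask at alpha, adjusted
    effect_sizes: np.ndarray       # Hedges' g, group1 - group2 in the numerator
    n_permutations: int
    seed: int
    alpha: float


def _n_bins(x: np.ndarray, n_bins: int | str) -> int:
    """Bin count: explicit integer, Freedman-Diaconis, or Sturges fallback."""
    if isinstance(n_bins, (int, np.integer)):
        if n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        return int(n_bins)
    n = x.size
    sturges = int(np.ceil(np.log2(n))) + 1
    if n_bins == "sturges" or n < 64:
        return sturges
    if n_bins != "fd":
        raise ValueError(f"unknown binning rule {n_bins!r}")
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    if iqr == 0:
        return sturges
    width = 2.0 * iqr / n ** (1.0 / 3.0)
    span = x.max() - x.min()
    return max(int(np.ceil(span / width)), 1)


def shannon_entropy(
    x: Sequence[float] | np.ndarray,
    estimator: str = "differential",
    n_bins: int | str = "fd",
    log_base: float = math.e,
) -> float:
    """Histogram Shannon entropy of a sample.

    ``differential`` (default) adds log(bin width) to the plug-in discrete
    entropy, estimating the differential entropy of the underlying density;
    ``discrete`` returns the plug-in entropy of the binned distribution
    (0 for a constant sample, at most log(n_bins)).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 8:
        raise ValueError(f"need at least 8 samples, got {x.size}")
    if not np.isfinite(x).all():
        raise ValueError("samples must be finite")
    if estimator not in {"differential", "discrete"}:
        raise ValueError(f"unknown estimator {estimator!r}")
    span = x.max() - x.min()
    if span == 0:
        if estimator == "differential":
            raise ValueError(
                "constant sample: differential entropy diverges to -inf"
            )
        return 0.0
    bins = _n_bins(x, n_bins)
    counts, edges = np.histogram(x, bins=bins)
    p = counts[counts > 0] / x.size
    h = -np.sum(p * np.log(p))
    if estimator == "differential":
        h += np.log(edges[1] - edges[0])
    return float(h / np.log(log_base))


def entropy_profiles(
    sources: np.ndarray,
    subject_boundaries: Sequence[tuple[int, int]],
    subject_ids: Sequence[str] | None = None,
    estimator: str = "differential",
    n_bins: int | str = "fd",
    log_base: float = math.e,
) -> list[EntropyProfile]:
    """Per-subject entropy profiles from k x T_total component sources.

    ``subject_boundaries`` must partition the source columns; each profile
    holds the k per-component entropies of that subject's column range and
    their exact sum as the joint entropy.
    """
    sources = np.asarray(sources, dtype=float)
    t_total = sources.shape[1]
    covered = 0
    for start, stop in subject_boundaries:
        if not 0 <= start < stop <= t_total:
            raise ValueError(f"invalid subject range ({start}, {stop})")
        covered += stop - start
    if covered != t_total:
        raise ValueError("subject boundaries do not partition the columns")
    if subject_ids is None:
        subject_ids = [f"s{i:03d}" for i in range(len(subject_boundaries))]
    profiles = []
    for sid, (start, stop) in zip(subject_ids, subject_boundaries):
        h = np.array([
            shannon_entropy(sources[j, start:stop], estimator, n_bins, log_base)
            for j in range(sources.shape[0])
        ])
        profiles.append(EntropyProfile(subject_id=sid, per_component=h))
    return profiles


def permutation_diff_means(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Two-sided difference-of-means permutation p-value.

    p = (1 + #{\\|perm diff\\| >= \\|observed diff\\|}) / (n_perm + 1), so the
    smallest attainable value is 1/(n_perm + 1) and p is never zero.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n_a, n_tot = a.size, pooled.size
    # vectorized label shuffles: one permuted copy of the pooled sample per row
    perm = rng.permuted(np.broadcast_to(pooled, (n_perm, n_tot)), axis=1)
    diffs = perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1)
    exceed = int(np.sum(np.abs(diffs) >= observed - 1e-12))
    return (1 + exceed) / (n_perm + 1)


def hedges_g(a: np.ndarray, b: np.ndarray) -> float:
    """Hedges' g with small-sample correction J = 1 - 3/(4(n_a+n_b) - 9).

    Positive g means the first group has the larger mean.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    n_a, n_b = a.size, b.size
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 observations")
    s2 = ((n_a - 1) * a.var(ddof=1) + (n_b - 1) * b.var(ddof=1)) / (n_a + n_b - 2)
    if s2 == 0:
        raise ValueError("zero pooled variance; effect size undefined")
    j = 1.0 - 3.0 / (4.0 * (n_a + n_b) - 9.0)
    return float(j * (a.mean() - b.mean()) / math.sqrt(s2))


def adjust_pvalues(
    p: Sequence[float] | np.ndarray,
    method: str = "fdr_bh",
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Multiple-comparison adjustment: step-up FDR, Sidak, or Bonferroni.

    Returns (adjusted p-values, boolean rejection mask at ``alpha``).
    """
    p = np.asarray(p, dtype=float).ravel()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if method not in {"fdr_bh", "sidak", "bonferroni"}:
        raise ValueError(f"unknown adjustment method {method!r}")
    rejected, p_adj, _, _ = multipletests(p, alpha=alpha, method=method)
    return p_adj, rejected


def compare_groups(
    group1: Sequence[EntropyProfile],
    group2: Sequence[EntropyProfile],
    n_perm: int = 10_000,
    seed: int = 0,
    method: str = "fdr_bh",
    alpha: float = 0.05,
) -> GroupComparison:
    """Dimension-wise permutation comparison of two groups of profiles."""
    h1 = np.array([p.per_component for p in group1])  # subjects x k
    h2 = np.array([p.per_component for p in group2])
    if h1.shape[1] != h2.shape[1]:
        raise ValueError("groups have different numbers of components")
    k = h1.shape[1]
    rng = np.random.default_rng(seed)
    stats = np.empty(k)
    pvals = np.empty(k)
    effects = np.empty(k)
    for j in range(k):
        stats[j] = h1[:, j].mean() - h2[:, j].mean()
        pvals[j] = permutation_diff_means(h1[:, j], h2[:, j], n_perm, rng)
        effects[j] = hedges_g(h1[:, j], h2[:, j])
    p_adj, rejected = adjust_pvalues(pvals, method=method, alpha=alpha)
    return GroupComparison(
        statistic=stats,
        p_values=pvals,
        p_adjusted=p_adj,
        adjust_method=method,
        rejected=rejected,
        effect_sizes=effects,
        n_permutations=n_perm,
        seed=seed,
        alpha=alpha,
    )
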