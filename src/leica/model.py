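"""High-level modelling interface.

``LEICA`` is the front door of the package: build it from one or two
groups of regional time series plus a :class:`~leica.io.RunConfig`, call
``fit()``, and read the results (dimensionality, independent components,
entropy profiles, group comparison) off the returned
:class:`LEICAResults`, statsmodels-style.

The compression chain is: band-pass filter -> Hilbert phase ->
per-timepoint phase-coherence matrix -> leading eigenvector (or one of
the two comparison representations) -> Marcenko-Pastur dimensionality ->
temporal ICA -> per-component entropies -> permutation group tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import phase as _phase
from .decomposition import (
    Decomposition,
    component_core_regions,
    count_significant_dimensions,
    fit_ica,
)
from .entropy import (
    EntropyProfile,
    GroupComparison,
    compare_groups,
    entropy_profiles,
    hedges_g,
    permutation_diff_means,
)
from .io import RegionalTimeSeries, RunConfig

__all__ = ["LEICA", "LEICAResults"]


@dataclass
class LEICAResults:
    """Fitted LEICA decomposition and group statistics.

    ``profiles`` holds one entropy profile per subject (group 1 first);
    when two groups were supplied, ``comparison`` carries the
    dimension-wise permutation tests (FDR-adjusted) and ``joint_p`` /
    ``joint_g`` the joint-entropy contrast.
    """

    config: RunConfig
    representation: str
    n_components: int
    decomposition: Decomposition
    rho: np.ndarray | None
    subject_boundaries: list[tuple[int, int]]
    profiles: list[EntropyProfile]
    group_sizes: tuple[int, int]
    comparison: GroupComparison | None = None
    joint_p: float | None = None
    joint_g: float | None = None
    labels: Sequence[str] | None = None
    E: np.ndarray | None = None

    @property
    def group1_profiles(self) -> list[EntropyProfile]:
        return self.profiles[: self.group_sizes[0]]

    @property
    def group2_profiles(self) -> list[EntropyProfile]:
        return self.profiles[self.group_sizes[0]:]

    def entropy_table(self) -> pd.DataFrame:
        """Tidy per-subject table: one row per subject, one column per dimension."""
        rows = []
        for i, p in enumerate(self.profiles):
            group = 1 if i < self.group_sizes[0] else 2
            row = {"subject_id": p.subject_id, "group": group, "joint": p.joint}
            row.update({f"H{j + 1}": h for j, h in enumerate(p.per_component)})
            rows.append(row)
        return pd.DataFrame(rows)

    def comparison_table(self) -> pd.DataFrame:
        if self.comparison is None:
            raise ValueError("fitted on a single group; no comparison available")
        c = self.comparison
        df = pd.DataFrame({
            "dimension": np.arange(1, self.n_components + 1),
            "mean_diff": c.statistic,
            "p": c.p_values,
            "p_adj": c.p_adjusted,
            "significant": c.rejected,
            "hedges_g": c.effect_sizes,
        })
        joint = pd.DataFrame({
            "dimension": ["joint"],
            "mean_diff": [
                np.mean([p.joint for p in self.group1_profiles])
                - np.mean([p.joint for p in self.group2_profiles])
            ],
            "p": [self.joint_p],
            "p_adj": [np.nan],
            "significant": [self.joint_p < self.comparison.alpha],
            "hedges_g": [self.joint_g],
        })
        return pd.concat([df, joint], ignore_index=True)

    def core_regions(self, z_threshold: float = 1.3) -> list[dict]:
        """Signed core-region sets of each component map (|z| above threshold)."""
        cores = component_core_regions(self.decomposition.maps, z_threshold)
        if self.labels is not None:
            labels = list(self.labels)
            for c in cores:
                c["positive_labels"] = [labels[i] for i in c["positive"]]
                c["negative_labels"] = [labels[i] for i in c["negative"]]
        return cores

    def summary(self) -> str:
        n1, n2 = self.group_sizes
        lines = [
            "Leading-eigenvector independent component analysis",
            "=" * 58,
            f"representation:      {self.representation}",
            f"subjects:            {n1}" + (f" + {n2}" if n2 else ""),
            f"components (MP):     {self.n_components}",
        ]
        if self.rho is not None:
            lines.append(
                f"rho (min / mean):    {self.rho.min():.4f} / {self.rho.mean():.4f}"
            )
        lines.append(
            f"joint entropy:       {np.mean([p.joint for p in self.profiles]):.4f} "
            f"(mean over subjects, nats)"
        )
        if self.comparison is not None:
            lines += [
                "-" * 58,
                f"{'dim':>4} {'mean diff':>10} {'p':>8} {'p_adj':>8} {'g':>8}",
            ]
            c = self.comparison
            for j in range(self.n_components):
                flag = " *" if c.rejected[j] else ""
                lines.append(
                    f"{j + 1:>4} {c.statistic[j]:>10.4f} {c.p_values[j]:>8.4f} "
                    f"{c.p_adjusted[j]:>8.4f} {c.effect_sizes[j]:>8.4f}{flag}"
                )
            lines.append(
                f"{'joint':>4} {'':>10} {self.joint_p:>8.4f} {'':>8} {self.joint_g:>8.4f}"
            )
            lines.append(f"(* significant after {c.adjust_method} at alpha={c.alpha})")
        return "\n".join(lines)

    def plot_entropy(self, ax=None):
        """Box plot of joint entropies by group (matplotlib axes returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        data = [[p.joint for p in self.group1_profiles]]
        labels = ["group 1"]
        if self.group_sizes[1]:
            data.append([p.joint for p in self.group2_profiles])
            labels.append("group 2")
        ax.boxplot(data, tick_labels=labels)
        ax.set_ylabel("joint entropy (nats)")
        return ax


class LEICA:
    """Leading-eigenvector ICA model over one or two groups of subjects.

    Parameters
    ----------
    group1, group2 : sequences of RegionalTimeSeries
        Parcellated BOLD-like series, all with the same region count and
        sampling interval; ``group2`` may be omitted for a single-cohort
        decomposition.
    config : RunConfig, optional
        Band, representation, permutation and entropy settings.
    """

    def __init__(
        self,
        group1: Sequence[RegionalTimeSeries],
        group2: Sequence[RegionalTimeSeries] | None = None,
        config: RunConfig | None = None,
    ) -> None:
        self.config = config or RunConfig()
        group2 = list(group2) if group2 else []
        self.group1 = list(group1)
        self.group2 = group2
        cohort = self.group1 + self.group2
        if not cohort:
            raise ValueError("empty cohort")
        n = cohort[0].n_regions
        tr = cohort[0].tr
        for ts in cohort:
            if ts.n_regions != n:
                raise ValueError("all subjects must share the region count")
            if ts.tr != tr:
                raise ValueError("all subjects must share the sampling interval")
        self.config.validate_band(tr)
        self.labels = cohort[0].labels
        self._cohort = cohort

    def fit(self, n_components: int | None = None) -> LEICAResults:
        """Run the full compression + decomposition + entropy chain.

        ``n_components`` overrides the Marcenko-Pastur estimate (useful
        when the comparison representations detect a different count).
        """
        cfg = self.config
        filtered = [
            _phase.bandpass_filter(ts, cfg.band_low, cfg.band_high)
            for ts in self._cohort
        ]
        rho = None
        e_matrix = None
        if cfg.representation == "eigenvector":
            ev = _phase.eigenvector_series(filtered)
            x, bounds = ev.E, ev.subject_boundaries
            rho, e_matrix = ev.rho, ev.E
            ids = ev.subject_ids
        else:
            x, bounds = _phase.alternative_representation(
                filtered, cfg.representation
            )
            ids = [ts.subject_id for ts in self._cohort]
        k = n_components if n_components is not None else count_significant_dimensions(x)
        if k < 1:
            raise ValueError(
                "no dimension exceeds the Marcenko-Pastur bound; "
                "pass n_components explicitly to force a decomposition"
            )
        decomp = fit_ica(x, k, seed=cfg.seed)
        profiles = entropy_profiles(
            decomp.sources,
            bounds,
            ids,
            estimator=cfg.entropy_estimator,
            n_bins=cfg.entropy_bins,
            log_base=cfg.entropy_log_base,
        )
        n1, n2 = len(self.group1), len(self.group2)
        comparison = joint_p = joint_g = None
        if n2 >= 2:
            comparison = compare_groups(
                profiles[:n1],
                profiles[n1:],
                n_perm=cfg.n_permutations,
                seed=cfg.seed,
                alpha=cfg.alpha,
            )
            j1 = np.array([p.joint for p in profiles[:n1]])
            j2 = np.array([p.joint for p in profiles[n1:]])
            joint_p = permutation_diff_means(
                j1, j2, cfg.n_permutations, np.random.default_rng(cfg.seed + 1)
            )
            joint_g = hedges_g(j1, j2)
        return LEICAResults(
            config=cfg,
            representation=cfg.representation,
            n_components=k,
            decomposition=decomp,
            rho=rho,
            subject_boundaries=bounds,
            profiles=profiles,
            group_sizes=(n1, n2),
            comparison=comparison,
            joint_p=joint_p,
            joint_g=joint_g,
            labels=self.labels,
            E=e_matrix,
        )
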