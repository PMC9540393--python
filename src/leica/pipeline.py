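"""End-to-end orchestration: load cohorts, run the analysis, persist reports.

The pipeline mirrors the analysis chain of the modelling layer and adds
artifact handling: every stage's tables are written as CSV, the run
metadata (config, seed, package version, config hash) as JSON, so a run
is reproducible from its report directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .ec import FitResult, fit_effective_connectivity
from .hopf import natural_frequencies
from .io import RegionalTimeSeries, RunConfig, load_timeseries_table, write_report
from .model import LEICA, LEICAResults
from .nbs import NBSResult, network_based_statistic, strength_comparison

logger = logging.getLogger("leica")

__all__ = ["PipelineReport", "run_pipeline", "load_cohort"]


@dataclass
class PipelineReport:
    """Everything a run produced, plus provenance."""

    results: LEICAResults
    config: RunConfig
    provenance: dict
    ec_fits: dict[str, FitResult] = field(default_factory=dict)
    nbs_results: dict[float, NBSResult] = field(default_factory=dict)
    strength: dict[str, pd.DataFrame] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    failures: list[str] = field(default_factory=list)

    def tables(self) -> dict:
        out: dict = {
            "entropy": self.results.entropy_table(),
            "component_maps": self.results.decomposition.maps,
            "sources": self.results.decomposition.sources,
            "metadata": self.provenance,
        }
        if self.results.comparison is not None:
            out["group_comparison"] = self.results.comparison_table()
        for sid, fit in self.ec_fits.items():
            out[f"ec_{sid}"] = fit.C_eff
        for thr, nbs in self.nbs_results.items():
            rows = [
                {"source": i, "target": j, "sign": c.sign,
                 "component_size": c.size, "p": c.p_value,
                 "t": nbs.t_matrix[i, j]}
                for c in nbs.components for (i, j) in c.edges
            ]
            out[f"nbs_t{thr:g}"] = pd.DataFrame(
                rows, columns=["source", "target", "sign", "component_size", "p", "t"]
            )
        for direction, df in self.strength.items():
            out[f"strength_{direction}"] = df
        return out

    def write(self, out_dir: str | Path) -> list[str]:
        return write_report(self.tables(), out_dir)


def load_cohort(
    paths: Sequence[str | Path], tr: float, labels_path: str | Path | None = None
) -> list[RegionalTimeSeries]:
    return [load_timeseries_table(p, tr=tr, labels_path=labels_path) for p in paths]


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(
    config: RunConfig,
    group1: Sequence[RegionalTimeSeries],
    group2: Sequence[RegionalTimeSeries] | None = None,
    template_C: np.ndarray | None = None,
    fit_ec: bool = False,
    run_nbs: bool = False,
    out_dir: str | Path | None = None,
    ec_options: dict | None = None,
) -> PipelineReport:
    """Execute the configured analysis and (optionally) the model stages.

    The statistical chain (filter -> phase -> representation -> dimension
    count -> ICA -> entropies -> group tests) always runs.  Effective
    connectivity fitting (``fit_ec``, needs ``template_C``) and the
    network-based statistic over the configured threshold sweep
    (``run_nbs``, needs fitted matrices in both groups) are opt-in since
    they are orders of magnitude slower.
    """
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    failures: list[str] = []
    group2 = list(group2) if group2 else []
    if group2 and (len(group1) < 2 or len(group2) < 2):
        raise ValueError("group stages need at least 2 subjects per group")
    model = LEICA(group1, group2, config)
    results = model.fit()
    timings["analysis"] = time.perf_counter() - t0
    provenance = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "representation": results.representation,
        "n_components": results.n_components,
        "group_sizes": list(results.group_sizes),
    }
    report = PipelineReport(
        results=results, config=config, provenance=provenance,
        timings=timings, failures=failures,
    )
    if fit_ec:
        if template_C is None:
            raise ValueError("fit_ec requires a structural template matrix")
        t1 = time.perf_counter()
        cohort = list(group1) + group2
        for idx, ts in enumerate(cohort):
            profile = results.profiles[idx]
            try:
                omega = natural_frequencies(ts, config.band_low, config.band_high)
                fit = fit_effective_connectivity(
                    profile,
                    results.decomposition,
                    template_C,
                    omega,
                    seed=config.seed + idx,
                    model_options=dict(
                        G=config.G,
                        alpha=config.alpha_bifurcation,
                        beta=config.beta_noise,
                        dt=config.dt,
                        duration=ts.n_timepoints * ts.tr,
                        output_tr=ts.tr,
                        band=(config.band_low, config.band_high),
                        entropy_estimator=config.entropy_estimator,
                        entropy_bins=config.entropy_bins,
                        **(ec_options or {}),
                    ),
                    n_particles=config.pso_particles,
                    n_iters=config.pso_iterations,
                )
                report.ec_fits[profile.subject_id] = fit
            except Exception as exc:  # noqa: BLE001 - partial report on stage failure
                failures.append(f"ec_fit[{profile.subject_id}]: {exc}")
                logger.exception("EC fit failed for %s", profile.subject_id)
        timings["ec_fit"] = time.perf_counter() - t1
    if run_nbs:
        n1 = len(group1)
        fits = list(report.ec_fits.values())
        if len(fits) != n1 + len(group2) or not group2:
            failures.append("nbs: needs complete EC fits for two groups")
        else:
            t2 = time.perf_counter()
            g1 = [f.C_eff for f in fits[:n1]]
            g2 = [f.C_eff for f in fits[n1:]]
            for thr in config.nbs_thresholds:
                report.nbs_results[thr] = network_based_statistic(
                    g1, g2, t_threshold=thr,
                    n_perm=config.n_permutations, seed=config.seed,
                )
            for direction in ("in", "out"):
                p, p_adj, rej, g = strength_comparison(
                    g1, g2, direction=direction,
                    n_perm=config.n_permutations, seed=config.seed,
                    alpha=config.alpha,
                )
                report.strength[direction] = pd.DataFrame({
                    "node": np.arange(p.size), "p": p, "p_adj": p_adj,
                    "significant": rej, "hedges_g": g,
                })
            timings["nbs"] = time.perf_counter() - t2
    timings["total"] = time.perf_counter() - t0
    if out_dir is not None:
        report.write(out_dir)
    return report
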