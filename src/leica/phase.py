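"""Band-limited phase dynamics and leading-eigenvector compression.

The instantaneous phase-coherence matrix at time t is

    dFC(m, n, t) = cos(theta(m, t) - theta(n, t))

with theta the Hilbert phase of the band-passed signal.  Writing
c = cos(theta(:, t)) and s = sin(theta(:, t)), the matrix equals
c c' + s s', so it is symmetric positive semidefinite with unit diagonal
and numerical rank at most two.  Its leading eigenvector therefore always
captures at least half of the eigenvalue mass (rho >= 0.5), and its sign
pattern splits the regions into two mutually opposed communities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg, signal

from .io import RegionalTimeSeries

logger = logging.getLogger("leica")

__all__ = [
    "PhaseSeries",
    "EigenvectorSeries",
    "bandpass_filter",
    "instantaneous_phase",
    "coherence_matrix",
    "leading_eigenvector",
    "eigenvector_series",
    "alternative_representation",
]


class DegenerateSignalError(ValueError):
    """A region's signal is identically zero (no phase can be defined)."""


@dataclass
class PhaseSeries:
    """Instantaneous phases, radians in (-pi, pi]; ``theta`` is N x T."""

    theta: np.ndarray
    tr: float
    edge_flags: np.ndarray | None = None  # True where Hilbert edge effects expected

    @property
    def n_regions(self) -> int:
        return self.theta.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.theta.shape[1]


@dataclass
class EigenvectorSeries:
    """Leading eigenvectors over all timepoints and subjects.

    ``E`` is N x T_total with unit-norm columns; ``rho`` holds the variance
    fraction lambda_1 / sum(lambda) per column; ``subject_boundaries`` maps
    each subject to its half-open column range.
    """

    E: np.ndarray
    rho: np.ndarray
    subject_boundaries: list[tuple[int, int]] = field(default_factory=list)
    subject_ids: list[str] = field(default_factory=list)
    tr: float = 0.0

    @property
    def n_regions(self) -> int:
        return self.E.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.E.shape[1]


def bandpass_filter(
    ts: RegionalTimeSeries, low: float, high: float, order: int = 2
) -> RegionalTimeSeries:
    """Zero-phase Butterworth band-pass after demeaning and detrending.

    Forward-backward filtering doubles the stop-band slope, so the default
    second-order design attenuates by more than 20 dB one octave outside
    the band while tolerating short series (a long FIR kernel would not).
    """
    nyquist = 0.5 * ts.fs
    if not 0 < low < high < nyquist:
        raise ValueError(
            f"band [{low}, {high}] Hz must satisfy 0 < low < high < Nyquist={nyquist:.4f}"
        )
    x = signal.detrend(ts.values, axis=1, type="linear")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=ts.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, x, axis=1)
    return RegionalTimeSeries(
        values=filtered, tr=ts.tr, labels=ts.labels, subject_id=ts.subject_id
    )


def instantaneous_phase(ts: RegionalTimeSeries) -> PhaseSeries:
    """Hilbert phase of each (demeaned, detrended) regional signal.

    The first and last ceil(T/20) samples are flagged as edge-affected by
    the transform's circularity but are kept: downstream analysis uses all
    timepoints by default.
    """
    x = signal.detrend(ts.values - ts.values.mean(axis=1, keepdims=True), axis=1)
    norms = np.abs(x).max(axis=1)
    if np.any(norms == 0):
        bad = int(np.argmax(norms == 0))
        raise DegenerateSignalError(f"region {bad} is constant; phase undefined")
    analytic = signal.hilbert(x, axis=1)
    theta = np.angle(analytic)
    t = ts.n_timepoints
    k = int(np.ceil(t / 20))
    flags = np.zeros(t, dtype=bool)
    flags[:k] = True
    flags[t - k:] = True
    return PhaseSeries(theta=theta, tr=ts.tr, edge_flags=flags)


def coherence_matrix(phases: PhaseSeries | np.ndarray, t: int) -> np.ndarray:
    """Phase-coherence matrix cos(theta_m - theta_n) at timepoint t."""
    theta = phases.theta if isinstance(phases, PhaseSeries) else np.asarray(phases)
    if not 0 <= t < theta.shape[1]:
        raise IndexError(f"timepoint {t} out of range [0, {theta.shape[1]})")
    col = theta[:, t]
    c, s = np.cos(col), np.sin(col)
    m = np.outer(c, c) + np.outer(s, s)
    # exact unit diagonal despite rounding
    np.fill_diagonal(m, 1.0)
    return m


def _apply_sign_convention(v: np.ndarray) -> np.ndarray:
    """Orient an eigenvector so that most of its elements are negative.

    Tie (exactly half non-positive): orient so the element sum is negative;
    if the sum is zero too, make the first nonzero element negative.
    """
    n = v.size
    n_nonpos = int(np.sum(v <= 0))
    if n_nonpos * 2 > n:
        return v
    if n_nonpos * 2 < n:
        return -v
    s = v.sum()
    if s > 0:
        return -v
    if s < 0:
        return v
    nz = np.nonzero(v)[0]
    if nz.size and v[nz[0]] > 0:
        return -v
    return v


def leading_eigenvector(m: np.ndarray) -> tuple[np.ndarray, float]:
    """Leading eigenvector and its variance fraction rho = lambda_1/sum(lambda).

    The matrix is positive semidefinite by construction, so the eigenvalue
    sum is taken over the eigenvalues clipped at zero (tiny negative values
    are rounding noise).  The returned vector has unit norm and satisfies
    the majority-negative sign convention.
    """
    m = np.asarray(m, dtype=float)
    eigvals, eigvecs = linalg.eigh(m)
    if m.shape[0] > 1 and abs(eigvals[-1] - eigvals[-2]) < 1e-12:
        logger.warning("leading eigenvalue is degenerate; tie broken by solver order")
    v1 = _apply_sign_convention(eigvecs[:, -1])
    v1 = v1 / np.linalg.norm(v1)
    pos = np.clip(eigvals, 0.0, None)
    total = pos.sum()
    rho = float(pos[-1] / total) if total > 0 else 0.0
    return v1, rho


def eigenvector_series(
    cohort: Sequence[RegionalTimeSeries] | Sequence[PhaseSeries],
) -> EigenvectorSeries:
    """Concatenate per-timepoint leading eigenvectors across a cohort.

    Accepts raw (already band-passed) time series, or precomputed phase
    series.  Columns are ordered subject by subject, time within subject.
    """
    if not cohort:
        raise ValueError("empty cohort")
    phase_list: list[PhaseSeries] = []
    ids: list[str] = []
    for i, item in enumerate(cohort):
        if isinstance(item, PhaseSeries):
            phase_list.append(item)
            ids.append(f"s{i:03d}")
        else:
            phase_list.append(instantaneous_phase(item))
            ids.append(item.subject_id or f"s{i:03d}")
    n = phase_list[0].n_regions
    if any(p.n_regions != n for p in phase_list):
        raise ValueError("all subjects must share the same number of regions")
    cols, rhos, bounds = [], [], []
    start = 0
    for p in phase_list:
        for t in range(p.n_timepoints):
            v1, rho = leading_eigenvector(coherence_matrix(p, t))
            cols.append(v1)
            rhos.append(rho)
        bounds.append((start, start + p.n_timepoints))
        start += p.n_timepoints
    return EigenvectorSeries(
        E=np.column_stack(cols),
        rho=np.asarray(rhos),
        subject_boundaries=bounds,
        subject_ids=ids,
        tr=phase_list[0].tr,
    )


def alternative_representation(
    cohort: Sequence[RegionalTimeSeries] | Sequence[PhaseSeries],
    kind: str,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Comparison compressions of the dFC array.

    ``vectorized``: the upper triangle of each coherence matrix (diagonal
    excluded, row-major pair order (0,1), (0,2), ...), N(N-1)/2 rows.
    ``spatial_mean``: the row means of each coherence matrix, N rows.
    Returns the space-time matrix and per-subject column ranges.
    """
    if kind not in {"vectorized", "spatial_mean"}:
        raise ValueError(f"unknown representation kind {kind!r}")
    phase_list = [
        item if isinstance(item, PhaseSeries) else instantaneous_phase(item)
        for item in cohort
    ]
    n = phase_list[0].n_regions
    iu = np.triu_indices(n, k=1)
    cols, bounds = [], []
    start = 0
    for p in phase_list:
        for t in range(p.n_timepoints):
            m = coherence_matrix(p, t)
            cols.append(m[iu] if kind == "vectorized" else m.mean(axis=1))
        bounds.append((start, start + p.n_timepoints))
        start += p.n_timepoints
    return np.column_stack(cols), bounds
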