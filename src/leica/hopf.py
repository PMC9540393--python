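"""Coupled supercritical Hopf oscillator network.

Each node j obeys the normal form

    dx_j = [(alpha_j - x_j^2 - y_j^2) x_j - omega_j y_j
            + G sum_i C_ij (x_i - x_j)] dt + beta dW_jx
    dy_j = [(alpha_j - x_j^2 - y_j^2) y_j + omega_j x_j
            + G sum_i C_ij (y_i - y_j)] dt + beta dW_jy

so alpha_j > 0 gives a limit cycle of radius sqrt(alpha_j) at angular
frequency omega_j, alpha_j < 0 a damped noise-driven focus, and alpha_j = 0
(the default operating point, with G = 0.2) the critical regime between
them.  C[i, j] is the coupling strength from node i into node j; diffusive
coupling acts identically on x and y.  Integration is Euler-Maruyama.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import signal as _signal

from .io import RegionalTimeSeries

__all__ = ["HopfParams", "natural_frequencies", "simulate_hopf", "InstabilityError"]


class InstabilityError(RuntimeError):
    """The Euler-Maruyama trajectory blew up (reduce dt or coupling)."""


@dataclass
class HopfParams:
    """Parameters of a Hopf network simulation.

    ``omega`` is per-node angular frequency in rad/s; ``alpha`` may be a
    scalar or per-node array; ``beta`` is the additive noise amplitude;
    ``dt`` the integrator step and ``output_tr`` the sampling interval of
    the returned series (``dt <= output_tr / 5``); ``burn_in`` seconds are
    discarded before sampling.
    """

    C: np.ndarray
    G: float = 0.2
    alpha: float | np.ndarray = 0.0
    omega: np.ndarray = field(default_factory=lambda: np.array([2 * np.pi * 0.05]))
    beta: float = 0.02
    dt: float = 0.1
    duration: float = 350.0
    output_tr: float = 2.0
    burn_in: float = 20.0

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim != 2 or self.C.shape[0] != self.C.shape[1]:
            raise ValueError("C must be square")
        if not np.isfinite(self.C).all():
            raise ValueError("C must be finite")
        if np.any(np.diag(self.C) != 0):
            raise ValueError("C must have zero diagonal")
        n = self.C.shape[0]
        self.omega = np.broadcast_to(np.asarray(self.omega, float), (n,)).copy()
        self.alpha = np.broadcast_to(np.asarray(self.alpha, float), (n,)).copy()
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if self.dt > self.output_tr / 5 + 1e-12:
            raise ValueError("require dt <= output_tr / 5")

    @property
    def n_nodes(self) -> int:
        return self.C.shape[0]


def natural_frequencies(
    ts: RegionalTimeSeries, band_low: float = 0.01, band_high: float = 0.08
) -> np.ndarray:
    """Per-node angular frequency from the in-band periodogram peak.

    omega_j = 2 pi f_peak where f_peak maximizes the periodogram of node j
    restricted to [band_low, band_high] Hz.
    """
    if ts.n_timepoints * ts.tr < 3.0 / band_low:
        raise ValueError(
            "series too short to resolve the low band edge "
            f"(need >= {3.0 / band_low:.0f} s, have {ts.n_timepoints * ts.tr:.0f} s)"
        )
    freqs, pxx = _signal.periodogram(ts.values, fs=ts.fs, axis=1, detrend="linear")
    in_band = (freqs >= band_low) & (freqs <= band_high)
    if not in_band.any():
        raise ValueError("no periodogram frequencies inside the band")
    band_freqs = freqs[in_band]
    peak = np.argmax(pxx[:, in_band], axis=1)
    return 2 * np.pi * band_freqs[peak]


@njit(cache=True)
def _integrate(x, y, c, col_strength, g, alpha, omega, beta_sqdt, dt, n_steps,
               noise, keep_every, burn_steps, out_x, out_y):  # pragma: no cover
    n = x.size
    kept = 0
    for step in range(n_steps):
        # diffusive coupling: sum_i C[i, j] * (x_i - x_j)
        cx = x @ c
        cy = y @ c
        for j in range(n):
            r2 = x[j] * x[j] + y[j] * y[j]
            dx = (alpha[j] - r2) * x[j] - omega[j] * y[j] + g * (cx[j] - col_strength[j] * x[j])
            dy = (alpha[j] - r2) * y[j] + omega[j] * x[j] + g * (cy[j] - col_strength[j] * y[j])
            x[j] = x[j] + dx * dt + beta_sqdt * noise[step, j]
            y[j] = y[j] + dy * dt + beta_sqdt * noise[step, n + j]
        if step >= burn_steps and (step - burn_steps) % keep_every == 0:
            for j in range(n):
                out_x[j, kept] = x[j]
                out_y[j, kept] = y[j]
                if not (abs(x[j]) <= 1e6):
                    return -1
            kept += 1
    return kept


def simulate_hopf(
    params: HopfParams,
    seed: int | np.random.Generator = 0,
    return_xy: bool = False,
) -> RegionalTimeSeries | tuple[np.ndarray, np.ndarray]:
    """Euler-Maruyama simulation; returns x sampled every ``output_tr``.

    Deterministic given the seed: one generator drives all Wiener
    increments (independent streams for each node's x and y).  With
    ``return_xy=True`` the raw sampled (x, y) arrays are returned instead
    of a RegionalTimeSeries (useful for single-node phase-plane checks).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = params.n_nodes
    dt = params.dt
    n_steps = int(round((params.burn_in + params.duration) / dt))
    burn_steps = int(round(params.burn_in / dt))
    keep_every = max(int(round(params.output_tr / dt)), 1)
    n_out = (n_steps - burn_steps + keep_every - 1) // keep_every
    noise = (
        rng.standard_normal((n_steps, 2 * n))
        if params.beta > 0
        else np.zeros((n_steps, 2 * n))
    )
    x = 0.1 + 0.01 * rng.standard_normal(n)
    y = 0.01 * rng.standard_normal(n)
    out_x = np.empty((n, n_out))
    out_y = np.empty((n, n_out))
    kept = _integrate(
        x, y,
        np.ascontiguousarray(params.C),
        params.C.sum(axis=0),
        float(params.G),
        np.asarray(params.alpha, float),
        np.asarray(params.omega, float),
        float(params.beta) * np.sqrt(dt),
        float(dt),
        n_steps,
        noise,
        keep_every,
        burn_steps,
        out_x,
        out_y,
    )
    if kept < 0:
        raise InstabilityError(
            f"trajectory exceeded 1e6 with dt={dt}; reduce dt or coupling"
        )
    if return_xy:
        return out_x[:, :kept], out_y[:, :kept]
    return RegionalTimeSeries(
        values=out_x[:, :kept], tr=params.output_tr, subject_id="hopf"
    )
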