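"""Intrinsic dimensionality via random-matrix theory, and temporal ICA.

If the m rows of an m x n matrix are independent noise, the eigenvalues of
their correlation matrix follow the Marcenko-Pastur law with upper edge
sigma^2 (1 + sqrt(1/q))^2, q = n/m.  Eigenvalues above that edge mark
dimensions that recur above chance; fastICA then extracts that many
temporally independent component time courses from the space-time matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "MPBound",
    "Decomposition",
    "mp_upper_bound",
    "count_significant_dimensions",
    "fit_ica",
    "component_core_regions",
    "project_sources",
]


@dataclass(frozen=True)
class MPBound:
    """Marcenko-Pastur eigenvalue support for an m x n data matrix."""

    sigma2: float
    q: float  # aspect ratio n/m >= 1
    lambda_max: float
    lambda_min: float


@dataclass
class Decomposition:
    """A fitted temporal ICA of a space-time matrix X (N rows, T columns).

    ``sources`` (k x T) are zero-mean unit-variance independent time
    courses ordered by decreasing mean absolute activity; ``maps`` = the
    mixing matrix columns give each component's spatial weights;
    ``unmixing`` (k x N) applied to centered columns of X reproduces the
    sources.  Component sign is arbitrary (relative orientation only).
    """

    n_components: int
    maps: np.ndarray       # N x k (== mixing)
    mixing: np.ndarray     # N x k
    unmixing: np.ndarray   # k x N
    sources: np.ndarray    # k x T
    row_means: np.ndarray  # N, training row means used for centering
    seed: int
    converged: bool = True

    @property
    def n_features(self) -> int:
        return self.maps.shape[0]


def mp_upper_bound(m: int, n: int, sigma2: float = 1.0) -> MPBound:
    """Marcenko-Pastur support edges for m rows observed over n columns.

    The long axis must be passed as ``n`` (q = n/m >= 1).
    """
    if m < 2:
        raise ValueError("need at least 2 rows")
    if n < m:
        raise ValueError(
            f"aspect ratio requires n >= m; got m={m}, n={n} (pass the long axis as n)"
        )
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    q = n / m
    root = np.sqrt(1.0 / q)
    return MPBound(
        sigma2=float(sigma2),
        q=float(q),
        lambda_max=float(sigma2 * (1 + root) ** 2),
        lambda_min=float(sigma2 * (1 - root) ** 2),
    )


def standardize_rows(x: np.ndarray) -> np.ndarray:
    """Center and scale each row to zero mean, unit (population) variance."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        bad = int(np.argmax(sd.ravel() == 0))
        raise ValueError(f"row {bad} is constant; cannot standardize")
    return (x - mu) / sd


def _integrated_autocorr_time(z: np.ndarray, max_lag: int) -> float:
    """Mean integrated autocorrelation time of standardized rows.

    tau = 1 + 2 sum_l rho_l, summed until the autocorrelation first drops
    below 0.05 (initial-positive-sequence truncation).
    """
    n = z.shape[1]
    taus = []
    for row in z:
        f = np.fft.rfft(row, 2 * n)
        ac = np.fft.irfft(f * np.conj(f))[:n]
        ac /= ac[0]
        tau = 1.0
        for lag in range(1, max_lag):
            if ac[lag] < 0.05:
                break
            tau += 2.0 * ac[lag]
        taus.append(tau)
    return float(np.mean(taus))


def count_significant_dimensions(
    x: np.ndarray,
    return_spectrum: bool = False,
    autocorr_correction: bool = False,
):
    """Number of row-correlation eigenvalues above the Marcenko-Pastur edge.

    Rows are standardized first, so sigma^2 = 1 exactly and the bound is
    parameter-free.  Rows are space, columns time; requires more columns
    than rows.

    The Marcenko-Pastur law assumes independent columns.  Compressed
    connectivity series are temporally autocorrelated, which widens the
    null spectrum and inflates the count; ``autocorr_correction=True``
    replaces the column count with an effective sample size
    n / tau (tau the mean integrated autocorrelation time of the rows),
    a partial mitigation that leaves iid inputs untouched.
    """
    x = np.asarray(x, dtype=float)
    m, n = x.shape
    if n <= m:
        raise ValueError(f"need more timepoints than rows (got {m} x {n})")
    z = standardize_rows(x)
    corr = (z @ z.T) / n
    eigvals = linalg.eigvalsh(corr)
    n_eff = n
    if autocorr_correction:
        tau = _integrated_autocorr_time(z, max(2, n // 20))
        n_eff = int(max(n / tau, m + 1))
    bound = mp_upper_bound(m, n_eff, sigma2=1.0)
    k = int(np.sum(eigvals > bound.lambda_max))
    if return_spectrum:
        return k, eigvals[::-1], bound
    return k


def fit_ica(x: np.ndarray, k: int, seed: int = 0) -> Decomposition:
    """Whiten to k dimensions and run fixed-point (log-cosh) fastICA.

    Components are reordered by decreasing mean absolute source activity
    and the sources standardized to zero mean, unit variance; the stored
    mixing/unmixing matrices absorb that rescaling, so
    ``unmixing @ (x - row_means)`` reproduces ``sources`` and
    ``mixing @ sources`` approximates the centered input (exactly, up to
    the discarded trailing principal components).
    """
    x = np.asarray(x, dtype=float)
    n, t = x.shape
    if not 1 <= k <= min(n, t):
        raise ValueError(f"k={k} outside [1, {min(n, t)}]")
    ica = FastICA(
        n_components=k,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        max_iter=1000,
        tol=1e-6,
        random_state=int(seed),
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        sources = ica.fit_transform(x.T).T  # k x T
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            warnings.warn(
                "fastICA did not converge; returning best iterate",
                RuntimeWarning,
                stacklevel=2,
            )
    mixing = ica.mixing_            # N x k
    unmixing = ica.components_      # k x N
    row_means = ica.mean_.copy()
    # order by mean absolute activity, largest first
    order = np.argsort(-np.mean(np.abs(sources), axis=1), kind="stable")
    sources = sources[order]
    mixing = mixing[:, order]
    unmixing = unmixing[order]
    # sources are zero-mean by construction; make the variance exactly one
    # and push the rescaling into the mixing/unmixing matrices
    sd = sources.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    sources = sources / sd
    mixing = mixing * sd.T
    unmixing = unmixing / sd
    return Decomposition(
        n_components=k,
        maps=mixing.copy(),
        mixing=mixing,
        unmixing=unmixing,
        sources=sources,
        row_means=row_means,
        seed=int(seed),
        converged=converged,
    )


def component_core_regions(
    maps: np.ndarray, z_threshold: float = 1.3
) -> list[dict[str, np.ndarray]]:
    """Core regions of each component map at an absolute z-score threshold.

    Each map is z-scored across regions; regions with \\|z\\| above the
    threshold are returned split by sign into the two opposing communities.
    """
    maps = np.asarray(maps, dtype=float)
    out = []
    for j in range(maps.shape[1]):
        col = maps[:, j]
        sd = col.std()
        if sd == 0:
            warnings.warn(
                f"component {j} map is constant; z-scores undefined, empty core",
                RuntimeWarning,
                stacklevel=2,
            )
            out.append({"positive": np.array([], dtype=int),
                        "negative": np.array([], dtype=int),
                        "z": np.full(col.shape, np.nan)})
            continue
        z = (col - col.mean()) / sd
        above = np.abs(z) > z_threshold
        out.append({
            "positive": np.nonzero(above & (z > 0))[0],
            "negative": np.nonzero(above & (z < 0))[0],
            "z": z,
        })
    return out


def project_sources(
    decomp: Decomposition, x_new: np.ndarray, center: bool = True
) -> np.ndarray:
    """Apply the stored centering + unmixing transform to new columns."""
    x_new = np.asarray(x_new, dtype=float)
    if x_new.shape[0] != decomp.n_features:
        raise ValueError(
            f"expected {decomp.n_features} rows, got {x_new.shape[0]}"
        )
    centered = x_new - decomp.row_means[:, None] if center else x_new
    return decomp.unmixing @ centered
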