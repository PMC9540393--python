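"""Reading and writing of time-series tables, matrices, labels and reports.

All external artifacts are plain text: CSV/TSV for numeric tables, JSON for
run metadata, YAML or JSON for run configuration, one-label-per-line text
files for region lists.  The canonical orientation of a time-series table is
regions (rows) by timepoints (columns).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("leica")

__all__ = [
    "RegionalTimeSeries",
    "RunConfig",
    "InputFormatError",
    "load_timeseries_table",
    "load_square_matrix",
    "load_labels",
    "write_matrix",
    "write_report",
    "load_config",
]


class InputFormatError(ValueError):
    """Raised when an external file does not match the expected layout."""


@dataclass
class RegionalTimeSeries:
    """Parcellated regional BOLD-like signal: ``values`` is regions x time.

    Parameters
    ----------
    values : ndarray, shape (N, T)
        One row per region, one column per sampled volume.
    tr : float
        Sampling interval in seconds (repetition time).
    labels : sequence of str, optional
        Region names, length N and unique.  Defaults to ``r000..r{N-1}``.
    subject_id : str
        Identifier carried through reports.
    """

    values: np.ndarray
    tr: float
    labels: Sequence[str] | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InputFormatError("time series must be a 2-D regions x time array")
        n, t = self.values.shape
        if n < 2:
            raise InputFormatError(f"need at least 2 regions, got {n}")
        if t < 8:
            raise InputFormatError(f"need at least 8 timepoints, got {t}")
        if not np.isfinite(self.values).all():
            raise InputFormatError("time series contains non-finite values")
        if self.tr <= 0:
            raise InputFormatError("tr must be positive (seconds)")
        if self.labels is None:
            self.labels = [f"r{i:03d}" for i in range(n)]
        self.labels = list(self.labels)
        if len(self.labels) != n:
            raise InputFormatError(
                f"{len(self.labels)} labels for {n} regions"
            )
        if len(set(self.labels)) != n:
            raise InputFormatError("region labels must be unique")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def fs(self) -> float:
        """Sampling frequency in Hz."""
        return 1.0 / self.tr


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    The band defaults to the canonical resting-state window 0.01-0.08 Hz;
    group tests default to 10,000 label permutations; the Hopf model starts
    at the bifurcation point (``alpha_bifurcation = 0``) with global
    coupling ``G = 0.2``.
    """

    band_low: float = 0.01
    band_high: float = 0.08
    representation: str = "eigenvector"
    n_permutations: int = 10_000
    alpha: float = 0.05
    entropy_estimator: str = "differential"
    entropy_bins: int | str = "fd"
    entropy_log_base: float = float(np.e)
    G: float = 0.2
    alpha_bifurcation: float = 0.0
    beta_noise: float = 0.02
    dt: float = 0.1
    pso_particles: int = 20
    pso_iterations: int = 50
    nbs_thresholds: tuple[float, ...] = (4.0, 4.5, 5.0, 5.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError("require 0 < band_low < band_high")
        if self.representation not in {"eigenvector", "vectorized", "spatial_mean"}:
            raise ValueError(f"unknown representation {self.representation!r}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if any(t <= 0 for t in self.nbs_thresholds):
            raise ValueError("NBS thresholds must be positive")

    def validate_band(self, tr: float) -> None:
        nyquist = 0.5 / tr
        if self.band_high >= nyquist:
            raise ValueError(
                f"band_high={self.band_high} Hz is at or above Nyquist "
                f"({nyquist:.4f} Hz for tr={tr}s)"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["nbs_thresholds"] = list(self.nbs_thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "nbs_thresholds" in d:
            d["nbs_thresholds"] = tuple(d["nbs_thresholds"])
        return cls(**d)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        raise InputFormatError(f"{path} is empty")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep, header=None, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise InputFormatError(f"{path} is empty") from exc
    return df


def _to_float_matrix(df: pd.DataFrame, path: Path, skip_header: bool) -> np.ndarray:
    if skip_header:
        df = df.iloc[1:]
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise InputFormatError(f"non-numeric cell in {path}: {exc}") from exc
    if np.isnan(values).any():
        raise InputFormatError(f"missing or ragged values in {path}")
    return values


def _looks_like_header(df: pd.DataFrame) -> bool:
    first = df.iloc[0]
    try:
        first.astype(float)
    except ValueError:
        return True
    return False


def load_timeseries_table(
    path: str | Path,
    tr: float,
    labels_path: str | Path | None = None,
    subject_id: str | None = None,
) -> RegionalTimeSeries:
    """Load a delimited regions x time table.

    Rows are regions by convention.  If a label file is supplied and its
    length matches the number of *columns* instead, the table is transposed
    (and the transposition logged); labels are otherwise taken in file
    order, never reordered.
    """
    path = Path(path)
    df = _read_table(path)
    values = _to_float_matrix(df, path, skip_header=_looks_like_header(df))
    labels = load_labels(labels_path) if labels_path is not None else None
    if labels is not None:
        if len(labels) == values.shape[1] and len(labels) != values.shape[0]:
            logger.info(
                "%s: %d labels match columns, not rows; transposing to regions x time",
                path, len(labels),
            )
            values = values.T
        elif len(labels) != values.shape[0]:
            raise InputFormatError(
                f"{len(labels)} labels do not match table shape {values.shape}"
            )
    return RegionalTimeSeries(
        values=values,
        tr=tr,
        labels=labels,
        subject_id=subject_id or path.stem,
    )


def load_square_matrix(path: str | Path) -> np.ndarray:
    """Load a square delimited matrix (e.g. a structural connectivity template).

    Asymmetry produces a warning, not an error: effective connectivity is
    directed.
    """
    path = Path(path)
    df = _read_table(path)
    values = _to_float_matrix(df, path, skip_header=_looks_like_header(df))
    if values.shape[0] != values.shape[1]:
        raise InputFormatError(f"{path}: matrix is {values.shape}, not square")
    if not np.allclose(values, values.T):
        logger.warning("%s: matrix is asymmetric; keeping as directed", path)
    return values


def load_labels(path: str | Path) -> list[str]:
    """Read a one-label-per-line region list, preserving file order."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return [ln for ln in lines if ln]


def write_matrix(values: np.ndarray, path: str | Path) -> None:
    """Write a numeric matrix as headerless CSV with full double precision."""
    np.savetxt(path, np.atleast_2d(values), delimiter=",", fmt="%.17g")


def write_timeseries(ts: RegionalTimeSeries, path: str | Path) -> None:
    write_matrix(ts.values, path)


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML or JSON."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise InputFormatError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)


def write_report(results: dict, out_dir: str | Path) -> list[str]:
    """Persist pipeline results and return the manifest of written files.

    ``results`` maps names to pandas DataFrames (written as CSV), numpy
    arrays (headerless CSV) or JSON-serializable objects (written as JSON,
    e.g. the run metadata under the key ``"metadata"``).  Re-running with
    the same configuration and seed reproduces every table byte for byte.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc
    manifest: list[str] = []
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            fname = f"{name}.csv"
            obj.to_csv(out_dir / fname, index=False, float_format="%.17g")
        elif isinstance(obj, np.ndarray):
            fname = f"{name}.csv"
            write_matrix(obj, out_dir / fname)
        else:
            fname = f"{name}.json"
            (out_dir / fname).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))
        manifest.append(fname)
        logger.info("wrote %s", out_dir / fname)
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
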