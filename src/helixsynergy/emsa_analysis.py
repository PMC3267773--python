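"""EMSA mobility detrending and periodic local-minimum detection.

In a native gel, a protein-DNA complex whose bound factors protrude on
opposite sides of the helix is effectively wider than one with all
factors on the same side, and migrates more slowly.  Across a spacer
series, however, the probe itself grows with the spacer, so migration
reflects both probe length and complex shape.  The analysis removes the
length effect by fitting a *marker line* — log(migration) of the free
probe versus probe length — and examining the residual of each
saturated-complex lane from that line.  Local minima of the residual
series (lanes slowest relative to their length) mark spacers where the
complex is widest, i.e. the activators sit on opposite helix faces.

The minimum-picking rule handles near-ties explicitly: where two or
more consecutive residuals are indistinguishable (within ``tie_epsilon``
of the run's minimum), the middle lane of the run is reported as the
single minimum.  Endpoints of the series are never reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError

__all__ = [
    "GelTable",
    "MarkerLine",
    "DetrendedSeries",
    "read_gel_table",
    "marker_line",
    "detrend",
    "find_local_minima",
    "find_extrema_runs",
    "DEFAULT_TIE_FRACTION",
]

#: Default tie tolerance as a fraction of the detrended series' range.
DEFAULT_TIE_FRACTION = 0.02

GEL_COLUMNS = ["spacer_bp", "probe_length_bp", "migration_free", "migration_complex"]


@dataclass(frozen=True)
class GelTable:
    """Per-lane gel measurements for a spacer series.

    One lane per spacer: probe length in bp and migration distances of
    the free probe and of the fully saturated complex (same length
    units throughout, e.g. mm or px).
    """

    lanes: pd.DataFrame
    units: str = "mm"

    def __post_init__(self) -> None:
        df = self.lanes
        missing = [c for c in GEL_COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"gel table missing columns: {missing}")
        if (df["migration_free"] <= 0).any():
            raise InputError("free-probe migrations must be positive")
        spacers = df["spacer_bp"].to_numpy()
        if not np.all(np.diff(spacers) > 0):
            raise InputError("spacers must be strictly increasing")
        if not np.all(np.diff(df["probe_length_bp"].to_numpy()) > 0):
            raise InputError("probe length must strictly increase with spacer")


def read_gel_table(path, units: str = "mm") -> GelTable:
    """Read a gel table from CSV/TSV (delimiter sniffed from extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return GelTable(lanes=pd.read_csv(path, sep=sep), units=units)


@dataclass(frozen=True)
class MarkerLine:
    """Least-squares line of log(free-probe migration) on probe length."""

    slope: float
    intercept: float
    residual_sd: float

    def __call__(self, length_bp) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(length_bp, dtype=float)


@dataclass(frozen=True)
class DetrendedSeries:
    """Residual log-mobility of the complex after marker-line removal.

    A lower residual means the complex ran slower than a free probe of
    the same length predicts, i.e. the complex is larger.
    """

    spacers: np.ndarray
    residuals: np.ndarray


def marker_line(free_lengths, free_migrations) -> MarkerLine:
    """Fit the free-probe marker line log(migration) ~ length.

    Requires at least 3 lanes and positive migrations; returns slope,
    intercept and the residual standard deviation of the fit.
    """
    lengths = np.asarray(free_lengths, dtype=float)
    migrations = np.asarray(free_migrations, dtype=float)
    if lengths.size < 3:
        raise InputError("marker line needs at least 3 lanes")
    if np.any(migrations <= 0):
        raise InputError("migrations must be positive")
    fit = stats.linregress(lengths, np.log(migrations))
    resid = np.log(migrations) - (fit.intercept + fit.slope * lengths)
    return MarkerLine(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        residual_sd=float(np.std(resid, ddof=2)) if lengths.size > 2 else 0.0,
    )


def detrend(gel: GelTable, marker: MarkerLine) -> DetrendedSeries:
    """Residual of each complex lane from the marker line.

    Lanes without a usable (positive, finite) complex migration are
    skipped with a warning.
    """
    df = gel.lanes
    mig = df["migration_complex"].to_numpy(dtype=float)
    ok = np.isfinite(mig) & (mig > 0)
    if not ok.all():
        bad = df["spacer_bp"].to_numpy()[~ok]
        warnings.warn(
            f"skipping lanes without complex migration at spacers {bad.tolist()}",
            stacklevel=2,
        )
    lengths = df["probe_length_bp"].to_numpy(dtype=float)[ok]
    residual = np.log(mig[ok]) - marker(lengths)
    return DetrendedSeries(
        spacers=df["spacer_bp"].to_numpy(dtype=float)[ok], residuals=residual
    )


def _check_regular_grid(x: np.ndarray) -> None:
    steps = np.diff(x)
    if x.size < 3:
        raise InputError("need at least 3 points")
    if not np.allclose(steps, steps[0]) or steps[0] <= 0:
        raise InputError("grid must be regular and increasing")


def find_extrema_runs(values: np.ndarray, tie_epsilon: float) -> list[tuple[int, int]]:
    """Maximal runs of consecutive near-tied values, scanned left to right.

    A run grows while every value in it stays within ``tie_epsilon`` of
    the running minimum/maximum of the window.  Used by the minimum
    finder; exposed for the shared peak/trough contract.
    """
    runs = []
    n = len(values)
    i = 0
    while i < n:
        j = i
        lo = hi = values[i]
        while j + 1 < n:
            lo2 = min(lo, values[j + 1])
            hi2 = max(hi, values[j + 1])
            if hi2 - lo2 > tie_epsilon:
                break
            lo, hi = lo2, hi2
            j += 1
        runs.append((i, j))
        i = j + 1
    return runs


def find_local_minima(
    series: DetrendedSeries, tie_epsilon: float | None = None
) -> list[float]:
    """Spacers at interior local minima of the detrended series.

    An interior point strictly below both neighbours is a minimum.
    Where a run of two or more consecutive points is indistinguishable
    (all within ``tie_epsilon`` of the run's minimum), the run counts
    as one minimum and its middle point (lower index for even-length
    runs) is reported.  Series endpoints are never reported.  The
    default ``tie_epsilon`` is 2% of the series' residual range.
    """
    x = np.asarray(series.spacers, dtype=float)
    v = np.asarray(series.residuals, dtype=float)
    _check_regular_grid(x)
    if tie_epsilon is None:
        span = float(v.max() - v.min())
        tie_epsilon = DEFAULT_TIE_FRACTION * span
    minima: list[float] = []
    runs = find_extrema_runs(v, tie_epsilon)
    for i, j in runs:
        if i == 0 or j == len(v) - 1:
            continue  # touches an endpoint
        run_min = v[i : j + 1].min()
        if run_min < v[i - 1] and run_min < v[j + 1]:
            mid = i + (j - i) // 2
            minima.append(float(x[mid]))
    return minima
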