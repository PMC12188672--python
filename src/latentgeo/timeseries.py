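"""Concentration time series: parsing, FMM cubic splines, error resampling.

A measured node signal is a short trajectory of concentrations (arbitrary
units) on a coarse time grid in hours, optionally with a per-point error
half-width (e.g. the standard deviation across biological replicates).
Before information-flow estimation the trajectories are densified with the
cubic spline of Forsythe, Malcolm and Moler (FMM): a C2-continuous
interpolant whose end conditions are taken from the exact cubic through the
four boundary knots at each end, so the spline reproduces cubic polynomials
exactly and passes through every measured point.  Error half-widths are
interpolated with the same spline.  Uncertainty on downstream estimates is
propagated by resampling whole curves uniformly and independently per grid
point inside the error band.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PPoly

from .exceptions import (
    InsufficientDataError,
    ParseError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeries",
    "TimeSeriesSet",
    "SplineCurve",
    "read_timeseries",
    "write_timeseries",
    "fmm_spline",
    "sample_within_errors",
]


@dataclass
class TimeSeries:
    """A labeled concentration trajectory with optional error half-widths."""

    label: str
    times: np.ndarray
    values: np.ndarray
    errors: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
        if self.times.ndim != 1 or self.values.shape != self.times.shape:
            raise ValidationError(
                f"series '{self.label}': times and values must be 1-D arrays "
                f"of equal length"
            )
        if self.errors is not None and self.errors.shape != self.times.shape:
            raise ValidationError(
                f"series '{self.label}': errors length does not match times"
            )
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError(
                f"series '{self.label}': times must be strictly increasing"
            )
        if np.any(~np.isfinite(self.times)) or np.any(~np.isfinite(self.values)):
            raise ValidationError(f"series '{self.label}': non-finite entries")
        if self.errors is not None and np.any(self.errors < 0):
            raise ValidationError(f"series '{self.label}': negative error half-width")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class TimeSeriesSet:
    """A collection of series sharing one time grid, with unique labels."""

    series: list[TimeSeries]

    def __post_init__(self):
        labels = [s.label for s in self.series]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate series labels")

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.series]

    @property
    def grid_size(self) -> int:
        return len(self.series[0]) if self.series else 0

    def __getitem__(self, label: str) -> TimeSeries:
        for s in self.series:
            if s.label == label:
                return s
        raise KeyError(label)

    def __iter__(self):
        return iter(self.series)

    def __len__(self) -> int:
        return len(self.series)

    def has_errors(self) -> bool:
        return all(s.errors is not None for s in self.series)


@dataclass
class SplineCurve:
    """A densified trajectory: original knots plus the interpolated grid."""

    label: str
    knot_times: np.ndarray
    knot_values: np.ndarray
    dense_times: np.ndarray
    dense_values: np.ndarray
    dense_errors: np.ndarray | None = None
    _ppoly: PPoly | None = field(default=None, repr=False, compare=False)

    def to_timeseries(self) -> TimeSeries:
        return TimeSeries(
            self.label, self.dense_times, self.dense_values, self.dense_errors
        )


def _sniff_delimiter(path: str) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_timeseries(
    path: str,
    time_column: str = "time",
    value_columns: list[str] | None = None,
    error_suffix: str | None = "_sd",
) -> TimeSeriesSet:
    """Read a delimited text file into a :class:`TimeSeriesSet`.

    One row per timepoint; a header row is required.  ``value_columns``
    defaults to every non-time column that is not an error column.  A column
    named ``<species><error_suffix>`` is attached as the error half-width of
    ``<species>``.

    Raises
    ------
    SchemaError
        if a declared column is absent.
    ValidationError
        if times are duplicated (the file is sorted by time first).
    ParseError
        if a cell is non-numeric, reporting the 0-based data row index.
    """
    sep = _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    raw.columns = [c.strip() for c in raw.columns]
    if time_column not in raw.columns:
        raise SchemaError(f"time column '{time_column}' not found in {path}")

    suffix = error_suffix or ""
    if value_columns is None:
        value_columns = [
            c
            for c in raw.columns
            if c != time_column and not (suffix and c.endswith(suffix))
        ]
    missing = [c for c in value_columns if c not in raw.columns]
    if missing:
        raise SchemaError(f"value column(s) {missing} not found in {path}")

    def _numeric(col: str) -> np.ndarray:
        out = np.empty(len(raw), dtype=float)
        for i, cell in enumerate(raw[col]):
            try:
                out[i] = float(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"non-numeric value {cell!r} in column '{col}', row {i}"
                ) from None
        return out

    times = _numeric(time_column)
    order = np.argsort(times, kind="stable")
    times = times[order]
    if np.any(np.diff(times) <= 0):
        raise ValidationError(f"duplicate or non-increasing times in {path}")

    series = []
    for col in value_columns:
        values = _numeric(col)[order]
        errors = None
        err_col = f"{col}{suffix}" if suffix else None
        if err_col and err_col in raw.columns:
            errors = _numeric(err_col)[order]
        series.append(TimeSeries(col, times, values, errors))
    return TimeSeriesSet(series)


def write_timeseries(
    tss: TimeSeriesSet, path: str, time_column: str = "time", error_suffix: str = "_sd"
) -> None:
    """Write a shared-grid set back to delimited text (inverse of the reader)."""
    data = {time_column: tss.series[0].times}
    for s in tss:
        data[s.label] = s.values
        if s.errors is not None:
            data[f"{s.label}{error_suffix}"] = s.errors
    pd.DataFrame(data).to_csv(path, index=False)


def _fmm_coefficients(x: np.ndarray, y: np.ndarray) -> PPoly:
    """Cubic spline with Forsythe-Malcolm-Moler end conditions.

    The tridiagonal system is the classical one for the half second
    derivatives c_i = s''(x_i)/2; the end equations impose the third
    derivative of the exact cubic through the four boundary knots, computed
    from divided differences.  Requires at least four knots.
    """
    n = len(x)
    h = np.diff(x)  # interval widths
    delta = np.diff(y) / h  # first divided differences

    # Tridiagonal system A @ c = rhs, unknowns c_0..c_{n-1}.
    A = np.zeros((n, n))
    rhs = np.zeros(n)
    for i in range(1, n - 1):
        A[i, i - 1] = h[i - 1]
        A[i, i] = 2.0 * (h[i - 1] + h[i])
        A[i, i + 1] = h[i]
        rhs[i] = 3.0 * (delta[i] - delta[i - 1])

    # End conditions: s''' at each boundary equals the third derivative of
    # the exact cubic through the four end knots, 6 * f[x0,x1,x2,x3].  On
    # interval i the spline has s''' = 6 d_i = 2 (c_{i+1} - c_i) / h_i, so
    # the equation reads (c_1 - c_0) = 3 * divdiff * h_0 (and mirrored).
    dd3_left = _third_divdiff(x[:4], y[:4])
    dd3_right = _third_divdiff(x[-4:], y[-4:])
    A[0, 0] = -1.0
    A[0, 1] = 1.0
    rhs[0] = 3.0 * dd3_left * h[0]
    A[-1, -2] = -1.0
    A[-1, -1] = 1.0
    rhs[-1] = 3.0 * dd3_right * h[-1]

    c = np.linalg.solve(A, rhs)

    b = delta - h * (2.0 * c[:-1] + c[1:]) / 3.0
    d = (c[1:] - c[:-1]) / (3.0 * h)
    # PPoly coefficient layout: highest power first, per interval.
    coeffs = np.vstack([d, c[:-1], b, y[:-1]])
    return PPoly(coeffs, x, extrapolate=True)


def _third_divdiff(x: np.ndarray, y: np.ndarray) -> float:
    """Third-order divided difference f[x0,x1,x2,x3] over four points."""
    f = list(y.astype(float))
    for order in range(1, 4):
        f = [
            (f[i + 1] - f[i]) / (x[i + order] - x[i]) for i in range(len(f) - 1)
        ]
    return f[0]


def _dense_grid(knots: np.ndarray, n_out: int) -> np.ndarray:
    """Union of the knot times and uniform points, totalling ``n_out``.

    A uniform grid over [t_min, t_max] is laid down and, for every knot not
    already on it, the nearest uniform point is replaced by the knot so the
    total count stays at ``n_out`` and every knot is present exactly.
    """
    uniform = np.linspace(knots[0], knots[-1], n_out)
    grid = list(uniform)
    for t in knots:
        j = int(np.argmin(np.abs(np.asarray(grid) - t)))
        grid[j] = t
    grid = np.array(sorted(set(grid)))
    # Coincidences can shrink the set; pad with midpoints of the widest gaps.
    while len(grid) < n_out:
        gaps = np.diff(grid)
        j = int(np.argmax(gaps))
        grid = np.sort(np.append(grid, grid[j] + gaps[j] / 2.0))
    return grid


def fmm_spline(series: TimeSeries, n_out: int = 100) -> SplineCurve:
    """Interpolate a series to ``n_out`` points with the FMM cubic spline.

    The dense grid contains all knot times; error half-widths, when present,
    are interpolated with the same spline and clipped at zero.  Negative
    interpolated concentrations are clipped to zero with a logged warning
    (concentrations are physical quantities).

    Raises
    ------
    InsufficientDataError
        with fewer than four knots (the end conditions need four points).
    ValueError
        if ``n_out`` is smaller than the number of knots.
    """
    if len(series) < 4:
        raise InsufficientDataError(
            f"series '{series.label}': FMM spline needs at least 4 knots, "
            f"got {len(series)}"
        )
    if n_out < len(series):
        raise ValueError(f"n_out={n_out} is smaller than the number of knots")

    pp = _fmm_coefficients(series.times, series.values)
    grid = _dense_grid(series.times, n_out)
    dense = pp(grid)
    # Knot values exactly, immune to rounding in the evaluation.
    idx = np.searchsorted(grid, series.times)
    dense[idx] = series.values

    if np.any(dense < 0):
        logger.warning(
            "series '%s': %d interpolated concentrations were negative; "
            "clipped to 0",
            series.label,
            int((dense < 0).sum()),
        )
        dense = np.clip(dense, 0.0, None)

    dense_errors = None
    if series.errors is not None:
        ppe = _fmm_coefficients(series.times, series.errors)
        dense_errors = np.clip(ppe(grid), 0.0, None)
        dense_errors[idx] = series.errors

    return SplineCurve(
        label=series.label,
        knot_times=series.times.copy(),
        knot_values=series.values.copy(),
        dense_times=grid,
        dense_values=dense,
        dense_errors=dense_errors,
        _ppoly=pp,
    )


def sample_within_errors(
    curve: SplineCurve,
    n_rep: int = 100,
    seed: int | None = None,
    smooth: bool = False,
) -> list[TimeSeries]:
    """Draw ``n_rep`` replicate curves inside the error band.

    Each replicate is sampled uniformly and independently per dense grid
    point within ``[value - error, value + error]``; with ``smooth=True``
    offsets are drawn at the knots only and spline-interpolated in between
    before being clipped back into the band.  Deterministic given ``seed``.
    """
    if curve.dense_errors is None:
        raise ValidationError(
            f"curve '{curve.label}' has no error band to sample within"
        )
    rng = np.random.default_rng(seed)
    lo = curve.dense_values - curve.dense_errors
    hi = curve.dense_values + curve.dense_errors
    reps: list[TimeSeries] = []
    if not smooth:
        draws = rng.uniform(lo, hi, size=(n_rep, len(curve.dense_times)))
    else:
        idx = np.searchsorted(curve.dense_times, curve.knot_times)
        draws = np.empty((n_rep, len(curve.dense_times)))
        for k in range(n_rep):
            knot_vals = rng.uniform(lo[idx], hi[idx])
            if len(curve.knot_times) >= 4:
                sampled = _fmm_coefficients(curve.knot_times, knot_vals)(
                    curve.dense_times
                )
            else:
                sampled = np.interp(curve.dense_times, curve.knot_times, knot_vals)
            draws[k] = np.clip(sampled, lo, hi)
    for k in range(n_rep):
        reps.append(
            TimeSeries(f"{curve.label}#{k}", curve.dense_times, draws[k])
        )
    return reps
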