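"""Truncated-cone model: from directed TE pairs to an inter-node distance.

The bidirectional information flow between two nodes X and Y is pictured as
a truncated cone whose volume V is the total significant transfer entropy
(the sum of both directions; a direction whose surrogate p-value exceeds
the significance level alpha contributes zero) and whose base radii r_X,
r_Y measure each node's propensity to emit information — the mean absolute
time derivative of the chunked TE profile, in bits/hour.  When both TE
profiles are flat (linear trajectories carry no resolvable information
dynamics) the radii fall back to the absolute slope of the concentration
trajectory itself.  Inverting the truncated-cone volume formula
V = pi (r_X^2 + r_X r_Y + r_Y^2) h / 3 gives the height

    h = 3 V / (pi (r_X^2 + r_X r_Y + r_Y^2))

which serves as the distance between the two nodes: a large volume through
narrow bases means the interaction happens across a long information
distance.  Uncertainties Delta V, Delta r are standard errors of the mean
over error-resampled replicate curves and propagate to

    Delta h = 3 sqrt((V Dr_X)^2 (2 r_X + r_Y)^2 + (V Dr_Y)^2 (2 r_Y + r_X)^2
                     + (DV)^2) / (pi (r_X^2 + r_X r_Y + r_Y^2)^2)

This expression is dimensionally inhomogeneous (the (DV)^2 term is not
scaled by the base polynomial) but is kept verbatim as the model's printed
form; ``dh_variant="homogeneous"`` selects the first-order propagation
variant with (DV * q)^2 under the root, q being the base polynomial.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .exceptions import (
    DegenerateSeriesError,
    GeometryError,
    InsufficientDataError,
    ValidationError,
)
from .infoflow import (
    TEChunkSeries,
    _seed_sequence,
    chunked_te,
    discretize,
    estimate_te_pair,
    transfer_entropy,
)
from .timeseries import SplineCurve, TimeSeries, sample_within_errors

logger = logging.getLogger(__name__)

__all__ = [
    "ConeModel",
    "LinearFitParams",
    "DistanceMatrix",
    "ConeConfig",
    "interaction_volume",
    "radius_from_te_series",
    "radius_fallback",
    "cone_height",
    "cone_height_error",
    "estimate_pair",
    "assemble_distance_matrix",
]

#: mean |first difference| below this in both directions triggers the
#: linear-fit radius fallback
ZERO_DERIVATIVE_TOL = 1e-12


@dataclass
class LinearFitParams:
    """Least-squares line through a trajectory: value = slope * t + intercept."""

    slope: float
    intercept: float


@dataclass
class ConeModel:
    """One estimated pair: volume, radii, height and their uncertainties."""

    pair: tuple[str, str]
    V: float
    dV: float = 0.0
    r_x: float = 0.0
    dr_x: float = 0.0
    r_y: float = 0.0
    dr_y: float = 0.0
    h: float = 0.0
    dh: float = 0.0
    interacting: bool = False
    high_se: bool = False
    fallback_used: bool = False


@dataclass
class DistanceMatrix:
    """Symmetric matrix of cone heights with flags and companion errors."""

    labels: list[str]
    D: np.ndarray
    dD: np.ndarray | None = None
    no_interaction: np.ndarray = field(default=None)
    high_se: np.ndarray = field(default=None)

    def __post_init__(self):
        n = len(self.labels)
        self.D = np.asarray(self.D, dtype=float)
        if self.D.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(self.D, self.D.T):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(self.D) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(self.D < 0):
            raise ValidationError("distances must be non-negative")
        if self.no_interaction is None:
            self.no_interaction = np.zeros((n, n), dtype=bool)
        if self.high_se is None:
            self.high_se = np.zeros((n, n), dtype=bool)

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def entry(self, a: str, b: str) -> float:
        return float(self.D[self.index(a), self.index(b)])

    def augmented(self) -> "DistanceMatrix":
        """The error-augmented matrix D + Delta D (entrywise)."""
        if self.dD is None:
            raise ValidationError("no companion error matrix present")
        return DistanceMatrix(
            self.labels,
            self.D + self.dD,
            dD=None,
            no_interaction=self.no_interaction.copy(),
            high_se=self.high_se.copy(),
        )


@dataclass
class ConeConfig:
    """Estimator settings shared by every pair of one analysis."""

    n_bins: int = 3
    lag: int = 1
    order: int = 1
    chunk_size: int = 10
    n_surrogates: int = 100
    alpha: float = 0.10
    n_rep: int = 100
    seed: int | None = None
    derivative: str = "forward"  # or "central"
    dh_variant: str = "printed"  # or "homogeneous"


def interaction_volume(
    te_xy: float,
    te_yx: float,
    p_xy: float,
    p_yx: float,
    alpha: float = 0.10,
) -> tuple[float, bool]:
    """Interaction volume: total TE over the statistically significant directions.

    A direction with p > alpha is treated as null.  Returns ``(V,
    interacting)``; both directions null means no interaction (V = 0).
    """
    for p in (p_xy, p_yx):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    tx = te_xy if p_xy <= alpha else 0.0
    ty = te_yx if p_yx <= alpha else 0.0
    V = tx + ty
    return V, V > 0.0


def radius_from_te_series(chunks: TEChunkSeries, scheme: str = "forward") -> float:
    """Information-rate radius: mean absolute time derivative of chunked TE.

    The derivative is estimated by first differences of the chunk TE values
    over the chunk mid-times (``scheme="central"`` uses centered
    differences via ``numpy.gradient``).  A flat profile gives radius 0, in
    which case the caller should use :func:`radius_fallback`.
    """
    if len(chunks.te_values) < 2:
        raise InsufficientDataError("need at least 2 chunks for a derivative")
    t = chunks.chunk_mid_times
    v = chunks.te_values
    if scheme == "forward":
        deriv = np.diff(v) / np.diff(t)
    elif scheme == "central":
        deriv = np.gradient(v, t)
    else:
        raise ValueError(f"unknown derivative scheme {scheme!r}")
    return float(np.mean(np.abs(deriv)))


def radius_fallback(series: TimeSeries) -> float:
    """Fallback radius: absolute slope of the least-squares line value ~ t."""
    if len(series) < 2:
        raise InsufficientDataError("need at least 2 points for a line fit")
    fit = linear_fit(series)
    return abs(fit.slope)


def linear_fit(series: TimeSeries) -> LinearFitParams:
    slope, intercept = np.polyfit(series.times, series.values, 1)
    return LinearFitParams(float(slope), float(intercept))


def _base_polynomial(r_x: float, r_y: float) -> float:
    return r_x * r_x + r_x * r_y + r_y * r_y


def cone_height(V: float, r_x: float, r_y: float) -> float:
    """Truncated-cone height h = 3V / (pi (r_X^2 + r_X r_Y + r_Y^2))."""
    if V < 0:
        raise ValueError("volume must be non-negative")
    if r_x < 0 or r_y < 0:
        raise ValueError("radii must be non-negative")
    q = _base_polynomial(r_x, r_y)
    if q == 0.0:
        raise GeometryError("both radii are zero: cone height undefined")
    return 3.0 * V / (math.pi * q)


def cone_height_error(
    V: float,
    dV: float,
    r_x: float,
    dr_x: float,
    r_y: float,
    dr_y: float,
    variant: str = "printed",
) -> float:
    """Propagated height uncertainty Delta h.

    ``variant="printed"`` evaluates the model's stated expression verbatim;
    ``variant="homogeneous"`` scales the (Delta V)^2 term by the squared
    base polynomial, which is the dimensionally consistent first-order
    propagation of the height formula.
    """
    for name, val in [("V", V), ("dV", dV), ("dr_x", dr_x), ("dr_y", dr_y)]:
        if val < 0:
            raise ValueError(f"{name} must be non-negative")
    q = _base_polynomial(r_x, r_y)
    if q == 0.0:
        raise GeometryError("both radii are zero: cone height undefined")
    tx = (V * dr_x) ** 2 * (2 * r_x + r_y) ** 2
    ty = (V * dr_y) ** 2 * (2 * r_y + r_x) ** 2
    if variant == "printed":
        tv = dV**2
    elif variant == "homogeneous":
        tv = (dV * q) ** 2
    else:
        raise ValueError(f"unknown dh variant {variant!r}")
    return 3.0 * math.sqrt(tx + ty + tv) / (math.pi * q * q)


def _point_radii(
    x: TimeSeries, y: TimeSeries, cfg: ConeConfig
) -> tuple[float, float, bool]:
    """Radii for one pair from chunked TE, with the linear-fit fallback.

    The fallback applies per direction: a flat TE profile (mean absolute
    derivative below :data:`ZERO_DERIVATIVE_TOL`) carries no information
    dynamics, so that node's radius is taken from the rate of change of its
    own concentration trajectory instead.  A radius of exactly zero would
    otherwise make the cone height diverge whenever a single direction is
    flat.
    """
    ch_xy, ch_yx = chunked_te(
        x, y, chunk_size=cfg.chunk_size, lag=cfg.lag, order=cfg.order,
        n_bins=cfg.n_bins,
    )
    r_x = radius_from_te_series(ch_xy, scheme=cfg.derivative)
    r_y = radius_from_te_series(ch_yx, scheme=cfg.derivative)
    fallback = False
    if r_x < ZERO_DERIVATIVE_TOL:
        r_x = radius_fallback(x)
        fallback = True
    if r_y < ZERO_DERIVATIVE_TOL:
        r_y = radius_fallback(y)
        fallback = True
    return r_x, r_y, fallback


def estimate_pair(
    x: SplineCurve,
    y: SplineCurve,
    config: ConeConfig | None = None,
    x_replicates: list[TimeSeries] | None = None,
    y_replicates: list[TimeSeries] | None = None,
) -> ConeModel:
    """Full per-pair pipeline: TE, significance, volume, radii, height, errors.

    Significance gating (which directions count into V) is decided once on
    the mean curves; the error-resampled replicates re-estimate TE
    magnitudes and radii, and Delta V / Delta r are the standard errors of
    the mean over those replicate estimates.  Replicates are sampled from
    the curves' error bands when not supplied; without error bands the
    uncertainty stages are disabled and all Deltas are zero.
    """
    cfg = config or ConeConfig()
    xs, ys = x.to_timeseries(), y.to_timeseries()
    if not np.array_equal(x.dense_times, y.dense_times):
        raise ValidationError("curves must share one dense grid")

    te = estimate_te_pair(
        xs, ys, n_bins=cfg.n_bins, lag=cfg.lag, order=cfg.order,
        n_surrogates=cfg.n_surrogates, seed=cfg.seed,
    )
    V, interacting = interaction_volume(
        te.te_xy, te.te_yx, te.p_xy, te.p_yx, alpha=cfg.alpha
    )
    xy_significant = te.p_xy <= cfg.alpha
    yx_significant = te.p_yx <= cfg.alpha

    pair = (x.label, y.label)
    if not interacting:
        return ConeModel(pair=pair, V=0.0, interacting=False)

    r_x, r_y, fallback = _point_radii(xs, ys, cfg)

    dV = dr_x = dr_y = 0.0
    have_bands = x.dense_errors is not None and y.dense_errors is not None
    if x_replicates is None and have_bands:
        ss = _seed_sequence(cfg.seed).spawn(2)
        x_replicates = sample_within_errors(x, n_rep=cfg.n_rep, seed=ss[0])
        y_replicates = sample_within_errors(y, n_rep=cfg.n_rep, seed=ss[1])
    if x_replicates is not None and y_replicates is not None:
        n_rep = min(len(x_replicates), len(y_replicates))
        Vs = np.empty(n_rep)
        rxs = np.empty(n_rep)
        rys = np.empty(n_rep)
        for k in range(n_rep):
            xr, yr = x_replicates[k], y_replicates[k]
            try:
                dx = discretize(xr.values, cfg.n_bins)
                dy = discretize(yr.values, cfg.n_bins)
                t_yx = transfer_entropy(dx, dy, lag=cfg.lag, order=cfg.order)
                t_xy = transfer_entropy(dy, dx, lag=cfg.lag, order=cfg.order)
            except DegenerateSeriesError:
                t_yx = t_xy = 0.0
            Vs[k] = (t_xy if xy_significant else 0.0) + (
                t_yx if yx_significant else 0.0
            )
            rxs[k], rys[k], _ = _point_radii(xr, yr, cfg)
        if n_rep > 1:
            dV = float(np.std(Vs, ddof=1) / math.sqrt(n_rep))
            dr_x = float(np.std(rxs, ddof=1) / math.sqrt(n_rep))
            dr_y = float(np.std(rys, ddof=1) / math.sqrt(n_rep))

    h = cone_height(V, r_x, r_y)
    dh = cone_height_error(V, dV, r_x, dr_x, r_y, dr_y, variant=cfg.dh_variant)
    return ConeModel(
        pair=pair,
        V=V,
        dV=dV,
        r_x=r_x,
        dr_x=dr_x,
        r_y=r_y,
        dr_y=dr_y,
        h=h,
        dh=dh,
        interacting=True,
        high_se=dh > h,
        fallback_used=fallback,
    )


def assemble_distance_matrix(
    models: list[ConeModel], labels: list[str]
) -> DistanceMatrix:
    """Arrange per-pair heights into the symmetric distance matrix D = {h_ij}.

    Missing and non-interacting pairs enter as 0 with the no-interaction
    flag; high-SE flags are carried through.  At most one model per
    unordered pair.
    """
    n = len(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    D = np.zeros((n, n))
    dD = np.zeros((n, n))
    no_int = np.ones((n, n), dtype=bool)
    np.fill_diagonal(no_int, False)
    high = np.zeros((n, n), dtype=bool)
    seen: set[frozenset] = set()
    for m in models:
        a, b = m.pair
        if a not in index or b not in index:
            raise ValidationError(f"pair {m.pair} not covered by labels")
        key = frozenset((a, b))
        if key in seen:
            raise ValidationError(f"duplicate model for pair {m.pair}")
        seen.add(key)
        i, j = index[a], index[b]
        if m.interacting:
            D[i, j] = D[j, i] = m.h
            dD[i, j] = dD[j, i] = m.dh
            no_int[i, j] = no_int[j, i] = False
            high[i, j] = high[j, i] = m.high_se
    return DistanceMatrix(
        list(labels), D, dD=dD, no_interaction=no_int, high_se=high
    )


def all_unordered_pairs(labels: list[str]) -> list[tuple[str, str]]:
    """Every unordered node pair, in a stable order."""
    return list(combinations(labels, 2))
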