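"""Bottleneck detection by triangle thresholding of radii and distances.

A bottleneck, in this package's sense, is an interaction whose two nodes
have small information-rate radii yet sit far apart in the latent metric
space: the network's dynamics then waits on a low-propensity, long-range
link.  "Small" and "large" are separated automatically with the triangle
(Zack) method: on the value histogram, a line is drawn from the peak to the
farthest non-empty end, and the threshold is the bin whose histogram bar is
farthest from that line.

An interaction X–Y is flagged as a bottleneck when all three conditions
hold: r_X below the radius threshold, r_Y below the radius threshold, and
the embedded distance h* at or above the distance threshold.  By default
the radii of both pair members are pooled into one histogram (a single
radius threshold); per-variable thresholds and the inverted small-h*
condition are available as options.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cone import ConeModel
from .embedding import EmbeddingResult
from .exceptions import DegenerateHistogramError, InsufficientDataError

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdSet",
    "PairRecord",
    "BottleneckReport",
    "triangle_threshold",
    "classify_bottlenecks",
]


@dataclass
class ThresholdSet:
    """Thresholds used for one classification run."""

    r_threshold: float
    h_threshold: float
    histogram_bins: int = 256
    method: str = "triangle"
    r_threshold_y: float | None = None  # separate-threshold mode only


@dataclass
class PairRecord:
    """Per-pair classification outcome."""

    pair: tuple[str, str]
    r_x: float
    r_y: float
    h_star: float
    r_x_small: bool
    r_y_small: bool
    h_large: bool

    @property
    def is_bottleneck(self) -> bool:
        return self.r_x_small and self.r_y_small and self.h_large


@dataclass
class BottleneckReport:
    """Classification of every interacting pair, with the thresholds used."""

    records: list[PairRecord]
    thresholds: ThresholdSet | None
    geometry: str
    h_condition: str = "large"
    notes: dict = field(default_factory=dict)

    @property
    def bottlenecks(self) -> list[tuple[str, str]]:
        return [r.pair for r in self.records if r.is_bottleneck]

    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry,
            "h_condition": self.h_condition,
            "thresholds": None
            if self.thresholds is None
            else {
                "r_threshold": self.thresholds.r_threshold,
                "r_threshold_y": self.thresholds.r_threshold_y,
                "h_threshold": self.thresholds.h_threshold,
                "histogram_bins": self.thresholds.histogram_bins,
                "method": self.thresholds.method,
            },
            "pairs": [
                {
                    "pair": list(r.pair),
                    "r_x": r.r_x,
                    "r_y": r.r_y,
                    "h_star": r.h_star,
                    "r_x_small": r.r_x_small,
                    "r_y_small": r.r_y_small,
                    "h_large": r.h_large,
                    "is_bottleneck": r.is_bottleneck,
                }
                for r in self.records
            ],
            "bottlenecks": [list(p) for p in self.bottlenecks],
            "notes": self.notes,
        }


def triangle_threshold(values, n_bins: int = 256) -> float:
    """Triangle (Zack) threshold of a sample of values.

    The histogram spans [min, max] with ``n_bins`` bins.  A line runs from
    the top of the peak bin to the base of the farthest non-empty bin; the
    threshold is the midpoint of the bin maximizing the perpendicular
    distance between its bar and that line (ties resolved to the lower
    bin).  Deterministic; raises on constant input.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2 or np.all(values == values.flat[0]):
        raise DegenerateHistogramError(
            "need at least 2 distinct values for a histogram threshold"
        )
    if not np.all(np.isfinite(values)):
        raise DegenerateHistogramError("non-finite values in threshold sample")
    try:
        hist, edges = np.histogram(
            values, bins=n_bins, range=(values.min(), values.max())
        )
    except ValueError as err:  # value range too narrow for the bin count
        raise DegenerateHistogramError(str(err)) from None
    mids = 0.5 * (edges[:-1] + edges[1:])
    peak = int(np.argmax(hist))  # first maximal bin
    peak_height = float(hist[peak])
    nonzero = np.flatnonzero(hist)
    lo, hi = int(nonzero[0]), int(nonzero[-1])
    # Farthest non-empty end of the histogram from the peak.
    end = lo if peak - lo >= hi - peak else hi
    width = abs(peak - end)
    if width == 0:
        return float(mids[peak])
    # Perpendicular distance of each bar top to the peak-to-end line; the
    # normalization is shared so the argmax is the geometric one.
    norm = float(np.hypot(peak_height, width))
    lo_i, hi_i = min(peak, end), max(peak, end)
    best_d = -np.inf
    best_i = peak
    for i in range(lo_i, hi_i + 1):
        d = (peak_height * abs(i - end) - width * hist[i]) / norm
        if d > best_d:  # strict: ties keep the lower bin
            best_d = d
            best_i = i
    return float(mids[best_i])


def classify_bottlenecks(
    cones: list[ConeModel],
    embedding: EmbeddingResult,
    h_condition: str = "large",
    n_bins: int = 256,
    pooled_radii: bool = True,
    use_raw_h: bool = False,
) -> BottleneckReport:
    """Classify every interacting pair against triangle thresholds.

    Radius thresholds are computed over the pooled radii of the interacting
    pairs (``pooled_radii=False`` computes separate r_X and r_Y
    thresholds); the distance threshold over their embedded distances h* in
    the supplied geometry (``use_raw_h=True`` thresholds the raw cone
    heights instead).  Non-interacting pairs are excluded throughout.  When
    every value is identical no threshold exists and nothing is flagged.

    Raises
    ------
    InsufficientDataError
        with fewer than two interacting pairs.
    """
    if h_condition not in ("large", "small"):
        raise ValueError(f"unknown h_condition {h_condition!r}")
    interacting = [c for c in cones if c.interacting]
    if len(interacting) < 2:
        raise InsufficientDataError(
            f"only {len(interacting)} interacting pair(s); need at least 2"
        )
    label_index = {lab: i for i, lab in enumerate(embedding.labels)}
    for c in interacting:
        if c.pair[0] not in label_index or c.pair[1] not in label_index:
            raise InsufficientDataError(
                f"embedding does not cover pair {c.pair}"
            )

    def _hstar(c: ConeModel) -> float:
        if use_raw_h:
            return c.h
        i, j = label_index[c.pair[0]], label_index[c.pair[1]]
        return float(embedding.hstar[i, j])

    h_values = np.array([_hstar(c) for c in interacting])
    rx = np.array([c.r_x for c in interacting])
    ry = np.array([c.r_y for c in interacting])

    notes: dict = {}
    try:
        h_thr = triangle_threshold(h_values, n_bins)
        if pooled_radii:
            r_thr = triangle_threshold(np.concatenate([rx, ry]), n_bins)
            r_thr_y = None
        else:
            r_thr = triangle_threshold(rx, n_bins)
            r_thr_y = triangle_threshold(ry, n_bins)
    except DegenerateHistogramError as err:
        logger.warning("degenerate histogram, nothing flagged: %s", err)
        records = [
            PairRecord(c.pair, c.r_x, c.r_y, _hstar(c), False, False, False)
            for c in interacting
        ]
        return BottleneckReport(
            records, None, embedding.space, h_condition,
            notes={"degenerate": str(err)},
        )

    thresholds = ThresholdSet(
        r_threshold=r_thr, h_threshold=h_thr, histogram_bins=n_bins,
        r_threshold_y=r_thr_y,
    )
    records = []
    for c, hv in zip(interacting, h_values):
        ry_thr = r_thr_y if r_thr_y is not None else r_thr
        h_flag = hv >= h_thr if h_condition == "large" else hv < h_thr
        records.append(
            PairRecord(
                pair=c.pair,
                r_x=c.r_x,
                r_y=c.r_y,
                h_star=float(hv),
                r_x_small=c.r_x < r_thr,
                r_y_small=c.r_y < ry_thr,
                h_large=bool(h_flag),
            )
        )
    return BottleneckReport(records, thresholds, embedding.space, h_condition, notes)
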