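"""Thermal-niche limits from locality-temperature frequency curves.

The niche of a species is summarised by four temperatures,

    srz_lower <= stz_lower <= stz_upper <= srz_upper,

where the *species tolerance zone* (STZ, low physiological cost) is bounded
by the inflection points of the locality-count-versus-temperature curves and
the *species resistance zone* (SRZ, high cost, only some populations
persist) extends from the STZ out to the observed extremes.  The logic:
localities are plentiful at temperatures the species tolerates well, so the
count curve rises steeply inside the STZ; its flank inflections mark where
abundance starts to decay into the resistance zone.

Concretely, per species:

* ``srz_lower`` = coldest ``t_cold`` over localities; ``srz_upper`` =
  hottest ``t_hot``;
* ``stz_lower`` = inflection of the *rising* (left) flank of the cold-
  temperature histogram; ``stz_upper`` = inflection of the *falling*
  (right) flank of the hot-temperature histogram.

Inflections are located with the extremum distance estimator (EDE): on a
sigmoid-shaped segment, draw the chord joining the endpoints and average
the abscissae at which the curve deviates most above and most below it.
For an exact sigmoid the two extremal deviations straddle the inflection
symmetrically, so their midpoint estimates it without any model fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDistributionError,
    InsufficientDataError,
    NoInflectionError,
)


@dataclass
class FrequencyCurve:
    """Histogram of localities per temperature bin."""

    bin_centers: np.ndarray  # °C, strictly increasing, constant spacing
    counts: np.ndarray  # localities per bin, >= 0
    bin_width: float  # °C

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.counts = np.asarray(self.counts)
        if len(self.bin_centers) != len(self.counts):
            raise ValueError("bin_centers and counts differ in length")
        diffs = np.diff(self.bin_centers)
        if len(diffs) and not np.allclose(diffs, self.bin_width):
            raise ValueError("bin_centers must be evenly spaced by bin_width")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def left_edges(self) -> np.ndarray:
        return self.bin_centers - self.bin_width / 2.0

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def smoothed(self, window: int = 3) -> "FrequencyCurve":
        """Centred moving-average smoothing (edges use shrunken windows)."""
        if window < 1 or window % 2 == 0:
            raise ValueError("window must be a positive odd integer")
        half = window // 2
        sm = np.array(
            [
                self.counts[max(0, i - half) : i + half + 1].mean()
                for i in range(len(self.counts))
            ]
        )
        return FrequencyCurve(self.bin_centers.copy(), sm, self.bin_width)


@dataclass(frozen=True)
class ThermalNiche:
    """The four niche limits plus breadth, all in °C."""

    srz_lower: float
    stz_lower: float
    stz_upper: float
    srz_upper: float

    def __post_init__(self) -> None:
        if not (self.srz_lower <= self.stz_lower <= self.stz_upper <= self.srz_upper):
            raise ValueError(
                "niche limits must satisfy srz_lower <= stz_lower <= stz_upper <= srz_upper; got "
                f"({self.srz_lower}, {self.stz_lower}, {self.stz_upper}, {self.srz_upper})"
            )

    @property
    def breadth(self) -> float:
        return self.srz_upper - self.srz_lower


def build_frequency_curve(values: Sequence[float], bin_width: float = 1.0) -> FrequencyCurve:
    """Histogram with bins anchored at ``floor(min/bin_width) * bin_width``.

    Interior empty bins are retained; the total count equals ``len(values)``.
    Requires at least two distinct values.
    """
    vals = np.asarray(values, dtype=float)
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if vals.size < 2 or np.unique(vals).size < 2:
        raise DegenerateDistributionError("need at least 2 distinct temperature values")
    lo = np.floor(vals.min() / bin_width) * bin_width
    n_bins = int(np.floor((vals.max() - lo) / bin_width)) + 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    centers = edges[:-1] + bin_width / 2.0
    return FrequencyCurve(bin_centers=centers, counts=counts, bin_width=bin_width)


def ede_inflection(x: Sequence[float], y: Sequence[float]) -> float:
    """Extremum distance estimator of the inflection of a sigmoid segment.

    With chord L through ``(x[0], y[0])`` and ``(x[-1], y[-1])`` and
    deviations ``d_i = y_i - L(x_i)``, returns the midpoint of the abscissae
    of ``max(d)`` and ``min(d)``; ties resolve to the smallest index.

    Raises :class:`NoInflectionError` when the deviations never change sign
    (the segment is entirely convex or concave) and
    :class:`InsufficientDataError` for fewer than 4 points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    if x.size < 4:
        raise InsufficientDataError("EDE needs at least 4 points")
    if not np.all(np.diff(x) > 0):
        raise ValueError("x must be strictly increasing")
    slope = (y[-1] - y[0]) / (x[-1] - x[0])
    d = y - (y[0] + slope * (x - x[0]))
    if d.max() <= 0 or d.min() >= 0:
        raise NoInflectionError("chord deviations do not change sign; no inflection")
    return float((x[int(np.argmax(d))] + x[int(np.argmin(d))]) / 2.0)


@dataclass
class NicheEstimateReport:
    """Diagnostics accompanying :func:`estimate_niche`."""

    clamped: bool = False
    notes: list[str] = field(default_factory=list)


def _flank_inflection(curve: FrequencyCurve, side: str) -> float:
    """Chord-deviation (EDE) inflection of one flank of a unimodal histogram.

    ``side='left'`` takes the rising flank from the leftmost bin to the
    mode; ``side='right'`` the falling flank from the mode to the rightmost
    bin. The first-encountered mode is used when counts tie.

    The flank chord joins two points that lie on the curve itself, so the
    deviations vanish at both ends by construction and a strict
    sign-crossing test is uninformative there: count noise routinely erases
    the (small) deviation lobe adjacent to the mode. The flank estimate
    therefore takes the extremal deviations over the flank *interior*,
    which equals the strict EDE whenever a genuine crossing exists and
    degrades gracefully (nearest-to-chord interior bin) when noise hides
    it.
    """
    mode = int(np.argmax(curve.counts))
    if side == "left":
        xs, ys = curve.bin_centers[: mode + 1], curve.counts[: mode + 1]
    elif side == "right":
        xs, ys = curve.bin_centers[mode:], curve.counts[mode:]
    else:  # pragma: no cover
        raise ValueError(side)
    if len(xs) < 4:
        raise InsufficientDataError(
            f"{side} flank spans only {len(xs)} bins; need >= 4 for inflection detection "
            "(try a smaller bin width)"
        )
    ys = ys.astype(float)
    slope = (ys[-1] - ys[0]) / (xs[-1] - xs[0])
    d = ys - (ys[0] + slope * (xs - xs[0]))
    interior_x, interior_d = xs[1:-1], d[1:-1]
    return float(
        (interior_x[int(np.argmax(interior_d))] + interior_x[int(np.argmin(interior_d))])
        / 2.0
    )


def estimate_niche(
    min_temps: Sequence[float],
    max_temps: Sequence[float],
    bin_width: float = 1.0,
    min_n: int = 15,
    smooth: bool = False,
    smooth_window: int = 3,
) -> tuple[ThermalNiche, NicheEstimateReport]:
    """Estimate the four niche limits of one species.

    Parameters
    ----------
    min_temps, max_temps:
        Per-locality coldest monthly minimum and minimum monthly maximum, °C
        (same localities, but treated as two independent samples).
    bin_width:
        Histogram resolution, °C. The default 1 °C matches the granularity
        of monthly climate-surface data.
    min_n:
        Refuse estimation below this sample size; flank inflections of a
        sparse histogram are dominated by sampling noise.
    smooth:
        Apply a centred moving average (window ``smooth_window``) to each
        histogram before locating inflections. Off by default.

    Returns the niche and a report noting whether STZ limits had to be
    clamped into the SRZ interval.
    """
    min_temps = np.asarray(min_temps, dtype=float)
    max_temps = np.asarray(max_temps, dtype=float)
    if len(min_temps) < min_n or len(max_temps) < min_n:
        raise InsufficientDataError(
            f"need at least {min_n} localities per axis; "
            f"got {len(min_temps)} / {len(max_temps)}"
        )
    srz_lower = float(min_temps.min())
    srz_upper = float(max_temps.max())

    cold_curve = build_frequency_curve(min_temps, bin_width)
    hot_curve = build_frequency_curve(max_temps, bin_width)
    if smooth:
        cold_curve = cold_curve.smoothed(smooth_window)
        hot_curve = hot_curve.smoothed(smooth_window)

    stz_lower = _flank_inflection(cold_curve, "left")
    stz_upper = _flank_inflection(hot_curve, "right")

    report = NicheEstimateReport()
    lo, hi = sorted((stz_lower, stz_upper))
    clamped_lo = min(max(lo, srz_lower), srz_upper)
    clamped_hi = min(max(hi, srz_lower), srz_upper)
    if (clamped_lo, clamped_hi) != (stz_lower, stz_upper):
        report.clamped = True
        report.notes.append(
            f"STZ limits ({stz_lower:.3f}, {stz_upper:.3f}) adjusted to "
            f"({clamped_lo:.3f}, {clamped_hi:.3f}) to satisfy the niche ordering"
        )
        warnings.warn(report.notes[-1], stacklevel=2)
    niche = ThermalNiche(
        srz_lower=srz_lower,
        stz_lower=clamped_lo,
        stz_upper=clamped_hi,
        srz_upper=srz_upper,
    )
    return niche, report


def niche_breadth(niche: ThermalNiche) -> float:
    """Total thermal breadth: ``srz_upper - srz_lower``, °C."""
    return niche.breadth


def niche_table(niches: Mapping[str, ThermalNiche], n: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Per-species table of limits and breadth (one row per species)."""
    rows = []
    for sp, nich in niches.items():
        rows.append(
            {
                "species": sp,
                "n": (n or {}).get(sp, pd.NA),
                "srz_lower": nich.srz_lower,
                "stz_lower": nich.stz_lower,
                "stz_upper": nich.stz_upper,
                "srz_upper": nich.srz_upper,
                "breadth": nich.breadth,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class NicheSummary:
    """Cross-species summary of a niche table."""

    n_species: int
    mean: dict[str, float]
    sd: dict[str, float | None]  # None when n_species < 2
    max_srz_upper: float
    max_srz_upper_species: str
    min_breadth: float
    min_breadth_species: str
    max_breadth: float
    max_breadth_species: str
    stz_lower_threshold: float
    n_stz_lower_below: int
    species_stz_lower_below: list[str]


_LIMIT_COLS = ("srz_lower", "stz_lower", "stz_upper", "srz_upper")


def summarize_niche_table(
    table: pd.DataFrame, stz_lower_threshold: float = 15.0
) -> NicheSummary:
    """Summary statistics over a per-species niche table.

    Expects the columns produced by :func:`niche_table` (``breadth`` is
    recomputed if absent). The count of species whose ``stz_lower`` lies
    strictly below ``stz_lower_threshold`` flags taxa whose tolerance zone
    reaches unusually cold temperatures.
    """
    if len(table) < 1:
        raise ValueError("empty niche table")
    df = table.copy()
    if "breadth" not in df.columns:
        df["breadth"] = df["srz_upper"] - df["srz_lower"]
    mean = {c: float(df[c].mean()) for c in _LIMIT_COLS + ("breadth",)}
    sd = {
        c: (float(df[c].std(ddof=1)) if len(df) > 1 else None)
        for c in _LIMIT_COLS + ("breadth",)
    }
    i_up = df["srz_upper"].idxmax()
    i_bmin = df["breadth"].idxmin()
    i_bmax = df["breadth"].idxmax()
    below = df[df["stz_lower"] < stz_lower_threshold]
    return NicheSummary(
        n_species=len(df),
        mean=mean,
        sd=sd,
        max_srz_upper=float(df.loc[i_up, "srz_upper"]),
        max_srz_upper_species=str(df.loc[i_up, "species"]),
        min_breadth=float(df.loc[i_bmin, "breadth"]),
        min_breadth_species=str(df.loc[i_bmin, "species"]),
        max_breadth=float(df.loc[i_bmax, "breadth"]),
        max_breadth_species=str(df.loc[i_bmax, "species"]),
        stz_lower_threshold=stz_lower_threshold,
        n_stz_lower_below=len(below),
        species_stz_lower_below=list(below["species"]),
    )
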