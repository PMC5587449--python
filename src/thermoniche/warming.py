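"""Exposure of localities to uniform warming, and breadth-impact regression.

A species' localities are classified on the hot axis of its niche: a
locality with hot-season proxy temperature ``t_hot`` is

* in the tolerance zone (STZ) when ``t_hot <= stz_upper``,
* in the resistance zone (SRZ) when ``stz_upper < t_hot <= srz_upper``,
* beyond the niche when ``t_hot > srz_upper``

(limits inclusive on the tolerant side).  Adding a uniform increment
``delta_t`` to every locality and re-classifying yields two exposure
percentages: localities pushed from tolerance into resistance, and
localities pushed beyond the upper resistance limit altogether.  Across
species, the severity of the second percentage can then be regressed on
niche breadth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegeneratePredictorError, EmptyInputError, InsufficientDataError
from .niche import ThermalNiche


@dataclass(frozen=True)
class WarmingImpact:
    """Locality reclassification under a +delta_t shift (percent of all localities)."""

    delta_t: float
    pct_stz_to_srz: float
    pct_beyond_srz: float
    n_localities: int

    def __post_init__(self) -> None:
        for pct in (self.pct_stz_to_srz, self.pct_beyond_srz):
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"percentage {pct} outside [0, 100]")


def _hot_values(profiles) -> np.ndarray:
    vals = np.array(
        [p.t_hot if hasattr(p, "t_hot") else float(p) for p in profiles], dtype=float
    )
    if vals.size == 0:
        raise EmptyInputError("no thermal profiles")
    return vals


def project_warming(
    profiles: Sequence, niche: ThermalNiche, delta_t: float = 1.0
) -> WarmingImpact:
    """Classify localities before and after a uniform +delta_t warming.

    ``profiles`` may be ThermalProfile objects or bare ``t_hot`` values.
    Both percentages are integer-count ratios over all localities:

    * ``pct_stz_to_srz`` — in-STZ before and in-SRZ (not beyond) after;
    * ``pct_beyond_srz`` — not beyond before, beyond ``srz_upper`` after.
    """
    if delta_t < 0:
        raise ValueError("delta_t must be >= 0")
    t_hot = _hot_values(profiles)
    shifted = t_hot + delta_t
    in_stz_before = t_hot <= niche.stz_upper
    beyond_before = t_hot > niche.srz_upper
    in_srz_after = (shifted > niche.stz_upper) & (shifted <= niche.srz_upper)
    beyond_after = shifted > niche.srz_upper
    n = t_hot.size
    stz_to_srz = int(np.sum(in_stz_before & in_srz_after))
    newly_beyond = int(np.sum(~beyond_before & beyond_after))
    return WarmingImpact(
        delta_t=delta_t,
        pct_stz_to_srz=100.0 * stz_to_srz / n,
        pct_beyond_srz=100.0 * newly_beyond / n,
        n_localities=n,
    )


def project_warming_grid(
    profiles: Sequence, niche: ThermalNiche, deltas: Sequence[float] = (1.0, 1.5, 2.8)
) -> list[WarmingImpact]:
    """Impacts over a grid of warming increments (default: the conservative
    1.0 °C plus the 1.5-2.8 °C end-of-century scenario span)."""
    return [project_warming(profiles, niche, d) for d in deltas]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def regress_impact_vs_breadth(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS of impact percentage on niche breadth; two-sided p for the slope.

    With a single predictor the slope's t-test and the regression F-test
    coincide, so ``p_value`` is both.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    if x.size < 3:
        raise InsufficientDataError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise DegeneratePredictorError("predictor is constant")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    if x.size < 3:
        raise InsufficientDataError("correlation needs at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegeneratePredictorError("constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
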