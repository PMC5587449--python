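"""Sample-size sufficiency diagnostics.

Occurrence counts vary over two orders of magnitude between species, and
niche limits estimated from a handful of localities are unreliable.  The
diagnostic here asks whether the *variance* of a species' temperature
sample has stabilised by the time all n localities are included: for each
subsample size m = 2..n the mean sample variance over random subsamples is
recorded, and a trailing-window rule flags the trajectory as stabilised
(or not) without a human looking at the plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, ParameterError


@dataclass
class VarianceTrajectory:
    """Mean sample variance as a function of subsample size m = 2..n."""

    m: np.ndarray  # subsample sizes, 2..n
    var_mean: np.ndarray  # mean sample variance (ddof=1) over replicates
    replicates: int
    seed: int | None

    def __post_init__(self) -> None:
        if len(self.m) != len(self.var_mean):
            raise ValueError("m and var_mean differ in length")


def variance_trajectory(
    values, replicates: int = 100, seed: int | None = None
) -> VarianceTrajectory:
    """Mean sample variance of random subsamples of every size 2..n.

    For each replicate a random permutation of the (sorted) values is
    drawn; its prefixes of length m are uniform random subsets, so running
    variances along each permutation give one variance per size in a single
    pass. Values are sorted before permuting so that the trajectory depends
    only on the multiset of values, not their input order, for a given seed.
    Subsampling is without replacement; m starts at 2 because the variance
    of a single point is undefined.
    """
    vals = np.sort(np.asarray(values, dtype=float))
    n = vals.size
    if n < 3:
        raise InsufficientDataError("need at least 3 values for a variance trajectory")
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    ms = np.arange(2, n + 1)
    acc = np.zeros(n - 1)
    for _ in range(replicates):
        perm = vals[rng.permutation(n)]
        csum = np.cumsum(perm)
        csum2 = np.cumsum(perm**2)
        m = np.arange(1, n + 1, dtype=float)
        # running sample variance of each prefix; guard tiny negatives from
        # cancellation before dividing by (m - 1)
        ss = np.maximum(csum2 - csum**2 / m, 0.0)
        acc += ss[1:] / (m[1:] - 1.0)
    return VarianceTrajectory(m=ms, var_mean=acc / replicates, replicates=replicates, seed=seed)


@dataclass
class StabilizationResult:
    stable: bool
    m_stable: int | None  # smallest m at which the rule fires, if any
    window: int
    tol: float


def stabilization_check(
    traj: VarianceTrajectory, window: int = 10, tol: float = 0.05
) -> StabilizationResult:
    """Trailing-window flatness rule for variance stabilisation.

    The trajectory is declared stable at the smallest m for which the
    relative range of ``var_mean`` over the last ``window`` size increments
    (the window+1 values at sizes m-window..m) falls below ``tol``; the
    relative range is (max - min) / mean over the window, taken as 0 when
    the window is exactly constant.
    """
    if window < 2:
        raise ParameterError("window must be >= 2")
    if window >= len(traj.var_mean):
        raise ParameterError(
            f"window {window} must be smaller than trajectory length {len(traj.var_mean)}"
        )
    v = traj.var_mean
    for i in range(window, len(v)):
        w = v[i - window : i + 1]
        rng_w = w.max() - w.min()
        if rng_w == 0.0:
            rel = 0.0
        elif w.mean() == 0.0:
            rel = np.inf
        else:
            rel = rng_w / w.mean()
        if rel < tol:
            return StabilizationResult(True, int(traj.m[i]), window, tol)
    return StabilizationResult(False, None, window, tol)
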