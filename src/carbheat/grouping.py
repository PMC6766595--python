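"""Group-level generalization of per-food global intervals.

The per-food global intervals of one food group (fruits, vegetables or
cereals) are treated as a length measure on the kcal/g axis: the measure of
a set is the summed overlap of the intervals with it, and the total mass is
the arithmetic sum of the interval lengths. A group is then summarized by a
"center ± p%" expression chosen so that each tail beyond the expression
excludes less than a small fraction (2.5% by default) of the total interval
length. The center is the midpoint of the 2.5%/97.5% quantiles of the
cumulative length function and p is the smallest integer percentage whose
band keeps both tail exclusions under the cap. Finally the expression is
compared against the classical Atwater heat of combustion for vegetal
carbohydrates (4.2 kcal/g) to quantify how much that constant overestimates
the group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .exceptions import InsufficientDataError, ValidationError
from .global_interval import FoodGlobalResult

#: Atwater's classical heat of combustion for vegetable-source carbohydrate.
ATWATER_HC = 4.2

#: Default per-tail cap on excluded interval length.
DEFAULT_TAIL = 0.025


@dataclass(frozen=True)
class GroupSummary:
    """One food group's generalized heat-of-combustion expression."""

    group: str
    center: float                 # kcal/g, 2 decimals
    pct_half_width: int           # the p of "center +/- p%"
    pct_half_width_raw: float     # unrounded 100*(q_high-q_low)/(2*center)
    q_low: float                  # kcal/g, lower tail quantile
    q_high: float                 # kcal/g, upper tail quantile
    tail_low_fraction: float      # measure below center*(1-p), as proportion
    tail_high_fraction: float     # measure above center*(1+p)
    overestimation_min: int       # %, vs the Atwater constant
    overestimation_max: int
    n_intervals: int


def _validated(intervals: Sequence[tuple[float, float]]) -> np.ndarray:
    if len(intervals) == 0:
        raise ValidationError("no intervals given")
    arr = np.asarray(intervals, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("intervals must be (low, high) pairs")
    if np.any(arr[:, 0] > arr[:, 1]):
        raise ValidationError("every interval needs low <= high")
    return arr


def excluded_fraction(
    intervals: Sequence[tuple[float, float]],
    bound: float,
    side: str,
) -> float:
    """Fraction of total interval length beyond ``bound`` on one side.

    ``side='below'`` measures overlap with (-inf, bound), ``side='above'``
    with (bound, +inf); degenerate intervals carry zero length.
    """
    arr = _validated(intervals)
    lengths = arr[:, 1] - arr[:, 0]
    total = lengths.sum()
    if total <= 0:
        raise InsufficientDataError("total interval length is zero")
    if side == "below":
        overlap = np.clip(bound - arr[:, 0], 0.0, lengths)
    elif side == "above":
        overlap = np.clip(arr[:, 1] - bound, 0.0, lengths)
    else:
        raise ValidationError(f"side must be 'below' or 'above', got {side!r}")
    return float(overlap.sum() / total)


def _cumulative_length(arr: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Total overlap of the intervals with (-inf, x] for each x, vectorized."""
    lengths = arr[:, 1] - arr[:, 0]
    over = np.clip(xs[:, None] - arr[None, :, 0], 0.0, lengths[None, :])
    return over.sum(axis=1)


def length_measure_quantiles(
    intervals: Sequence[tuple[float, float]],
    tail: float = DEFAULT_TAIL,
) -> tuple[float, float]:
    """Tail quantiles of the cumulative interval-length function.

    Returns (q_low, q_high): the smallest value at which the length excluded
    below reaches ``tail`` of the total, and the largest at which the length
    excluded above reaches it. The cumulative function is piecewise linear
    with knots at interval endpoints, so each quantile is found by linear
    interpolation within the crossing segment; on a flat (gap) segment the
    edge nearest the tail is taken.
    """
    if not 0 < tail < 0.5:
        raise ValidationError(f"tail must lie in (0, 0.5), got {tail}")
    arr = _validated(intervals)
    lengths = arr[:, 1] - arr[:, 0]
    total = lengths.sum()
    if total <= 0:
        raise InsufficientDataError("total interval length is zero")
    xs = np.unique(arr.ravel())
    cum = _cumulative_length(arr, xs) / total

    def invert(target: float, from_above: bool) -> float:
        if from_above:
            # largest x with F(x) <= target
            j = int(np.searchsorted(cum, target, side="right")) - 1
            if j >= len(xs) - 1:
                return float(xs[-1])
            if cum[j + 1] == cum[j]:  # plateau at target: take its right edge
                return float(xs[j + 1])
            frac = (target - cum[j]) / (cum[j + 1] - cum[j])
            return float(xs[j] + frac * (xs[j + 1] - xs[j]))
        # smallest x with F(x) >= target
        i = int(np.searchsorted(cum, target, side="left"))
        if i == 0:
            return float(xs[0])
        frac = (target - cum[i - 1]) / (cum[i] - cum[i - 1])
        return float(xs[i - 1] + frac * (xs[i] - xs[i - 1]))

    return invert(tail, from_above=False), invert(1.0 - tail, from_above=True)


def atwater_bounds(center: float, pct: float, atwater: float = ATWATER_HC) -> tuple[int, int]:
    """Overestimation range (%) incurred by using the Atwater constant.

    The minimum compares Atwater against the band's upper edge
    center*(1 + p), the maximum against its lower edge center*(1 - p); both
    are rounded to the nearest integer percent.
    """
    if center <= 0:
        raise ValidationError("center must be positive")
    p = pct / 100.0
    omin = 100.0 * (atwater - center * (1 + p)) / atwater
    omax = 100.0 * (atwater - center * (1 - p)) / atwater
    return int(round(omin)), int(round(omax))


def generalized_expression(
    intervals: Sequence[tuple[float, float]],
    tail: float = DEFAULT_TAIL,
    group: str = "",
    atwater: float = ATWATER_HC,
) -> GroupSummary:
    """Build the "center ± p%" expression for one group of global intervals.

    The center is the midpoint of the tail quantiles, rounded to 2 decimals;
    p is the half-width in percent rounded to the nearest integer (the style
    the expressions are quoted in). The exact quantile band [q_low, q_high]
    excludes precisely ``tail`` per side by construction; rounding center
    and p can shift the realized exclusions by a fraction of a percent of
    the total length, so the achieved tail fractions are re-measured with
    :func:`excluded_fraction` and recorded on the summary.
    """
    q_low, q_high = length_measure_quantiles(intervals, tail)
    center = round((q_low + q_high) / 2.0, 2)
    pct_raw = 100.0 * (q_high - q_low) / (2.0 * center)
    pct = math.floor(pct_raw + 0.5)  # round half up
    p = pct / 100.0
    f_low = excluded_fraction(intervals, center * (1 - p), "below")
    f_high = excluded_fraction(intervals, center * (1 + p), "above")
    omin, omax = atwater_bounds(center, pct, atwater)
    return GroupSummary(
        group=group,
        center=center,
        pct_half_width=pct,
        pct_half_width_raw=pct_raw,
        q_low=q_low,
        q_high=q_high,
        tail_low_fraction=f_low,
        tail_high_fraction=f_high,
        overestimation_min=omin,
        overestimation_max=omax,
        n_intervals=len(intervals),
    )


def atwater_overestimation(summary: GroupSummary, atwater: float = ATWATER_HC) -> tuple[int, int]:
    """Overestimation range (%) for an already-built group summary."""
    return atwater_bounds(summary.center, summary.pct_half_width, atwater)


def generic_containment(
    results: Sequence[FoodGlobalResult],
    pct: float = 4.0,
) -> list[tuple[FoodGlobalResult, float]]:
    """Foods whose global interval escapes the generic band HCcinf ± pct%.

    Returns (food, excess) pairs, excess being the largest distance by which
    an interval endpoint falls outside [HCcinf*(1-p), HCcinf*(1+p)];
    boundary-touching intervals count as contained.
    """
    p = pct / 100.0
    offenders: list[tuple[FoodGlobalResult, float]] = []
    for r in results:
        lo_bound = r.hcc_inf * (1 - p)
        hi_bound = r.hcc_inf * (1 + p)
        excess = max(lo_bound - r.low, r.high - hi_bound)
        if excess > 0:
            offenders.append((r, excess))
    return offenders
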