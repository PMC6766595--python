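"""Food-level composition stage.

Turns per-carbohydrate (mean %, standard error, n) triples — the statistics
a composition database such as the USDA National Nutrient Database reports —
into two-sided normal tolerance intervals for the true composition, and
rescales compositions from a per-100-g-of-food basis to percentages of the
food's carbohydrate mass (the basis on which heats of combustion per g of
carbohydrate are propagated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

from scipy import stats

from .exceptions import DegenerateSampleError, InsufficientDataError, ValidationError
from .reference import FOOD_CARB_IDS

#: How composition-source nutrient names map onto the six reference classes.
#: Dietary fiber is treated as cellulose; database sugar masses are anhydrous,
#: hence maltose maps to the anhydrous reference.
DEFAULT_CARB_MAPPING: Mapping[str, str] = {
    "glucose": "glucose",
    "free_glucose": "glucose",
    "fructose": "fructose",
    "sucrose": "sucrose",
    "maltose": "maltose_anhydrous",
    "maltose_anhydrous": "maltose_anhydrous",
    "starch": "starch",
    "fiber": "cellulose",
    "dietary_fiber": "cellulose",
    "cellulose": "cellulose",
}

GROUPS = ("fruit", "vegetable", "cereal")


def resolve_carb_id(name: str, mapping: Optional[Mapping[str, str]] = None) -> str:
    """Map a composition-source nutrient name to a reference carb_id."""
    mapping = DEFAULT_CARB_MAPPING if mapping is None else mapping
    key = name.strip().lower().replace(" ", "_")
    try:
        return mapping[key]
    except KeyError:
        raise ValidationError(f"unknown carbohydrate name {name!r}") from None


@dataclass(frozen=True)
class CompositionRecord:
    """One food x carbohydrate composition datum.

    ``mean_pct`` is the mean composition (%), ``se`` its standard error (%)
    and ``n`` the number of underlying observations; ``se``/``n`` may be
    absent, which collapses the tolerance interval to the mean.
    """

    food_id: str
    group: str
    carb_id: str
    mean_pct: float
    se: Optional[float] = None
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 <= self.mean_pct <= 100:
            raise ValidationError(
                f"{self.food_id}/{self.carb_id}: mean_pct {self.mean_pct} outside [0, 100]"
            )
        if self.se is not None and self.se < 0:
            raise ValidationError(f"{self.food_id}/{self.carb_id}: negative se")
        if self.n is not None and self.n < 1:
            raise ValidationError(f"{self.food_id}/{self.carb_id}: n must be >= 1")
        if self.group not in GROUPS:
            raise ValidationError(f"unknown food group {self.group!r}")
        if self.carb_id not in FOOD_CARB_IDS:
            raise ValidationError(f"unknown carb_id {self.carb_id!r}")


@dataclass(frozen=True)
class CompositionInterval:
    """Tolerance interval [low, high] (%) for one carbohydrate's composition."""

    carb_id: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 <= self.low <= self.high:
            raise ValidationError(
                f"{self.carb_id}: need 0 <= low <= high, got ({self.low}, {self.high})"
            )

    @property
    def width(self) -> float:
        return self.high - self.low

    @property
    def degenerate(self) -> bool:
        return self.low == self.high


def tolerance_factor(n: int, coverage: float = 0.90, confidence: float = 0.90) -> float:
    """Two-sided normal tolerance factor k(n, coverage, confidence).

    Howe's approximation::

        k = z_{(1+coverage)/2} * sqrt( nu * (1 + 1/n) / chi2_{1-confidence, nu} )

    with nu = n - 1 and the chi-squared quantile taken at the lower tail.
    Converges to the central-coverage normal quantile as n grows (1.6449 for
    90% coverage) and agrees with the published two-sided tolerance tables
    to ~3 decimals for n >= 5.
    """
    if n < 2:
        raise InsufficientDataError("tolerance factor needs n >= 2")
    if not (0 < coverage < 1) or not (0 < confidence < 1):
        raise ValidationError("coverage and confidence must lie in (0, 1)")
    z = stats.norm.ppf((1 + coverage) / 2)
    nu = n - 1
    chi2 = stats.chi2.ppf(1 - confidence, nu)
    return z * math.sqrt(nu * (1 + 1 / n) / chi2)


def composition_interval(
    rec: CompositionRecord,
    coverage: float = 0.90,
    confidence: float = 0.90,
) -> CompositionInterval:
    """Tolerance interval for one composition record.

    With se and n available and se > 0, the sample standard deviation is
    recovered as s = se * sqrt(n) and the interval is mean -/+ k(n) * s,
    clamped to the physical range [0, 100]. A missing or zero se, or a
    missing n, collapses the interval to the mean (the degenerate rule used
    when a database lists a single determination).
    """
    if rec.se is None or rec.n is None or rec.se == 0:
        return CompositionInterval(rec.carb_id, rec.mean_pct, rec.mean_pct)
    if rec.n < 2:
        return CompositionInterval(rec.carb_id, rec.mean_pct, rec.mean_pct)
    s = rec.se * math.sqrt(rec.n)
    h = tolerance_factor(rec.n, coverage, confidence)
    low = max(0.0, rec.mean_pct - h * s)
    high = min(100.0, rec.mean_pct + h * s)
    return CompositionInterval(rec.carb_id, low, high)


def normalize_to_carb_basis(records: Sequence[CompositionRecord]) -> list[CompositionRecord]:
    """Rescale one food's compositions so the means sum to 100.

    Converts per-100-g-of-food carbohydrate masses into percentages of the
    food's carbohydrate mass; standard errors are scaled by the same factor.
    Records must all belong to the same food.
    """
    if not records:
        raise ValidationError("no composition records given")
    food_ids = {r.food_id for r in records}
    if len(food_ids) > 1:
        raise ValidationError(f"records span several foods: {sorted(food_ids)}")
    total = sum(r.mean_pct for r in records)
    if total <= 0:
        raise DegenerateSampleError(f"food {records[0].food_id!r} has an all-zero composition")
    factor = 100.0 / total
    return [
        replace(
            r,
            mean_pct=min(100.0, r.mean_pct * factor),  # guard float overshoot
            se=None if r.se is None else r.se * factor,
        )
        for r in records
    ]
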