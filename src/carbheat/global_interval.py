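"""Per-food uncertainty propagation by exhaustive endpoint enumeration.

A food's carbohydrate mass is a mixture of up to six carbohydrate classes,
each with a composition interval (%) and a heat-of-combustion overall
interval (kcal/g). Every combination of interval endpoints — 2^k composition
choices times 2^k heat choices for k classes present, 4,096 when all six are
— yields one candidate mixture heat 0.01 * sum(C_i * HC_i). The "global
interval" is the range of those candidates, HCcf their mean, and HCcinf the
simplified point value built from composition means and representative
heats. The enumeration is deliberately literal (a cartesian product); its
closed-form min/max/mean equivalents serve as cross-check oracles in the
test suite rather than as the implementation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

from .composition import CompositionInterval
from .exceptions import ValidationError
from .reference import CarbRef, CarbRefTable

#: Interval-length cutoff (kcal/g) above which a food's composition data are
#: considered too noisy to report.
MAX_INTERVAL_LENGTH = 0.32


@dataclass(frozen=True)
class FoodGlobalResult:
    """Per-food outcome of the endpoint enumeration (all heats in kcal/g)."""

    food_id: str
    group: str
    hcc_inf: float
    hcc_f: float
    low: float
    high: float
    n_enumerated: int

    @property
    def length(self) -> float:
        return self.high - self.low


def enumerate_candidates(
    comp: Mapping[str, CompositionInterval],
    heats: Mapping[str, CarbRef],
) -> list[float]:
    """All endpoint-combination heats for one food, kcal/g.

    ``comp`` and ``heats`` must be keyed by the same carb_ids. Carbohydrates
    with a degenerate zero composition interval contribute nothing and are
    dropped before enumerating, so the result has exactly 2^(2k) entries for
    the k carbohydrates actually present.
    """
    if set(comp) - set(heats):
        raise ValidationError(
            f"composition carbs {sorted(set(comp) - set(heats))} missing from heats"
        )
    present = [c for c in comp if not (comp[c].low == 0.0 and comp[c].high == 0.0)]
    if not present:
        return [0.0]
    comp_end = [(comp[c].low, comp[c].high) for c in present]
    heat_end = [(heats[c].low, heats[c].high) for c in present]
    comp_sets = list(itertools.product(*comp_end))
    heat_sets = list(itertools.product(*heat_end))
    return [
        0.01 * sum(c * h for c, h in zip(cs, hs))
        for cs in comp_sets
        for hs in heat_sets
    ]


def global_interval(candidates: Sequence[float]) -> tuple[float, float]:
    """(min, max) over the enumerated candidate heats."""
    if not candidates:
        raise ValidationError("no candidates to take extremes of")
    return (min(candidates), max(candidates))


def hcc_f(candidates: Sequence[float]) -> float:
    """Arithmetic mean of the enumerated candidate heats (HCcf)."""
    if not candidates:
        raise ValidationError("no candidates to average")
    return sum(candidates) / len(candidates)


def hcc_inf(means: Mapping[str, float], refs: CarbRefTable) -> float:
    """Simplified mixture heat 0.01 * sum(mean_i * representative_i) (HCcinf).

    ``means`` are composition means on the carbohydrate-mass basis (%).
    """
    return 0.01 * sum(pct * refs.lookup(c).representative for c, pct in means.items())


def food_global_result(
    food_id: str,
    group: str,
    comp: Mapping[str, CompositionInterval],
    means: Mapping[str, float],
    refs: CarbRefTable,
) -> FoodGlobalResult:
    """Run the full enumeration for one food and collect its summary."""
    candidates = enumerate_candidates(comp, refs)
    low, high = global_interval(candidates)
    return FoodGlobalResult(
        food_id=food_id,
        group=group,
        hcc_inf=hcc_inf(means, refs),
        hcc_f=hcc_f(candidates),
        low=low,
        high=high,
        n_enumerated=len(candidates),
    )


def length_filter(
    results: Sequence[FoodGlobalResult],
    max_length: float = MAX_INTERVAL_LENGTH,
) -> tuple[list[FoodGlobalResult], list[FoodGlobalResult]]:
    """Split foods into (kept, dropped) by global-interval length.

    Foods whose interval length strictly exceeds ``max_length`` are dropped;
    a length exactly at the limit is kept (with a 1e-9 guard so that a
    length that is 0.32 to printed precision is not dropped by float noise).
    """
    limit = max_length + 1e-9
    kept = [r for r in results if r.length <= limit]
    dropped = [r for r in results if r.length > limit]
    return kept, dropped
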