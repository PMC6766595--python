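"""Carbohydrate-level reference stage.

Bomb-calorimetry data reduction for the six carbohydrate classes found in
vegetal foods (glucose, fructose, sucrose, maltose, starch, cellulose):

* correction of measured heats of combustion for residual lipid/protein
  contamination of the assayed sample;
* conversion between hydrated and anhydrous crystal forms (needed for
  maltose, whose anhydrous form cannot be assayed directly);
* outlier screening (Grubbs' test and boxplot fences) used to decide
  whether a new measurement is statistically consistent with the body of
  bibliographic determinations;
* the packaged reference table of representative heats of combustion and
  their "overall intervals" (kcal per g), which merge bibliographic and
  new experimental data and drive every downstream food-level stage.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import DegenerateSampleError, InsufficientDataError, ValidationError

#: Heats of combustion of the contaminating macronutrients, kcal/g
#: (vegetable-source lipids and cereal proteins).
LIPID_HC = 9.3
PROTEIN_HC = 5.8

#: Maltose hydration constants: anhydrous molar mass (g/mol), bound water per
#: formula unit (g), and hydration heat (kcal per g of anhydrous maltose).
MALTOSE_MOLAR_MASS = 342.30
WATER_FORMULA_MASS = 18.00
MALTOSE_HYDRATION_HEAT = 0.03

#: All carbohydrate identifiers carried by the reference table.
CARB_IDS = (
    "glucose",
    "fructose",
    "sucrose",
    "maltose_monohydrate",
    "maltose_anhydrous",
    "starch",
    "cellulose",
)

#: The six classes composition databases report for foods (sugar masses are
#: anhydrous, so the monohydrate entry is not food-facing).
FOOD_CARB_IDS = (
    "glucose",
    "fructose",
    "sucrose",
    "maltose_anhydrous",
    "starch",
    "cellulose",
)


@dataclass(frozen=True)
class MeasurementSet:
    """One calorimetric replicate: measured heat plus sample composition.

    ``hc_exp`` is the heat of combustion of the whole sample (kcal/g);
    ``m_total`` the sample mass and ``m_lipid``/``m_protein`` the masses of
    the contaminating macronutrients it contains (g).
    """

    sample_id: str
    hc_exp: float
    m_total: float
    m_lipid: float = 0.0
    m_protein: float = 0.0

    def __post_init__(self) -> None:
        if self.m_total <= 0:
            raise ValidationError(f"m_total must be positive, got {self.m_total}")
        if self.m_lipid < 0 or self.m_protein < 0:
            raise ValidationError("contaminant masses must be non-negative")
        if self.hc_exp <= 0:
            raise ValidationError(f"hc_exp must be positive, got {self.hc_exp}")
        if self.m_lipid + self.m_protein >= self.m_total:
            raise DegenerateSampleError(
                "lipid + protein mass leaves no carbohydrate mass "
                f"({self.m_lipid} + {self.m_protein} >= {self.m_total})"
            )


@dataclass(frozen=True)
class HydrationSpec:
    """Crystal-form conversion constants for one substance.

    ``molar_mass_anhydrous`` (g/mol) and ``water_mass_per_formula`` (g per
    formula unit) fix the hydrated:anhydrous mass ratio; ``hydration_heat``
    is the heat difference per g of anhydrous substance (kcal/g).
    """

    molar_mass_anhydrous: float
    water_mass_per_formula: float = WATER_FORMULA_MASS
    hydration_heat: float = 0.0

    def __post_init__(self) -> None:
        if self.molar_mass_anhydrous <= 0:
            raise ValidationError("molar mass must be positive")
        if self.water_mass_per_formula < 0:
            raise ValidationError("water mass must be non-negative")


#: Default conversion spec for maltose monohydrate -> anhydrous maltose.
MALTOSE_SPEC = HydrationSpec(
    molar_mass_anhydrous=MALTOSE_MOLAR_MASS,
    water_mass_per_formula=WATER_FORMULA_MASS,
    hydration_heat=MALTOSE_HYDRATION_HEAT,
)


@dataclass(frozen=True)
class CarbRef:
    """Representative heat of combustion and overall interval, kcal/g."""

    carb_id: str
    representative: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low <= self.representative <= self.high):
            raise ValidationError(
                f"{self.carb_id}: need 0 < low <= representative <= high, "
                f"got ({self.low}, {self.representative}, {self.high})"
            )


class CarbRefTable(Mapping[str, CarbRef]):
    """Immutable mapping carb_id -> :class:`CarbRef` over the seven entries."""

    def __init__(self, refs: Sequence[CarbRef]):
        self._refs = {r.carb_id: r for r in refs}
        missing = set(CARB_IDS) - set(self._refs)
        if missing:
            raise ValidationError(f"reference table incomplete, missing {sorted(missing)}")

    def __getitem__(self, carb_id: str) -> CarbRef:
        return self._refs[carb_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self._refs)

    def __len__(self) -> int:
        return len(self._refs)

    def lookup(self, carb_id: str) -> CarbRef:
        """Alias for ``table[carb_id]`` with a clearer error."""
        try:
            return self._refs[carb_id]
        except KeyError:
            raise ValidationError(f"unknown carbohydrate id {carb_id!r}") from None


def correct_heat(
    m: MeasurementSet,
    lipid_hc: float = LIPID_HC,
    protein_hc: float = PROTEIN_HC,
) -> float:
    """Correct a measured heat for lipid/protein contamination.

    The total heat released by the sample, ``hc_exp * m_total``, is stripped
    of the contributions attributed to its lipid and protein masses and the
    remainder is referred to the carbohydrate mass::

        HC = (hc_exp * m_total - lipid_hc * m_lipid - protein_hc * m_protein)
             / (m_total - m_lipid - m_protein)

    Returns kcal per g of carbohydrate.
    """
    carb_mass = m.m_total - m.m_lipid - m.m_protein
    # MeasurementSet guarantees carb_mass > 0
    total_heat = m.hc_exp * m.m_total
    return (total_heat - lipid_hc * m.m_lipid - protein_hc * m.m_protein) / carb_mass


def hydrated_to_anhydrous(hc_hyd: float, spec: HydrationSpec) -> float:
    """Convert a heat of combustion from the hydrated to the anhydrous form.

    Each X g of anhydrous substance corresponds to X + w g of hydrated
    crystal (w = bound water per formula unit), so::

        HC_anh = hc_hyd * (X + w) / X + HH

    with HH the hydration heat per g of anhydrous substance.
    """
    if hc_hyd <= 0:
        raise ValidationError(f"hc_hyd must be positive, got {hc_hyd}")
    x = spec.molar_mass_anhydrous
    return hc_hyd * (x + spec.water_mass_per_formula) / x + spec.hydration_heat


def anhydrous_to_hydrated(hc_anh: float, spec: HydrationSpec) -> float:
    """Inverse of :func:`hydrated_to_anhydrous`."""
    x = spec.molar_mass_anhydrous
    return (hc_anh - spec.hydration_heat) * x / (x + spec.water_mass_per_formula)


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value for a single outlier among n points."""
    if n < 3:
        raise InsufficientDataError("Grubbs' test needs at least 3 values")
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_flag(values: Sequence[float], alpha: float = 0.05) -> Optional[int]:
    """Flag the single most extreme value if Grubbs' test rejects it.

    Computes G = max|x - mean| / s (s the sample standard deviation) and
    compares it with the two-sided critical value at ``alpha``. Returns the
    index of the flagged value, or ``None`` (including for zero spread).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("Grubbs' test needs at least 3 values")
    s = x.std(ddof=1)
    if s == 0:
        return None
    dev = np.abs(x - x.mean())
    idx = int(dev.argmax())
    g = dev[idx] / s
    return idx if g > grubbs_critical(x.size, alpha) else None


def boxplot_flags(values: Sequence[float], whisker: float = 1.5) -> set[int]:
    """Indices of values outside the Tukey fences Q1/Q3 -/+ whisker*IQR."""
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise InsufficientDataError("boxplot screening needs at least 4 values")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - whisker * iqr, q3 + whisker * iqr
    return {int(i) for i in np.flatnonzero((x < lo) | (x > hi))}


def is_consistent_with_reference(
    value: float,
    biblio_values: Sequence[float],
    alpha: float = 0.05,
) -> bool:
    """Is a new measurement a statistical non-outlier among reference data?

    The candidate is appended to the bibliographic determinations and both
    screens (Grubbs and boxplot) are run; it is consistent iff neither flags
    it. With too few points for a screen, that screen abstains.
    """
    if len(biblio_values) == 0:
        raise InsufficientDataError("need at least one bibliographic value")
    combined = list(biblio_values) + [value]
    idx = len(combined) - 1
    if len(combined) >= 3 and grubbs_flag(combined, alpha) == idx:
        return False
    if len(combined) >= 4 and idx in boxplot_flags(combined):
        return False
    return True


@lru_cache(maxsize=1)
def reference_table() -> CarbRefTable:
    """The packaged reference table of representative values and overall intervals.

    Values (kcal/g): glucose 3.74 [3.69, 3.78]; fructose 3.76 [3.70, 3.81];
    sucrose 3.95 [3.91, 4.00]; maltose monohydrate 3.76 [3.71, 3.81];
    anhydrous maltose 3.99 [3.93, 4.04]; starch 4.16 [4.07, 4.25];
    cellulose 4.15 [4.05, 4.25]. The anhydrous-maltose entry derives from the
    monohydrate one through :func:`hydrated_to_anhydrous`.
    """
    doc = json.loads(
        resources.files("carbheat.data").joinpath("reference_table.json").read_text()
    )
    return CarbRefTable([CarbRef(**row) for row in doc["carbohydrates"]])


def point_reference_table(base: Optional[CarbRefTable] = None) -> CarbRefTable:
    """A copy of the reference table with every interval collapsed to its
    representative value (low = representative = high).

    Useful when heat-of-combustion uncertainty should not contribute — e.g.
    parameter-recovery checks where only composition uncertainty is under
    study.
    """
    base = reference_table() if base is None else base
    return CarbRefTable(
        [
            CarbRef(r.carb_id, r.representative, r.representative, r.representative)
            for r in base.values()
        ]
    )
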