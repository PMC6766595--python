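"""Synthetic composition tables and calorimetry replicates with known truth.

The generator emulates the statistical structure of a food-composition
database: for each food, a true carbohydrate profile is drawn from a
group-specific Dirichlet distribution on the six-class simplex (fruits
sugar-heavy, cereals starch-dominated), scaled to percentages of the
carbohydrate mass. The reported mean composition is the sample mean of n
noisy determinations, the reported se is s/sqrt(n) with s proportional to
the mean, and se/n are occasionally missing — the degenerate single-value
case real tables exhibit. The true mixture heat 0.01 * sum(C_i * HC_i) is
emitted alongside, so pipeline stages can be checked for parameter recovery.

All randomness flows through one numpy Generator seeded from the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .composition import CompositionRecord
from .exceptions import ValidationError
from .reference import FOOD_CARB_IDS, LIPID_HC, PROTEIN_HC, MeasurementSet, reference_table

#: Dirichlet concentration parameters per group over the six classes
#: (glucose, fructose, sucrose, maltose_anhydrous, starch, cellulose).
#: Chosen so expected profiles qualitatively match published food tables:
#: fruit carbohydrate is mostly free sugars (mixture heat near 3.87 kcal/g),
#: vegetables carry more fiber and starch (~3.97), cereals are
#: starch-dominated (~4.14).
DEFAULT_CONCENTRATIONS: Mapping[str, tuple[float, ...]] = {
    "fruit": (24.0, 28.0, 20.0, 1.0, 7.0, 10.0),
    "vegetable": (18.0, 16.0, 12.0, 1.0, 18.0, 25.0),
    "cereal": (2.0, 1.0, 2.0, 2.0, 75.0, 8.0),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the composition-table generator.

    ``se_scale`` is the relative spread of a single determination (the
    emitted sample SD is mean * se_scale); ``n_obs_range`` bounds the
    per-entry number of determinations; ``missing_se_prob`` is the chance an
    entry loses its se/n (degenerate-interval case).
    """

    n_foods: Mapping[str, int] = field(
        default_factory=lambda: {"fruit": 30, "vegetable": 30, "cereal": 30}
    )
    concentrations: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CONCENTRATIONS)
    )
    se_scale: float = 0.005
    n_obs_range: tuple[int, int] = (3, 12)
    missing_se_prob: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.se_scale < 0:
            raise ValidationError("se_scale must be non-negative")
        if not 0 <= self.missing_se_prob <= 1:
            raise ValidationError("missing_se_prob must lie in [0, 1]")
        lo, hi = self.n_obs_range
        if lo < 2 or hi < lo:
            raise ValidationError("n_obs_range must satisfy 2 <= lo <= hi")
        for g, alpha in self.concentrations.items():
            if len(alpha) != len(FOOD_CARB_IDS) or any(a <= 0 for a in alpha):
                raise ValidationError(f"concentrations for {g!r} must be 6 positive values")
        for g, n in self.n_foods.items():
            if n < 0:
                raise ValidationError(f"n_foods[{g!r}] must be non-negative")
            if g not in self.concentrations:
                raise ValidationError(f"no concentration profile for group {g!r}")


def expected_group_hc(cfg: SyntheticConfig, group: str) -> float:
    """Analytic mixture heat 0.01 * sum(E[C_i] * HC_i) under the Dirichlet profile."""
    alpha = np.asarray(cfg.concentrations[group], dtype=float)
    frac = alpha / alpha.sum()
    refs = reference_table()
    reps = np.array([refs[c].representative for c in FOOD_CARB_IDS])
    return float(np.sum(frac * reps))


def simulate_composition_table(
    cfg: SyntheticConfig,
) -> tuple[list[CompositionRecord], dict[str, float]]:
    """Draw a composition table plus the per-food true mixture heats.

    Returns ``(records, truth)`` where ``truth`` maps food_id to the heat of
    combustion (kcal/g) implied by the food's true composition and the
    representative reference values. With ``se_scale = 0`` the observed
    means equal the true compositions exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    refs = reference_table()
    reps = np.array([refs[c].representative for c in FOOD_CARB_IDS])
    records: list[CompositionRecord] = []
    truth: dict[str, float] = {}
    for group in sorted(cfg.n_foods):
        alpha = np.asarray(cfg.concentrations[group], dtype=float)
        for k in range(cfg.n_foods[group]):
            food_id = f"{group}_{k:03d}"
            true_c = rng.dirichlet(alpha) * 100.0
            truth[food_id] = float(0.01 * np.sum(true_c * reps))
            n_obs = rng.integers(cfg.n_obs_range[0], cfg.n_obs_range[1] + 1, size=len(true_c))
            sd = true_c * cfg.se_scale
            # observed mean of n determinations: truth + N(0, sd/sqrt(n))
            obs = true_c + rng.standard_normal(len(true_c)) * sd / np.sqrt(n_obs)
            obs = np.clip(obs, 0.0, 100.0)
            missing = rng.random(len(true_c)) < cfg.missing_se_prob
            for i, carb in enumerate(FOOD_CARB_IDS):
                se: Optional[float] = None if missing[i] else float(sd[i] / np.sqrt(n_obs[i]))
                records.append(
                    CompositionRecord(
                        food_id=food_id,
                        group=group,
                        carb_id=carb,
                        mean_pct=float(obs[i]),
                        se=se,
                        n=None if missing[i] else int(n_obs[i]),
                    )
                )
    return records, truth


def simulate_measurements(
    true_hc: float,
    n: int,
    sd: float,
    contamination: Optional[tuple[float, float, float]] = None,
    seed: int = 0,
) -> list[MeasurementSet]:
    """Replicate calorimetry measurements consistent with a known true heat.

    Each replicate's raw ``hc_exp`` is drawn around the value the
    contamination correction inverts back to ``true_hc``: for lipid/protein
    masses (m_l, m_p) in a sample of mass m_t,

        hc_exp = (true_hc * (m_t - m_l - m_p) + 9.3 * m_l + 5.8 * m_p) / m_t

    plus N(0, sd) noise. ``contamination`` is ``(m_lipid, m_protein,
    m_total)``; omitted means a pure sample of unit mass.
    """
    if n < 1:
        raise ValidationError("need n >= 1 replicates")
    if sd < 0:
        raise ValidationError("sd must be non-negative")
    if true_hc <= 0:
        raise ValidationError("true_hc must be positive")
    m_l, m_p, m_t = contamination if contamination is not None else (0.0, 0.0, 1.0)
    if m_l + m_p >= m_t:
        raise ValidationError("contamination leaves no carbohydrate mass")
    carb_mass = m_t - m_l - m_p
    center = (true_hc * carb_mass + LIPID_HC * m_l + PROTEIN_HC * m_p) / m_t
    rng = np.random.default_rng(seed)
    draws = center + rng.standard_normal(n) * sd
    return [
        MeasurementSet(
            sample_id=f"rep_{i:04d}",
            hc_exp=float(h),
            m_total=m_t,
            m_lipid=m_l,
            m_protein=m_p,
        )
        for i, h in enumerate(draws)
    ]
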