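"""End-to-end pipeline, file formats and reports.

Ties the stages together: read a composition table (one row per food x
carbohydrate), normalize each food to the carbohydrate-mass basis, build
tolerance intervals, enumerate endpoint combinations against the reference
heats, filter over-long global intervals, and summarize each food group by
its generalized "center ± p%" expression.

Composition CSV dialect: header ``food_id,group,carb_id,mean_pct,se,n``;
empty ``se``/``n`` cells mean "not available". Reports are written either
as CSV (kcal/g rounded to 2 decimals, the convention of the published
tables) or as full-precision JSON.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, TextIO, Union

import pandas as pd

from .composition import (
    CompositionRecord,
    composition_interval,
    normalize_to_carb_basis,
    resolve_carb_id,
)
from .exceptions import DegenerateSampleError, ValidationError
from .global_interval import (
    MAX_INTERVAL_LENGTH,
    FoodGlobalResult,
    food_global_result,
    length_filter,
)
from .grouping import ATWATER_HC, DEFAULT_TAIL, GroupSummary, generalized_expression
from .reference import CarbRefTable, reference_table

logger = logging.getLogger("carbheat")

COMPOSITION_COLUMNS = ("food_id", "group", "carb_id", "mean_pct", "se", "n")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunables of the end-to-end run.

    ``coverage``/``confidence`` parameterize the composition tolerance
    intervals; ``max_length`` (kcal/g) drops foods whose global interval is
    too long; ``tail`` caps the per-tail excluded length fraction of the
    group expression; ``atwater`` is the benchmark heat the groups are
    compared against; ``round_decimals`` applies to CSV report output only.
    """

    coverage: float = 0.90
    confidence: float = 0.90
    max_length: float = MAX_INTERVAL_LENGTH
    tail: float = DEFAULT_TAIL
    atwater: float = ATWATER_HC
    round_decimals: int = 2

    def __post_init__(self) -> None:
        for name in ("coverage", "confidence", "tail"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")
        if self.max_length <= 0 or self.atwater <= 0:
            raise ValidationError("max_length and atwater must be positive")


def read_composition_csv(path: Union[str, Path, TextIO]) -> list[CompositionRecord]:
    """Parse a composition table, reporting offending rows by line number."""
    origin = "<stream>" if hasattr(path, "read") else str(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValidationError(
            f"{origin}: empty file; expected header {','.join(COMPOSITION_COLUMNS)}"
        ) from None
    missing = [c for c in COMPOSITION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{origin}: missing required column(s) {missing}")
    records: list[CompositionRecord] = []
    errors: list[str] = []
    for pos, row in df.iterrows():
        line = int(pos) + 2  # header is line 1
        try:
            se = None if pd.isna(row["se"]) else float(row["se"])
            n = None if pd.isna(row["n"]) else int(row["n"])
            records.append(
                CompositionRecord(
                    food_id=str(row["food_id"]),
                    group=str(row["group"]).strip().lower(),
                    carb_id=resolve_carb_id(str(row["carb_id"])),
                    mean_pct=float(row["mean_pct"]),
                    se=se,
                    n=n,
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"{origin}:{line}: {exc}")
    if errors:
        raise ValidationError("malformed composition rows:\n" + "\n".join(errors))
    return records


def write_composition_csv(records: Sequence[CompositionRecord], path: Union[str, Path]) -> None:
    """Write records in the dialect :func:`read_composition_csv` accepts."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(COMPOSITION_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.food_id,
                    r.group,
                    r.carb_id,
                    repr(r.mean_pct),
                    "" if r.se is None else repr(r.se),
                    "" if r.n is None else r.n,
                ]
            )


@dataclass
class PipelineResult:
    """Everything one run produces."""

    foods: list[FoodGlobalResult]
    dropped: list[FoodGlobalResult]
    groups: dict[str, GroupSummary] = field(default_factory=dict)


def run_pipeline(
    records_or_path: Union[str, Path, Sequence[CompositionRecord]],
    config: Optional[PipelineConfig] = None,
    refs: Optional[CarbRefTable] = None,
) -> PipelineResult:
    """Composition records -> per-food global intervals -> group summaries.

    Foods whose global interval exceeds ``config.max_length`` are excluded
    from the group stage and reported in ``dropped`` (with a log line each);
    a group whose surviving intervals carry zero total length is skipped
    with a warning (its summary is omitted).
    """
    config = config or PipelineConfig()
    refs = refs or reference_table()
    if isinstance(records_or_path, (str, Path)):
        records = read_composition_csv(records_or_path)
    else:
        records = list(records_or_path)
    by_food: dict[str, list[CompositionRecord]] = {}
    for r in records:
        by_food.setdefault(r.food_id, []).append(r)

    results: list[FoodGlobalResult] = []
    for food_id, recs in by_food.items():
        groups = {r.group for r in recs}
        if len(groups) > 1:
            raise ValidationError(f"food {food_id!r} appears in several groups: {sorted(groups)}")
        try:
            normed = normalize_to_carb_basis(recs)
        except DegenerateSampleError as exc:
            logger.warning("skipping %s: %s", food_id, exc)
            continue
        comp = {
            r.carb_id: composition_interval(r, config.coverage, config.confidence)
            for r in normed
        }
        means = {r.carb_id: r.mean_pct for r in normed}
        results.append(food_global_result(food_id, groups.pop(), comp, means, refs))

    kept, dropped = length_filter(results, config.max_length)
    for r in dropped:
        logger.info(
            "dropping %s: global-interval length %.3f kcal/g exceeds %.2f",
            r.food_id, r.length, config.max_length,
        )

    summaries: dict[str, GroupSummary] = {}
    for group in sorted({r.group for r in kept}):
        intervals = [(r.low, r.high) for r in kept if r.group == group]
        if sum(h - l for l, h in intervals) <= 0:
            logger.warning("group %s: zero total interval length, skipping summary", group)
            continue
        summaries[group] = generalized_expression(
            intervals, tail=config.tail, group=group, atwater=config.atwater
        )
    return PipelineResult(foods=kept, dropped=dropped, groups=summaries)


def foods_to_frame(foods: Sequence[FoodGlobalResult]) -> pd.DataFrame:
    rows = [
        {
            "food_id": r.food_id,
            "group": r.group,
            "hcc_inf": r.hcc_inf,
            "hcc_f": r.hcc_f,
            "low": r.low,
            "high": r.high,
            "length": r.length,
            "n_enumerated": r.n_enumerated,
        }
        for r in foods
    ]
    columns = ["food_id", "group", "hcc_inf", "hcc_f", "low", "high", "length", "n_enumerated"]
    return pd.DataFrame(rows, columns=columns)


def write_report(
    result: PipelineResult,
    path: Union[str, Path],
    format: str = "json",
    round_decimals: int = 2,
) -> None:
    """Serialize a pipeline run.

    ``json`` keeps full precision (byte-identical across identical runs);
    ``csv`` writes the per-food table with kcal/g rounded to
    ``round_decimals``.
    """
    path = Path(path)
    if format == "csv":
        df = foods_to_frame(result.foods)
        for col in ("hcc_inf", "hcc_f", "low", "high", "length"):
            if col in df:
                df[col] = df[col].round(round_decimals)
        df.to_csv(path, index=False)
    elif format == "json":
        doc = {
            "schema_version": 1,
            "units": "kcal/g",
            "foods": foods_to_frame(result.foods).to_dict(orient="records"),
            "dropped": foods_to_frame(result.dropped).to_dict(orient="records"),
            "groups": {g: asdict(s) for g, s in sorted(result.groups.items())},
        }
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    else:
        raise ValidationError(f"unknown report format {format!r}")
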