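"""Packaged datasets: reference constants and the published food table.

The food table transcribes the reported per-food results for 68 vegetal
foods (31 fruits, 24 vegetables, 13 cereals): the simplified mixture heat
HCcinf, the enumeration mean HCcf, and the global-interval endpoints, all in
kcal/g. The underlying per-food composition statistics are not public, so
this table is the fixture the group-level stage consumes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

GROUPS = ("fruit", "vegetable", "cereal")


def load_published_food_table() -> pd.DataFrame:
    """The published per-food results as a DataFrame, in table order.

    Columns: group, food_no, food_desc, hcc_inf, hcc_f, low, high.
    """
    with resources.files("carbheat.data").joinpath("published_foods.csv").open() as fh:
        return pd.read_csv(fh)


def published_intervals(group: str) -> list[tuple[float, float]]:
    """The (low, high) global intervals for one food group, table order."""
    df = load_published_food_table()
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    sub = df[df["group"] == group]
    return list(zip(sub["low"].tolist(), sub["high"].tolist()))
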