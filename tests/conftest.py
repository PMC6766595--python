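import pytest

from carbheat.datasets import load_published_food_table, published_intervals
from carbheat.reference import reference_table


@pytest.fixture(scope="session")
def published_df():
    """The packaged per-food table (68 foods, kcal/g to 2 decimals)."""
    return load_published_food_table()


@pytest.fixture(scope="session")
def group_intervals():
    """group name -> list of (low, high) global intervals, table order."""
    return {g: published_intervals(g) for g in ("fruit", "vegetable", "cereal")}


@pytest.fixture(scope="session")
def refs():
    return reference_table()
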