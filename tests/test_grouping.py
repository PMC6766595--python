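"""Group-level generalization: the interval-length measure, its tail
quantiles, the "center ± p%" expressions, and the Atwater comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carbheat.exceptions import InsufficientDataError, ValidationError
from carbheat.global_interval import FoodGlobalResult
from carbheat.grouping import (
    atwater_bounds,
    atwater_overestimation,
    excluded_fraction,
    generalized_expression,
    generic_containment,
    length_measure_quantiles,
)


class TestExcludedFraction:
    def test_bound_below_all_intervals(self):
        assert excluded_fraction([(1.0, 2.0), (3.0, 4.0)], 0.5, "below") == 0.0

    def test_uniform_measure_on_single_interval(self):
        assert excluded_fraction([(0.0, 1.0)], 0.25, "below") == pytest.approx(0.25)
        assert excluded_fraction([(0.0, 1.0)], 0.25, "above") == pytest.approx(0.75)

    def test_degenerate_intervals_carry_no_length(self):
        frac = excluded_fraction([(0.0, 1.0), (0.2, 0.2)], 0.5, "below")
        assert frac == pytest.approx(0.5)

    def test_below_plus_above_at_most_one(self):
        ivs = [(0.0, 1.0), (0.5, 2.0), (3.0, 3.5)]
        for b in np.linspace(-0.5, 4.0, 19):
            s = excluded_fraction(ivs, b, "below") + excluded_fraction(ivs, b, "above")
            assert s <= 1.0 + 1e-12

    def test_monotone_in_bound(self):
        ivs = [(0.0, 1.0), (2.0, 4.0)]
        bs = np.linspace(-1.0, 5.0, 25)
        below = [excluded_fraction(ivs, b, "below") for b in bs]
        above = [excluded_fraction(ivs, b, "above") for b in bs]
        assert all(x <= y + 1e-12 for x, y in zip(below, below[1:]))
        assert all(x >= y - 1e-12 for x, y in zip(above, above[1:]))

    def test_fruits_band_edges_exclude_under_cap(self, group_intervals):
        ivs = group_intervals["fruit"]
        assert excluded_fraction(ivs, 3.88 * 0.96, "below") < 0.025
        assert excluded_fraction(ivs, 3.88 * 1.04, "above") < 0.025

    def test_errors(self):
        with pytest.raises(ValidationError):
            excluded_fraction([], 0.0, "below")
        with pytest.raises(ValidationError):
            excluded_fraction([(0.0, 1.0)], 0.5, "sideways")
        with pytest.raises(InsufficientDataError):
            excluded_fraction([(1.0, 1.0)], 0.5, "below")


def grid_oracle(intervals, tail, npts=100_000):
    """Brute-force discretization of the cumulative length function."""
    arr = np.asarray(intervals, dtype=float)
    xs = np.linspace(arr.min(), arr.max(), npts)
    lengths = arr[:, 1] - arr[:, 0]
    cum = np.clip(xs[:, None] - arr[None, :, 0], 0.0, lengths).sum(axis=1) / lengths.sum()
    q_low = xs[np.searchsorted(cum, tail, side="left")]
    q_high = xs[np.searchsorted(cum, 1.0 - tail, side="right") - 1]
    return float(q_low), float(q_high)


class TestLengthMeasureQuantiles:
    def test_uniform_single_interval(self):
        assert length_measure_quantiles([(0.0, 1.0)]) == (
            pytest.approx(0.025),
            pytest.approx(0.975),
        )

    def test_two_disjoint_unit_intervals(self):
        q_low, q_high = length_measure_quantiles([(0.0, 1.0), (2.0, 3.0)])
        assert q_low == pytest.approx(0.05)
        assert q_high == pytest.approx(2.95)

    def test_ordering_for_small_tails(self):
        for tail in (0.01, 0.025, 0.2, 0.49):
            q_low, q_high = length_measure_quantiles([(0.0, 1.0), (0.5, 1.5)], tail)
            assert q_low < q_high

    @given(
        raw=st.lists(
            st.tuples(st.floats(3.0, 4.5), st.floats(0.01, 0.6)),
            min_size=2,
            max_size=12,
        ),
        tail=st.sampled_from([0.01, 0.025, 0.1]),
    )
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_agrees_with_grid_oracle(self, raw, tail):
        intervals = [(lo, lo + w) for lo, w in raw]
        q = length_measure_quantiles(intervals, tail)
        o = grid_oracle(intervals, tail)
        assert q[0] == pytest.approx(o[0], abs=1e-3)
        assert q[1] == pytest.approx(o[1], abs=1e-3)

    def test_zero_total_length_rejected(self):
        with pytest.raises(InsufficientDataError):
            length_measure_quantiles([(1.0, 1.0)])

    def test_invalid_tail_rejected(self):
        with pytest.raises(ValidationError):
            length_measure_quantiles([(0.0, 1.0)], tail=0.6)


class TestGeneralizedExpression:
    @pytest.mark.parametrize(
        "group,center,pct",
        [("fruit", 3.88, 4), ("vegetable", 3.98, 5), ("cereal", 4.13, 3)],
    )
    def test_reproduces_published_expressions(self, group_intervals, group, center, pct):
        s = generalized_expression(group_intervals[group], group=group)
        assert s.center == pytest.approx(center)
        assert s.pct_half_width == pct
        assert s.n_intervals == len(group_intervals[group])

    @pytest.mark.parametrize("group", ["fruit", "vegetable", "cereal"])
    def test_self_consistent_tail_exclusions(self, group_intervals, group):
        # the exact quantile band excludes 2.5% per side by construction;
        # integer rounding of p may add a small excess (vegetables: 0.0268)
        s = generalized_expression(group_intervals[group])
        assert s.tail_low_fraction < 0.025 + 0.003
        assert s.tail_high_fraction < 0.025 + 0.003

    def test_single_interval_center_is_midpoint(self):
        s = generalized_expression([(3.6, 4.0)])
        assert s.center == pytest.approx(3.8)
        # quantile band is the interval shrunk by `tail` of its length per side
        assert s.q_low == pytest.approx(3.6 + 0.025 * 0.4)
        assert s.q_high == pytest.approx(4.0 - 0.025 * 0.4)

    def test_quantiles_bracket_center(self, group_intervals):
        for ivs in group_intervals.values():
            s = generalized_expression(ivs)
            assert s.q_low <= s.center <= s.q_high


class TestAtwaterOverestimation:
    def test_fruits_range(self, group_intervals):
        s = generalized_expression(group_intervals["fruit"], group="fruit")
        assert atwater_overestimation(s) == (4, 11)

    def test_vegetables_max(self, group_intervals):
        s = generalized_expression(group_intervals["vegetable"], group="vegetable")
        assert atwater_overestimation(s)[1] == 10

    def test_cereals_max(self, group_intervals):
        s = generalized_expression(group_intervals["cereal"], group="cereal")
        assert atwater_overestimation(s)[1] == 5

    def test_zero_when_atwater_at_band_top(self):
        # center*(1+p) == atwater -> no overestimation at the band's upper edge
        assert atwater_bounds(4.0, 5.0, atwater=4.2)[0] == 0

    def test_rejects_nonpositive_center(self):
        with pytest.raises(ValidationError):
            atwater_bounds(0.0, 4.0)


def food(food_id, hcc_inf, low, high):
    return FoodGlobalResult(food_id, "fruit", hcc_inf, hcc_inf, low, high, 4096)


class TestGenericContainment:
    def test_boundary_exactly_contained(self):
        f = food("edge", 4.00, 4.00 * 0.96, 4.00 * 1.04)
        assert generic_containment([f]) == []

    def test_excess_distance_reported(self):
        f = food("out", 4.00, 3.83, 4.17)
        offenders = generic_containment([f])
        assert len(offenders) == 1
        assert offenders[0][0].food_id == "out"
        assert offenders[0][1] == pytest.approx(0.01)

    def test_degenerate_interval_contained(self):
        f = food("pt", 4.00, 4.00, 4.00)
        assert generic_containment([f]) == []
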