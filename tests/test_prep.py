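"""Filters, DIM class assignments and Fleischmann lactation totals."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lactrr.prep import (
    apply_filters,
    fleischmann_total,
    lactation_totals,
    mt_period,
    mt_phenotypes,
    residual_class,
)


def brute_residual_class(d):
    bounds = [(7, 36), (37, 66), (67, 96), (97, 126), (127, 156),
              (157, 186), (187, 216), (217, 246), (247, 270)]
    for c, (lo, hi) in enumerate(bounds, start=1):
        if lo <= d <= hi:
            return c
    raise AssertionError


def brute_mt_period(d):
    bounds = [(7, 45), (46, 90), (91, 135), (136, 180), (181, 225), (226, 270)]
    for c, (lo, hi) in enumerate(bounds, start=1):
        if lo <= d <= hi:
            return c
    raise AssertionError


class TestClassAssignments:
    def test_residual_class_boundaries(self):
        assert residual_class(7) == 1
        assert residual_class(36) == 1
        assert residual_class(37) == 2
        assert residual_class(270) == 9

    def test_mt_period_boundaries(self):
        assert mt_period(45) == 1
        assert mt_period(46) == 2
        assert mt_period(226) == 6

    def test_total_on_dim_range_and_matches_brute_force(self):
        d = np.arange(7, 271)
        assert np.array_equal(residual_class(d),
                              [brute_residual_class(x) for x in d])
        assert np.array_equal(mt_period(d), [brute_mt_period(x) for x in d])

    def test_out_of_range_rejected(self):
        for f in (residual_class, mt_period):
            with pytest.raises(ValueError):
                f(6)
            with pytest.raises(ValueError):
                f(271)


class TestFleischmann:
    def test_single_testday_hand_value(self):
        # 3 kg at day 100 with a 250-day horizon: 3*100 + 3*150
        assert fleischmann_total([100], [3.0]) == pytest.approx(750.0)

    def test_two_testday_hand_value(self):
        # 2 kg @ 50 d and 4 kg @ 150 d: 100 + 300 + 400
        assert fleischmann_total([50, 150], [2.0, 4.0]) == pytest.approx(800.0)

    def test_zero_yields_give_zero_total(self):
        assert fleischmann_total([30, 90, 150], [0, 0, 0]) == 0.0

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            fleischmann_total([], [])
        with pytest.raises(ValueError):
            fleischmann_total([100, 50], [1, 1])
        with pytest.raises(ValueError):
            fleischmann_total([50], [-1.0])

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.floats(min_value=0.1, max_value=9.0),
           st.lists(st.integers(min_value=7, max_value=270), min_size=1,
                    max_size=8, unique=True))
    def test_constant_yield_equals_level_times_horizon(self, level, dims):
        dims = sorted(dims)
        total = fleischmann_total(dims, [level] * len(dims))
        assert total == pytest.approx(level * 250, rel=1e-12)

    def test_lactation_totals_per_goat(self):
        rec = pd.DataFrame({
            "goat": [1, 1, 2],
            "dim": [50, 150, 100],
            "y": [2.0, 4.0, 3.0],
        })
        out = lactation_totals(rec).set_index("goat")["total"]
        assert out[1] == pytest.approx(800.0)
        assert out[2] == pytest.approx(750.0)


class TestMtPhenotypes:
    def test_two_testdays_in_one_period_averaged(self):
        rec = pd.DataFrame({"goat": [1, 1], "dim": [100, 120],
                            "y": [3.0, 4.0]})
        out = mt_phenotypes(rec)
        assert len(out) == 1
        assert out.loc[0, "period"] == 3
        assert out.loc[0, "y"] == pytest.approx(3.5)


def _records(goats):
    rows = []
    for g, herd, sire, dam, dims, lact in goats:
        for d in dims:
            rows.append((g, herd, "2001-01-01", d, sire, dam, lact, 1.0))
    return pd.DataFrame(rows, columns=["goat", "herd", "test_date", "dim",
                                       "sire", "dam", "lactation_length", "y"])


class TestFilters:
    def test_goat_with_three_testdays_removed(self):
        base_dims = [20, 60, 100, 140]
        goats = [(i, 1, 100, 200 + i, base_dims, 250) for i in range(20)]
        goats.append((99, 1, 100, 299, [20, 60, 100], 250))
        rec, report = apply_filters(_records(goats))
        assert 99 not in set(rec["goat"])
        assert report.removed["few_testdays"] == 1
        assert set(rec["goat"]) == set(range(20))

    def test_lactation_length_rule(self):
        goats = [(i, 1, 100, 200 + i, [20, 60, 100, 140], 250)
                 for i in range(20)]
        goats.append((98, 1, 100, 298, [20, 60, 100, 140], 170))
        goats.append((97, 1, 100, 297, [20, 60, 100, 140], 360))
        rec, report = apply_filters(_records(goats))
        assert {97, 98}.isdisjoint(set(rec["goat"]))
        assert report.removed["lactation_length"] == 2

    def test_htd_with_exactly_four_animals_removed(self):
        # 20 goats in herd 1 (kept) + 4 goats with one extra record in herd 2
        goats = [(i, 1, 100, 200 + i, [20, 60, 100, 140], 250)
                 for i in range(20)]
        rec = _records(goats)
        extra = _records([(i, 2, 100, 200 + i, [90], 250) for i in range(4)])
        rec = pd.concat([rec, extra], ignore_index=True)
        out, report = apply_filters(rec)
        assert not ((out["herd"] == 2).any())
        assert report.removed["herd_testdate_groups"] >= 1

    def test_sire_needs_twenty_progeny(self):
        goats = [(i, 1, 100, 200 + i, [20, 60, 100, 140], 250)
                 for i in range(19)]  # only 19 daughters
        rec, report = apply_filters(_records(goats))
        assert len(rec) == 0
        assert report.removed["small_sire_family"] == 19

    def test_unknown_dam_removed(self):
        goats = [(i, 1, 100, 200 + i, [20, 60, 100, 140], 250)
                 for i in range(20)]
        goats.append((96, 1, 100, 0, [20, 60, 100, 140], 250))
        rec, report = apply_filters(_records(goats))
        assert 96 not in set(rec["goat"])
        assert report.removed["unknown_dam"] == 1

    def test_empty_input_empty_report(self):
        rec, report = apply_filters(_records([]))
        assert len(rec) == 0
        assert report.retained_goats == 0

    def test_fixpoint_rerun_removes_nothing(self, filterable_data):
        rec, report = apply_filters(filterable_data.records,
                                    filterable_data.pedigree)
        assert len(rec) > 0
        rec2, _ = apply_filters(rec, filterable_data.pedigree)
        assert len(rec2) == len(rec)
        n_removed = (report.input_records - report.retained_records)
        assert n_removed + report.retained_records == report.input_records

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            apply_filters(pd.DataFrame({"goat": [1]}))
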