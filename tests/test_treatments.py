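"""Exposure construction, regimen taxonomy and cumulative-risk estimation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _helpers import exposure_days_oracle, km_survival_oracle, make_rx
from ohcm_burden.treatments import (
    CHANGE_CATEGORIES,
    build_exposure_intervals,
    change_summary,
    classes_per_calendar_year,
    classify_transition,
    cumulative_risk_curve,
    derive_regimens,
    detect_first_change,
    initial_treatment,
    regimen_label,
)

ORIGIN = pd.Timestamp("2012-01-01")


def day(offset: int) -> pd.Timestamp:
    return ORIGIN + pd.Timedelta(days=offset)


class TestExposure:
    def test_single_script_spans_supply(self):
        out = build_exposure_intervals(make_rx([(0, day(10), "bisoprolol", 28)]))
        assert len(out) == 1
        assert out.loc[0, "start"] == day(10) and out.loc[0, "end"] == day(38)

    def test_gap_within_grace_merges(self):
        rx = make_rx([(0, day(10), "bisoprolol", 28),
                      (0, day(50), "bisoprolol", 28)])
        out = build_exposure_intervals(rx, grace_days=30)
        assert len(out) == 1
        assert out.loc[0, "end"] == day(78)

    def test_gap_beyond_grace_splits(self):
        rx = make_rx([(0, day(10), "bisoprolol", 28),
                      (0, day(70), "bisoprolol", 28)])
        out = build_exposure_intervals(rx, grace_days=30)
        assert len(out) == 2

    def test_zero_supply_dropped_negative_warns(self):
        rx = make_rx([(0, day(10), "bisoprolol", 0)])
        assert build_exposure_intervals(rx).empty
        with pytest.warns(UserWarning):
            out = build_exposure_intervals(make_rx([(0, day(1), "bisoprolol", -5)]))
        assert out.empty

    @given(st.lists(st.tuples(st.integers(0, 300), st.integers(1, 60)),
                    min_size=1, max_size=8))
    @settings(max_examples=80, deadline=None)
    def test_matches_day_set_oracle(self, scripts):
        rx = make_rx([(0, day(d), "bisoprolol", s) for d, s in scripts])
        out = build_exposure_intervals(rx, grace_days=30)
        got = set()
        for row in out.itertuples(index=False):
            got.update(range((row.start - ORIGIN).days, (row.end - ORIGIN).days))
        assert got == exposure_days_oracle(scripts, 30)

    def test_merge_order_independent(self):
        scripts = [(0, day(40), "bisoprolol", 28), (0, day(0), "bisoprolol", 28),
                   (0, day(90), "bisoprolol", 14)]
        a = build_exposure_intervals(make_rx(scripts))
        b = build_exposure_intervals(make_rx(list(reversed(scripts))))
        pd.testing.assert_frame_equal(a.reset_index(drop=True),
                                      b.reset_index(drop=True))


class TestRegimens:
    def test_monotherapy_label(self, drug_map):
        exp = build_exposure_intervals(make_rx([(0, day(0), "bisoprolol", 28)]))
        reg = derive_regimens(exp, drug_map)
        assert reg.loc[0, "classes"] == "BB"
        assert regimen_label(["bisoprolol"], drug_map) == "BB monotherapy"

    def test_same_class_dual_therapy(self, drug_map):
        rx = make_rx([(0, day(0), "atenolol", 28), (0, day(0), "bisoprolol", 28)])
        reg = derive_regimens(build_exposure_intervals(rx), drug_map)
        assert reg.loc[0, "classes"] == "BB+BB"
        assert regimen_label(["atenolol", "bisoprolol"], drug_map) \
            == "BB + BB dual therapy"

    def test_non_hcm_products_excluded(self, drug_map):
        rx = make_rx([(0, day(0), "atorvastatin", 28)])
        assert derive_regimens(build_exposure_intervals(rx), drug_map).empty

    def test_partition_at_product_boundaries(self, drug_map):
        rx = make_rx([(0, day(0), "bisoprolol", 56), (0, day(28), "verapamil", 56)])
        reg = derive_regimens(build_exposure_intervals(rx), drug_map)
        assert reg["classes"].tolist() == ["BB", "BB+CCB", "CCB"]
        # contiguous tiling of the exposed period
        assert (reg["start"].iloc[1:].to_numpy()
                == reg["end"].iloc[:-1].to_numpy()).all()

    def test_initial_treatment_labels(self, drug_map):
        exp = build_exposure_intervals(make_rx([(0, day(3), "verapamil", 28)]))
        assert initial_treatment(derive_regimens(exp, drug_map), drug_map) \
            == "CCB monotherapy"
        rx = make_rx([(0, day(3), "bisoprolol", 28), (0, day(3), "disopyramide", 28)])
        assert initial_treatment(derive_regimens(build_exposure_intervals(rx),
                                                 drug_map), drug_map) \
            == "BB + disopyramide dual therapy"
        assert initial_treatment(derive_regimens(
            build_exposure_intervals(make_rx([])), drug_map), drug_map) is None


PRODUCTS = {"atenolol": "BB", "bisoprolol": "BB", "metoprolol": "BB",
            "verapamil": "CCB", "diltiazem": "CCB", "disopyramide": "disopyramide"}


def _category_oracle(f: frozenset, t: frozenset) -> str:
    from collections import Counter
    if f < t:
        return "augment"
    if t < f:
        return "discontinuation"
    if Counter(PRODUCTS[p] for p in f) == Counter(PRODUCTS[p] for p in t):
        return "switch_within_class"
    if len(t) > len(f):
        return "switch_with_addition"
    return "switch_between_class"


class TestTaxonomy:
    def test_taxonomy_category_examples(self, drug_map):
        assert classify_transition({"bisoprolol"}, {"bisoprolol", "verapamil"},
                                   drug_map) == "augment"
        assert classify_transition({"bisoprolol", "verapamil"}, {"bisoprolol"},
                                   drug_map) == "discontinuation"
        assert classify_transition({"atenolol"}, {"bisoprolol"}, drug_map) \
            == "switch_within_class"
        assert classify_transition({"bisoprolol"}, {"verapamil"}, drug_map) \
            == "switch_between_class"
        assert classify_transition({"atenolol"}, {"bisoprolol", "verapamil"},
                                   drug_map) == "switch_with_addition"

    def test_exhaustive_and_mutually_exclusive(self, drug_map):
        """Every regimen pair up to three products maps to exactly one category."""
        sets = [frozenset(c) for n in (1, 2, 3)
                for c in itertools.combinations(PRODUCTS, n)]
        for f, t in itertools.product(sets, sets):
            if f == t:
                continue
            got = classify_transition(f, t, drug_map)
            assert got in CHANGE_CATEGORIES
            assert got == _category_oracle(f, t)

    def test_equal_sets_rejected(self, drug_map):
        with pytest.raises(ValueError):
            classify_transition({"atenolol"}, {"atenolol"}, drug_map)


class TestFirstChange:
    def _regimens(self, rx, drug_map):
        return derive_regimens(build_exposure_intervals(rx), drug_map)

    def test_augment_detected_at_change_date(self, drug_map):
        rx = make_rx([(0, day(d), "bisoprolol", 28) for d in range(0, 150, 28)]
                     + [(0, day(60), "verapamil", 28)])
        change = detect_first_change(self._regimens(rx, drug_map), day(400),
                                     drug_map)
        assert change["category"] == "augment" and change["date"] == day(60)

    def test_within_class_switch(self, drug_map):
        rx = make_rx([(0, day(0), "atenolol", 60), (0, day(60), "bisoprolol", 60)])
        change = detect_first_change(self._regimens(rx, drug_map), day(400),
                                     drug_map)
        assert change["category"] == "switch_within_class"

    def test_tail_gap_is_no_treatment(self, drug_map):
        rx = make_rx([(0, day(0), "bisoprolol", 28)])
        change = detect_first_change(self._regimens(rx, drug_map), day(400),
                                     drug_map)
        assert change["category"] == "no_treatment_gap"
        assert change["date"] == day(28)

    def test_short_tail_gap_is_no_change(self, drug_map):
        rx = make_rx([(0, day(0), "bisoprolol", 28)])
        assert detect_first_change(self._regimens(rx, drug_map), day(100),
                                   drug_map) is None

    def test_gap_then_same_regimen_resumed_is_no_change(self, drug_map):
        # 40-day unexposed gap (beyond grace, below the 90-day threshold)
        rx = make_rx([(0, day(0), "bisoprolol", 28),
                      (0, day(68), "bisoprolol", 28)])
        assert detect_first_change(self._regimens(rx, drug_map), day(120),
                                   drug_map) is None

    def test_gap_reaching_threshold_beats_later_change(self, drug_map):
        rx = make_rx([(0, day(0), "bisoprolol", 28),
                      (0, day(150), "verapamil", 28)])
        change = detect_first_change(self._regimens(rx, drug_map), day(400),
                                     drug_map)
        assert change["category"] == "no_treatment_gap"
        assert change["date"] == day(28)


class TestSummaryAndCurve:
    def test_change_summary_percentages(self):
        changes = pd.DataFrame({"category": ["augment"] * 3
                                + ["no_treatment_gap"] * 2})
        out = change_summary(changes, denominator=8).set_index("category")
        assert out.loc["augment", "pct"] == 37.5
        assert out.loc["any_change", "n"] == 5
        assert out.loc["any_change", "pct"] == 62.5

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            change_summary(pd.DataFrame({"category": []}), 0)

    def test_no_events_flat_zero(self):
        out = cumulative_risk_curve([5.0, 7.0], [False, False])
        assert (out["risk"] == 0.0).all()

    def test_hand_product_limit(self):
        # events at t=1,1; censored at 2,3 -> risk(1) = 1 - (1 - 2/4) = 0.5
        out = cumulative_risk_curve([1, 1, 2, 3], [True, True, False, False])
        at1 = out.loc[out["time"] == 1.0, "risk"].iloc[0]
        assert at1 == pytest.approx(0.5)

    @given(st.lists(st.tuples(st.integers(1, 10), st.booleans()),
                    min_size=1, max_size=20))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_product_limit(self, subjects):
        times = [t for t, _ in subjects]
        events = [e for _, e in subjects]
        out = cumulative_risk_curve(times, events)
        for t in sorted(set(times)):
            risk = out.loc[out["time"] <= t, "risk"].iloc[-1]
            assert risk == pytest.approx(1 - km_survival_oracle(times, events, t))
        # non-decreasing, within [0, 1]
        assert (np.diff(out["risk"]) >= -1e-12).all()
        assert out["risk"].between(-1e-12, 1 + 1e-12).all()

    def test_equals_ecdf_without_censoring(self):
        times = [1, 2, 2, 5, 9]
        out = cumulative_risk_curve(times, [True] * 5)
        for t in times:
            risk = out.loc[out["time"] <= t, "risk"].iloc[-1]
            assert risk == pytest.approx(np.mean([x <= t for x in times]))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            cumulative_risk_curve([-1.0], [True])


def test_classes_per_calendar_year(drug_map):
    rx = make_rx([(0, "2012-02-01", "bisoprolol", 28),
                  (0, "2012-07-01", "verapamil", 28),
                  (1, "2012-03-01", "bisoprolol", 28)])
    out = classes_per_calendar_year(rx, drug_map)
    assert out.loc[out["year"] == 2012, "mean_classes"].iloc[0] == 1.5
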