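"""Activity counting, unit/HRG costing and NYHA-stratified summaries."""

import numpy as np
import pandas as pd
import pytest

from ohcm_burden import resources
from ohcm_burden.costing import (
    cost_inpatient,
    cost_non_inpatient,
    cost_per_patient_year,
    count_activity,
    stratified_costs,
)

ORIGIN = pd.Timestamp("2012-01-01")


def day(offset: int) -> pd.Timestamp:
    return ORIGIN + pd.Timedelta(days=offset)


def _cohort(end_day=730):
    return pd.DataFrame({"patient_id": [0], "included": [True],
                         "followup_start": [day(0)], "followup_end": [day(end_day)]})


def _consults(rows):
    return pd.DataFrame([{"patient_id": p, "date": d, "type": t}
                         for p, d, t in rows],
                        columns=["patient_id", "date", "type"])


def _hospital(rows):
    return pd.DataFrame([{"patient_id": p, "admit_date": d, "discharge_date": d,
                          "type": t, "hrg_code": h} for p, d, t, h in rows],
                        columns=["patient_id", "admit_date", "discharge_date",
                                 "type", "hrg_code"])


_NO_PROC = pd.DataFrame(columns=["patient_id", "date", "concept"])


class TestCountActivity:
    def test_counts_in_followup(self):
        cons = _consults([(0, day(10), "gp"), (0, day(20), "gp"),
                          (0, day(30), "nurse")])
        hosp = _hospital([(0, day(40), "outpatient", "")] * 3)
        out = count_activity(cons, hosp, _NO_PROC, _cohort())
        assert (out["category"] == "gp").sum() == 2
        assert (out["category"] == "outpatient").sum() == 3

    def test_out_of_followup_dropped(self):
        cons = _consults([(0, day(800), "gp")])
        out = count_activity(cons, _hospital([]), _NO_PROC, _cohort())
        assert out.empty

    def test_unknown_category_warned_and_excluded(self):
        cons = _consults([(0, day(10), "home_visit")])
        with pytest.warns(UserWarning):
            out = count_activity(cons, _hospital([]), _NO_PROC, _cohort())
        assert out.empty

    def test_matches_filter_and_tally_oracle(self):
        rng = np.random.default_rng(0)
        cons = _consults([(0, day(int(d)), str(t)) for d, t in zip(
            rng.integers(0, 1000, 50),
            rng.choice(["gp", "nurse", "telephone"], 50))])
        out = count_activity(cons, _hospital([]), _NO_PROC, _cohort())
        expected = cons[(cons["date"] >= day(0)) & (cons["date"] < day(730))]
        assert len(out) == len(expected)
        for cat in ("gp", "nurse", "telephone"):
            assert (out["category"] == cat).sum() \
                == (expected["type"] == cat).sum()


class TestUnitCosting:
    def test_forced_arithmetic(self):
        cons = _consults([(0, day(d), "gp") for d in (1, 2, 3)])
        activity = count_activity(cons, _hospital([]), _NO_PROC, _cohort())
        unit_costs = pd.DataFrame({"category": ["gp"], "unit_cost": [150.0]})
        items = cost_non_inpatient(activity, unit_costs, inflation_factor=1.0)
        assert items["cost"].sum() == pytest.approx(450.0)
        items = cost_non_inpatient(activity, unit_costs, inflation_factor=1.02)
        assert items["cost"].sum() == pytest.approx(459.0)

    def test_zero_activity_zero_cost(self):
        activity = count_activity(_consults([]), _hospital([]), _NO_PROC, _cohort())
        items = cost_non_inpatient(activity, resources.default_unit_costs())
        assert items["cost"].sum() == 0.0

    def test_unpriced_category_raises(self):
        cons = _consults([(0, day(1), "gp")])
        activity = count_activity(cons, _hospital([]), _NO_PROC, _cohort())
        with pytest.raises(KeyError):
            cost_non_inpatient(activity, pd.DataFrame(
                {"category": ["nurse"], "unit_cost": [10.0]}))

    def test_out_of_hours_counted_but_not_costed(self):
        cons = _consults([(0, day(1), "out_of_hours")])
        activity = count_activity(cons, _hospital([]), _NO_PROC, _cohort())
        assert len(activity) == 1
        items = cost_non_inpatient(activity, resources.default_unit_costs())
        assert items.empty


class TestInpatientCosting:
    def test_hrg_lookup(self):
        hosp = _hospital([(0, day(5), "elective", "X1")])
        activity = count_activity(_consults([]), hosp, _NO_PROC, _cohort())
        hrg = pd.DataFrame({"hrg_code": ["X1"], "cost": [2000.0]})
        items = cost_inpatient(activity, hrg)
        assert items["cost"].sum() == pytest.approx(2000.0)

    def test_missing_hrg_policies(self):
        hosp = _hospital([(0, day(5), "elective", "NOPE")])
        activity = count_activity(_consults([]), hosp, _NO_PROC, _cohort())
        hrg = pd.DataFrame({"hrg_code": ["X1"], "cost": [2000.0]})
        with pytest.warns(UserWarning):
            items = cost_inpatient(activity, hrg, missing_hrg_policy="drop")
        assert items["cost"].sum() == 0.0
        with pytest.raises(KeyError):
            cost_inpatient(activity, hrg, missing_hrg_policy="error")

    def test_multi_episode_sum_matches_per_episode_oracle(self):
        rng = np.random.default_rng(3)
        codes = resources.default_hrg_costs()
        picks = rng.choice(codes["hrg_code"], 20)
        hosp = _hospital([(0, day(int(d)), "non_elective", h)
                          for d, h in zip(rng.integers(0, 700, 20), picks)])
        activity = count_activity(_consults([]), hosp, _NO_PROC, _cohort())
        items = cost_inpatient(activity, codes)
        price = codes.set_index("hrg_code")["cost"]
        assert items["cost"].sum() == pytest.approx(sum(price[h] for h in picks))


class TestStratified:
    def _intervals(self, rows):
        return pd.DataFrame([{"patient_id": p, "start": s, "end": e,
                              "nyha_class": c} for p, s, e, c in rows])

    def _items(self, rows):
        return pd.DataFrame([{"patient_id": p, "date": d, "component": comp,
                              "category": "x", "cost": c}
                             for p, d, comp, c in rows])

    def test_single_class_stratified_equals_overall(self):
        intervals = self._intervals([(0, day(0), day(365), 2)])
        items = self._items([(0, day(10), "primary_care", 100.0),
                             (0, day(20), "secondary_care", 400.0)])
        out = stratified_costs(items, intervals).set_index(["stratum", "component"])
        assert out.loc[(2, "total"), "total_cost"] \
            == out.loc[("overall", "total"), "total_cost"] == 500.0

    def test_additivity_and_component_sums(self):
        intervals = self._intervals([(0, day(0), day(100), 2),
                                     (0, day(100), day(200), 3)])
        items = self._items([(0, day(10), "primary_care", 100.0),
                             (0, day(150), "secondary_care", 400.0),
                             (0, day(199), "tests_procedures", 50.0)])
        out = stratified_costs(items, intervals).set_index(["stratum", "component"])
        strata_total = sum(out.loc[(c, "total"), "total_cost"] for c in (1, 2, 3, 4))
        assert strata_total == out.loc[("overall", "total"), "total_cost"] == 550.0
        comp_total = sum(out.loc[("overall", comp), "total_cost"]
                         for comp in ("primary_care", "secondary_care",
                                      "tests_procedures"))
        assert comp_total == 550.0

    def test_homogeneity_under_unit_cost_scaling(self):
        intervals = self._intervals([(0, day(0), day(365), 2)])
        items = self._items([(0, day(10), "primary_care", 100.0)])
        scaled = items.assign(cost=items["cost"] * 3)
        a = stratified_costs(items, intervals)
        b = stratified_costs(scaled, intervals)
        assert (b["total_cost"].to_numpy()
                == pytest.approx(3 * a["total_cost"].to_numpy()))

    def test_item_outside_trajectory_dropped_with_warning(self):
        intervals = self._intervals([(0, day(0), day(100), 2)])
        items = self._items([(0, day(150), "primary_care", 100.0)])
        with pytest.warns(UserWarning):
            out = stratified_costs(items, intervals)
        assert out.set_index(["stratum", "component"]) \
            .loc[("overall", "total"), "total_cost"] == 0.0

    def test_person_years_match_trajectory(self):
        intervals = self._intervals([(0, day(0), day(100), 2),
                                     (0, day(100), day(300), 3)])
        out = stratified_costs(self._items([]), intervals)
        py = out[out["component"] == "total"].set_index("stratum")["person_years"]
        assert py[2] == pytest.approx(100 / 365.25)
        assert py[3] == pytest.approx(200 / 365.25)


def test_cost_per_patient_year_rounds_half_up():
    assert cost_per_patient_year(84_879_948, 19_352) == 4386
    with pytest.raises(ZeroDivisionError):
        cost_per_patient_year(100.0, 0.0)
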