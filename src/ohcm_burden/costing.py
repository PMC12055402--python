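"""Healthcare resource counting and costing, stratified by NYHA class.

Three components mirror the usual UK costing split:

* primary care — consultation counts × unit costs (out-of-hours visits are
  counted but excluded from costs);
* secondary care — outpatient / A&E / critical-care activity priced per unit,
  plus inpatient episodes (elective, non-elective, day case) priced from an
  HRG casemix table;
* tests & procedures — coded diagnostics priced per unit.

Non-inpatient unit costs are uplifted by a single multiplicative inflation
factor.  Each dated cost item is attributed to the NYHA interval containing
its date (multi-day stays: the class at admission), and per-stratum totals
divide by the trajectory's person-years.  Internals stay unrounded; reported
£/PY round half-up to integers.
"""

from __future__ import annotations

import warnings

import pandas as pd

from ._util import round_half_up

PRIMARY_CATEGORIES = ["gp", "nurse", "telephone", "out_of_hours"]
SECONDARY_UNIT_CATEGORIES = ["outpatient", "ae", "critical_care"]
INPATIENT_TYPES = ["elective", "non_elective", "day_case"]
DEFAULT_EXCLUDED_FROM_COSTS = ("out_of_hours",)

_ITEM_COLUMNS = ["patient_id", "date", "component", "category", "cost"]


def count_activity(consultations: pd.DataFrame, hospital_activity: pd.DataFrame,
                   procedures: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Dated activity rows within follow-up: (patient_id, date, category, component).

    ``procedures`` holds annotated clinical events with a procedure concept.
    Records outside follow-up are dropped; unknown categories are excluded
    with a warning.
    """
    fu = cohort.loc[cohort["included"],
                    ["patient_id", "followup_start", "followup_end"]]
    frames = []
    cons = consultations.rename(columns={"type": "category"})
    known = cons["category"].isin(PRIMARY_CATEGORIES)
    if (~known).any():
        warnings.warn(f"excluded {int((~known).sum())} consultations with "
                      "unknown category")
    frames.append(cons[known].assign(component="primary_care")[
        ["patient_id", "date", "category", "component"]])
    hosp = hospital_activity.rename(columns={"admit_date": "date", "type": "category"})
    known = hosp["category"].isin(SECONDARY_UNIT_CATEGORIES + INPATIENT_TYPES)
    if (~known).any():
        warnings.warn(f"excluded {int((~known).sum())} hospital rows with "
                      "unknown category")
    frames.append(hosp[known].assign(component="secondary_care")[
        ["patient_id", "date", "category", "component", "hrg_code"]])
    if not procedures.empty:
        proc = procedures.rename(columns={"concept": "category"})
        frames.append(proc.assign(component="tests_procedures")[
            ["patient_id", "date", "category", "component"]])
    non_empty = [f for f in frames if not f.empty]
    if not non_empty:
        return pd.DataFrame(columns=["patient_id", "date", "category",
                                     "component", "hrg_code"])
    activity = pd.concat(non_empty, ignore_index=True)
    if "hrg_code" not in activity.columns:
        activity["hrg_code"] = ""
    merged = activity.merge(fu, on="patient_id", how="inner")
    inside = (merged["date"] >= merged["followup_start"]) \
        & (merged["date"] < merged["followup_end"])
    return merged[inside].drop(columns=["followup_start", "followup_end"]) \
        .reset_index(drop=True)


def cost_non_inpatient(activity: pd.DataFrame, unit_costs: pd.DataFrame,
                       inflation_factor: float = 1.0,
                       excluded_categories=DEFAULT_EXCLUDED_FROM_COSTS
                       ) -> pd.DataFrame:
    """Price every non-inpatient activity row: cost = unit cost × inflation.

    Raises if any non-excluded category has no unit-cost row.
    """
    rows = activity[~activity["category"].isin(INPATIENT_TYPES)
                    & ~activity["category"].isin(excluded_categories)]
    priced = rows.merge(unit_costs[["category", "unit_cost"]], on="category",
                        how="left")
    missing = priced.loc[priced["unit_cost"].isna(), "category"].unique()
    if len(missing):
        raise KeyError(f"no unit cost for categories: {sorted(missing)}")
    priced["cost"] = priced["unit_cost"] * inflation_factor
    return priced[_ITEM_COLUMNS]


def cost_inpatient(activity: pd.DataFrame, hrg_costs: pd.DataFrame,
                   missing_hrg_policy: str = "drop") -> pd.DataFrame:
    """Price inpatient episodes by HRG currency code.

    ``missing_hrg_policy``: 'drop' prices unknown codes at £0 with a warning;
    'error' raises.
    """
    if missing_hrg_policy not in ("drop", "error"):
        raise ValueError(f"unknown missing_hrg_policy {missing_hrg_policy!r}")
    episodes = activity[activity["category"].isin(INPATIENT_TYPES)]
    priced = episodes.merge(hrg_costs, on="hrg_code", how="left")
    missing = priced["cost"].isna()
    if missing.any():
        codes = sorted(priced.loc[missing, "hrg_code"].astype(str).unique())
        if missing_hrg_policy == "error":
            raise KeyError(f"no HRG cost for codes: {codes}")
        warnings.warn(f"{int(missing.sum())} episodes with unpriced HRG codes "
                      f"{codes} costed at £0")
        priced["cost"] = priced["cost"].fillna(0.0)
    return priced[_ITEM_COLUMNS]


def stratified_costs(cost_items: pd.DataFrame, intervals: pd.DataFrame
                     ) -> pd.DataFrame:
    """CostSummary rows: per-stratum, per-component totals and £/PY.

    Strata are NYHA classes 1–4 plus 'overall'; components plus a 'total' row
    per stratum.  ``cost_per_py`` is unrounded; ``cost_per_py_reported``
    rounds half-up to the nearest pound.  Items dated outside any interval are
    dropped with a warning.
    """
    from ._util import DAYS_PER_YEAR
    py = ((intervals["end"] - intervals["start"]).dt.days / DAYS_PER_YEAR) \
        .groupby(intervals["nyha_class"]).sum()
    if cost_items.empty:
        attributed = pd.DataFrame(columns=_ITEM_COLUMNS + ["nyha_class"])
    else:
        merged = cost_items.merge(intervals, on="patient_id", how="left")
        inside = (merged["date"] >= merged["start"]) & (merged["date"] < merged["end"])
        attributed = merged[inside]
    n_dropped = len(cost_items) - len(attributed)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} cost items outside the trajectory")
    components = ["primary_care", "secondary_care", "tests_procedures"]
    rows = []

    def emit(stratum, frame, person_years):
        for comp in components + ["total"]:
            sub = frame if comp == "total" else frame[frame["component"] == comp]
            total = float(sub["cost"].sum())
            per_py = total / person_years if person_years > 0 else float("nan")
            rows.append((stratum, comp, total, person_years, per_py,
                         int(round_half_up(per_py)) if person_years > 0 else pd.NA))

    for cls in (1, 2, 3, 4):
        emit(cls, attributed[attributed["nyha_class"] == cls],
             float(py.get(cls, 0.0)))
    emit("overall", attributed, float(py.sum()))
    return pd.DataFrame(rows, columns=["stratum", "component", "total_cost",
                                       "person_years", "cost_per_py",
                                       "cost_per_py_reported"])


def cost_per_patient_year(total_cost: float, person_years: float) -> int:
    """Reported £/PY: total divided by person-years, rounded half-up to £1."""
    if person_years <= 0:
        raise ZeroDivisionError("person_years must be positive")
    return int(round_half_up(total_cost / person_years))
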