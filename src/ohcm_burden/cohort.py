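"""Cohort construction: index date, eligibility, follow-up and baseline state.

The rules implemented here mirror a linked primary/secondary-care cohort
design: the index date is the earliest qualifying HCM diagnosis inside the
study window (earliest *obstructive* code when one exists, which also decides
the cohort label); eligibility requires adult age at index, a year of prior
continuous registration, provider-determined research quality and linkage
flags, an index inside the admissible index period, and no record of a
mimicking condition during the study period.  Follow-up runs from index to the
earliest of study end, death, the practice's last collection date and the end
of registration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import percent
from .resources import DEFAULT_CCI_WEIGHTS

ATTRITION_ORDER = [
    "index_before_index_period", "age_lt_18", "registration_lt_1y",
    "quality_fail", "not_linkage_eligible", "exclusion_condition",
]

BASELINE_LOOKBACK_DAYS = 730   # 2-year pre-index window, inclusive of index day
ACTIVE_RX_LOOKBACK_DAYS = 42   # 6-week active-prescription window, inclusive


class DegenerateFollowupError(ValueError):
    """Every candidate follow-up end precedes the index date."""


@dataclass
class StudyWindow:
    study_start: pd.Timestamp
    study_end: pd.Timestamp
    index_start: pd.Timestamp  # earliest admissible index (look-back complete)

    def __init__(self, study_start, study_end, index_start):
        self.study_start = pd.Timestamp(study_start)
        self.study_end = pd.Timestamp(study_end)
        self.index_start = pd.Timestamp(index_start)


DEFAULT_WINDOW = StudyWindow("2007-04-01", "2020-10-30", "2009-04-01")


def annotate_events(clinical_events: pd.DataFrame, codelists: pd.DataFrame) -> pd.DataFrame:
    """Join coded events onto the codelist, keeping only recognized codes."""
    return clinical_events.merge(codelists, on=["vocabulary", "code"], how="inner")


def find_index_and_cohort(patient_events: pd.DataFrame, window: StudyWindow
                          ) -> tuple[pd.Timestamp, str] | None:
    """Earliest qualifying HCM diagnosis and cohort label for one patient.

    ``patient_events`` must already carry codelist annotations (see
    :func:`annotate_events`).  Any obstructive code assigns the patient to the
    obstructive cohort with index at the earliest obstructive date; otherwise
    unspecified codes pool with non-obstructive.  Returns ``None`` when no HCM
    code falls inside the study window.
    """
    hcm = patient_events[(patient_events["hcm_subtype"] != "")
                         & (patient_events["date"] >= window.study_start)
                         & (patient_events["date"] <= window.study_end)]
    if hcm.empty:
        return None
    obstructive = hcm[hcm["hcm_subtype"] == "obstructive"]
    if not obstructive.empty:
        return obstructive["date"].min(), "obstructive"
    return hcm["date"].min(), "nonobstructive_unspecified"


def apply_eligibility(patient: pd.Series, index_date: pd.Timestamp,
                      patient_events: pd.DataFrame, window: StudyWindow
                      ) -> dict[str, bool]:
    """One boolean per attrition criterion; included iff all are False."""
    age_at_index = index_date.year - int(patient["birth_year"])
    in_study = patient_events[(patient_events["date"] >= window.study_start)
                              & (patient_events["date"] <= window.study_end)]
    return {
        "index_before_index_period": bool(index_date < window.index_start),
        "age_lt_18": bool(age_at_index < 18),
        "registration_lt_1y": bool((index_date - patient["reg_start"]).days < 365),
        "quality_fail": not bool(patient["acceptable_quality"]),
        "not_linkage_eligible": not bool(patient["linkage_eligible"]),
        "exclusion_condition": bool((in_study["is_exclusion"] == 1).any()),
    }


def compute_followup_end(patient: pd.Series, index_date: pd.Timestamp,
                         study_end: pd.Timestamp,
                         death_date: pd.Timestamp | None = None) -> pd.Timestamp:
    """min(study end, death, practice last collection, registration end)."""
    candidates = [study_end, patient["practice_last_collection"], patient["reg_end"]]
    if death_date is not None and not pd.isna(death_date):
        candidates.append(death_date)
    end = min(candidates)
    if end < index_date:
        raise DegenerateFollowupError(
            f"patient {patient['patient_id']}: all follow-up end candidates "
            f"precede index {index_date.date()}")
    return end


def baseline_characteristics(patient: pd.Series, index_date: pd.Timestamp,
                             patient_events: pd.DataFrame,
                             patient_rx: pd.DataFrame,
                             cci_weights: dict[str, int] | None = None) -> dict:
    """Baseline condition flags, active therapy classes and age-adjusted CCI.

    Condition flags look back two years from (and including) the index day;
    a prescription is active at baseline if issued within the six weeks up to
    and including the index day.
    """
    lb = index_date - pd.Timedelta(days=BASELINE_LOOKBACK_DAYS)
    in_window = patient_events[(patient_events["date"] >= lb)
                               & (patient_events["date"] <= index_date)]
    conditions = set(in_window.loc[in_window["condition"] != "", "condition"])
    rx_lb = index_date - pd.Timedelta(days=ACTIVE_RX_LOOKBACK_DAYS)
    active = patient_rx[(patient_rx["date"] >= rx_lb)
                        & (patient_rx["date"] <= index_date)]
    weights = DEFAULT_CCI_WEIGHTS if cci_weights is None else cci_weights
    age = index_date.year - int(patient["birth_year"])
    cci = sum(w for cond, w in weights.items() if cond in conditions)
    cci += max(0, min((age - 40) // 10, 4)) if age >= 50 else 0
    return {
        "baseline_conditions": sorted(conditions),
        "baseline_active_rx": sorted(set(active["therapy_class"])),
        "cci_age_adjusted": int(cci),
    }


def build_cohort(dataset, codelists: pd.DataFrame,
                 window: StudyWindow = DEFAULT_WINDOW,
                 cci_weights: dict[str, int] | None = None) -> pd.DataFrame:
    """One CohortRecord row per patient with any in-window HCM code.

    ``included`` is True when every attrition flag is False; follow-up fields
    are only populated for included patients.
    """
    annotated = annotate_events(dataset.clinical_events, codelists)
    deaths = dataset.deaths.set_index("patient_id")["date"] if not dataset.deaths.empty \
        else pd.Series(dtype="datetime64[ns]")
    ev_by_pid = dict(tuple(annotated.groupby("patient_id")))
    rx_by_pid = dict(tuple(dataset.prescriptions.groupby("patient_id")))
    empty_ev = annotated.iloc[0:0]
    empty_rx = dataset.prescriptions.iloc[0:0]

    records = []
    for patient in dataset.patients.itertuples(index=False):
        patient = pd.Series(patient._asdict())
        pid = patient["patient_id"]
        events = ev_by_pid.get(pid, empty_ev)
        found = find_index_and_cohort(events, window)
        if found is None:
            continue
        index_date, cohort_label = found
        flags = apply_eligibility(patient, index_date, events, window)
        included = not any(flags.values())
        rec = {"patient_id": pid, "index_date": index_date, "cohort": cohort_label,
               "included": included, **flags}
        if included:
            death = deaths.get(pid)
            end = compute_followup_end(patient, index_date, window.study_end, death)
            rec["followup_start"] = index_date
            rec["followup_end"] = end
            rec["death_date"] = death if death is not None else pd.NaT
            base = baseline_characteristics(
                patient, index_date, events, rx_by_pid.get(pid, empty_rx), cci_weights)
            rec["baseline_conditions"] = ";".join(base["baseline_conditions"])
            rec["baseline_active_rx"] = ";".join(base["baseline_active_rx"])
            rec["cci_age_adjusted"] = base["cci_age_adjusted"]
        records.append(rec)
    columns = ["patient_id", "index_date", "cohort", "included", *ATTRITION_ORDER,
               "followup_start", "followup_end", "death_date",
               "baseline_conditions", "baseline_active_rx", "cci_age_adjusted"]
    df = pd.DataFrame(records)
    return df.reindex(columns=columns) if not df.empty else pd.DataFrame(columns=columns)


def attrition_report(records: pd.DataFrame) -> pd.DataFrame:
    """Attrition counts/percentages with flag-first sequential attribution.

    Each excluded patient is attributed to the first criterion (in
    ``ATTRITION_ORDER``) that failed, so counts partition the identified
    population: included + sum(excluded-by-criterion) = identified.
    Percentages are of the identified population, to 2 decimal places; the
    cohort-split rows are percentages of the eligible population.
    """
    rows = []
    identified = len(records)
    rows.append(("identified", identified, 100.0 if identified else 0.0))
    if identified == 0:
        return pd.DataFrame(rows, columns=["criterion", "n", "pct"])
    remaining = records
    for crit in ATTRITION_ORDER:
        hit = remaining[remaining[crit]]
        rows.append((f"excluded_{crit}", len(hit), percent(len(hit), identified, 2)))
        remaining = remaining[~remaining[crit]]
    eligible = len(remaining)
    rows.append(("eligible", eligible, percent(eligible, identified, 2)))
    if eligible:
        n_obs = int((remaining["cohort"] == "obstructive").sum())
        rows.append(("obstructive", n_obs, percent(n_obs, eligible, 2)))
        rows.append(("nonobstructive_unspecified", eligible - n_obs,
                     percent(eligible - n_obs, eligible, 2)))
    return pd.DataFrame(rows, columns=["criterion", "n", "pct"])
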