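"""Clinical-event identification, person-time splitting and incidence.

Chronic conditions (AF/flutter, heart failure, conduction disorders, ...) are
first-occurrence-only events; acute presentations (MI, stroke, VT, ...) are
repeatable, with codes ≥ a dedup window apart counted as distinct events (a
greedy forward scan against the last *kept* code).  Person-time is split by
the time-varying NYHA trajectory and events are attributed to the half-open
class interval containing their date.  Rates are events per 100 patient-years
with an exact Poisson (Garwood) CI by default, or a patient-clustered
negative-binomial CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from scipy import stats

from ._util import DAYS_PER_YEAR
from .resources import FIRST_ONLY_EVENTS, REPEATABLE_EVENTS


@dataclass
class EventRule:
    name: str
    mode: str  # 'first_only' | 'repeatable'
    dedup_days: int = 30
    incident_only: bool = True  # first_only: drop patients with a baseline record

    def __post_init__(self) -> None:
        if self.mode not in ("first_only", "repeatable"):
            raise ValueError(f"unknown event mode {self.mode!r}")
        if self.dedup_days < 0:
            raise ValueError("dedup_days must be >= 0")


def default_event_rules() -> dict[str, EventRule]:
    rules = {name: EventRule(name, "first_only") for name in FIRST_ONLY_EVENTS}
    rules.update({name: EventRule(name, "repeatable") for name in REPEATABLE_EVENTS})
    return rules


def identify_events(patient_events: pd.DataFrame, rule: EventRule,
                    index_date: pd.Timestamp,
                    followup_end: pd.Timestamp) -> list[pd.Timestamp]:
    """Dated events for one patient and one rule.

    ``patient_events`` must be annotated rows whose ``condition`` matches the
    rule name.  First-only: at most one event (earliest in-study code), and no
    event at all when ``incident_only`` and a pre-index record exists.
    Repeatable: greedy scan keeping a code iff ≥ ``dedup_days`` after the last
    kept code.
    """
    coded = patient_events[patient_events["condition"] == rule.name]
    dates = coded["date"].sort_values()
    in_fu = dates[(dates >= index_date) & (dates < followup_end)]
    if rule.mode == "first_only":
        if rule.incident_only and (dates < index_date).any():
            return []
        return [in_fu.iloc[0]] if len(in_fu) else []
    kept: list[pd.Timestamp] = []
    for date in in_fu:
        if not kept or (date - kept[-1]).days >= rule.dedup_days:
            kept.append(date)
    return kept


def split_person_time(intervals: pd.DataFrame, events: pd.DataFrame
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label person-time slices and events by time-varying NYHA class.

    ``intervals`` is a per-patient trajectory tiling follow-up; ``events`` has
    columns (patient_id, event, date).  Returns (slices, labelled events);
    events outside any interval are rejected with a warning.
    """
    slices = intervals.copy()
    slices["person_years"] = (slices["end"] - slices["start"]).dt.days / DAYS_PER_YEAR
    if events.empty:
        labelled = events.assign(nyha_class=pd.Series(dtype=int))
        return slices, labelled
    merged = events.merge(intervals, on="patient_id", how="left")
    inside = (merged["date"] >= merged["start"]) & (merged["date"] < merged["end"])
    labelled = merged[inside][["patient_id", "event", "date", "nyha_class"]]
    n_out = len(events) - len(labelled)
    if n_out:
        warnings.warn(f"dropped {n_out} events outside follow-up")
    return slices, labelled.reset_index(drop=True)


def _garwood_ci(k: int, py: float, alpha: float = 0.05) -> tuple[float, float]:
    """Exact Poisson CI for a rate per 100 PY (chi-square closed form)."""
    lo = stats.chi2.ppf(alpha / 2, 2 * k) / 2 if k > 0 else 0.0
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * k + 2) / 2
    return 100.0 * lo / py, 100.0 * hi / py


def _nb_robust_ci(counts: np.ndarray, py: np.ndarray,
                  alpha: float = 0.05) -> tuple[float, float]:
    """Negative-binomial intercept model with patient-clustered robust SE."""
    exog = np.ones((len(counts), 1))
    model = sm.GLM(counts, exog, family=sm.families.NegativeBinomial(alpha=1.0),
                   offset=np.log(py))
    res = model.fit(cov_type="HC1")
    z = stats.norm.ppf(1 - alpha / 2)
    b, se = res.params[0], res.bse[0]
    return 100.0 * np.exp(b - z * se), 100.0 * np.exp(b + z * se)


def estimate_incidence(slices: pd.DataFrame, labelled_events: pd.DataFrame,
                       method: str = "poisson_exact") -> pd.DataFrame:
    """Per-(event, class) rates per 100 patient-years with 95% CIs.

    Strata with zero person-time are omitted with a warning.  ``method`` is
    ``poisson_exact`` (Garwood) or ``nb_robust`` (negative binomial on
    patient-level counts with robust variance).
    """
    if method not in ("poisson_exact", "nb_robust"):
        raise ValueError(f"unknown incidence method {method!r}")
    py_by_class = slices.groupby("nyha_class")["person_years"].sum()
    py_by_patient = slices.pivot_table(index="patient_id", columns="nyha_class",
                                       values="person_years", aggfunc="sum",
                                       fill_value=0.0)
    rows = []
    events_list = sorted(labelled_events["event"].unique()) if not labelled_events.empty else []
    for event in events_list:
        ev = labelled_events[labelled_events["event"] == event]
        counts_by_class = ev.groupby("nyha_class").size()
        for cls in (1, 2, 3, 4):
            py = float(py_by_class.get(cls, 0.0))
            k = int(counts_by_class.get(cls, 0))
            if py <= 0:
                if k:
                    warnings.warn(f"{event}: stratum {cls} has events but no "
                                  "person-time; omitted")
                continue
            rate = 100.0 * k / py
            if method == "poisson_exact":
                lo, hi = _garwood_ci(k, py)
            else:
                pat_py = py_by_patient[cls] if cls in py_by_patient else pd.Series(dtype=float)
                pat_py = pat_py[pat_py > 0]
                pat_counts = ev[ev["nyha_class"] == cls].groupby("patient_id").size()
                counts = pat_counts.reindex(pat_py.index, fill_value=0).to_numpy(float)
                lo, hi = _nb_robust_ci(counts, pat_py.to_numpy(float))
            rows.append((event, cls, k, py, rate, lo, hi, method))
    return pd.DataFrame(rows, columns=["event", "nyha_class", "events",
                                       "person_years", "rate", "ci_low",
                                       "ci_high", "method"])


def km_time_to_first(durations, event_observed) -> pd.DataFrame:
    """Product-limit survival for time from index to first event."""
    durations = np.asarray(durations, dtype=float)
    event_observed = np.asarray(event_observed, dtype=bool)
    if (durations < 0).any():
        raise ValueError("durations must be non-negative")
    if len(durations) == 0:
        return pd.DataFrame(columns=["time", "survival", "n_at_risk"])
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed)
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index).ffill()
    return pd.DataFrame({"time": surv.index.to_numpy(dtype=float),
                         "survival": surv.to_numpy(),
                         "n_at_risk": at_risk.to_numpy(dtype=int)})


def collect_events(cohort: pd.DataFrame, annotated_events: pd.DataFrame,
                   rules: dict[str, EventRule] | None = None,
                   deaths: pd.DataFrame | None = None) -> pd.DataFrame:
    """Dated events for every included patient under every rule.

    All-cause mortality, when present in the rules, is taken from the deaths
    table rather than coded events.
    """
    rules = default_event_rules() if rules is None else rules
    ev_by_pid = dict(tuple(annotated_events.groupby("patient_id")))
    empty = annotated_events.iloc[0:0]
    death_by_pid = (deaths.set_index("patient_id")["date"]
                    if deaths is not None and not deaths.empty else pd.Series(dtype=object))
    rows = []
    for row in cohort[cohort["included"]].itertuples(index=False):
        events = ev_by_pid.get(row.patient_id, empty)
        for rule in rules.values():
            if rule.name == "all_cause_mortality":
                death = death_by_pid.get(row.patient_id)
                if death is not None and not pd.isna(death) \
                        and row.index_date <= death < row.followup_end:
                    rows.append((row.patient_id, rule.name, death))
                continue
            for date in identify_events(events, rule, row.index_date,
                                        row.followup_end):
                rows.append((row.patient_id, rule.name, date))
    return pd.DataFrame(rows, columns=["patient_id", "event", "date"])
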