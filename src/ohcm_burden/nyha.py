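"""Proxy NYHA classification: baseline decision tree and daily trajectory.

NYHA functional class is rarely coded in primary care, so class is inferred
from what *is* coded: HCM-specific therapy intensity, symptom burden and
heart-failure hospitalization.  A recorded NYHA code always wins.  The default
proxy tree (fully overridable via :class:`NYHARuleset`):

* no HCM-relevant therapy, no symptoms        -> class I
* a single agent (BB or CCB)                  -> class II
* two+ agents, disopyramide or loop diuretic  -> class III
* heart-failure hospitalization in look-back  -> class IV
* +1 class (capped at IV) when >=2 distinct symptom concepts sit in the window

The daily trajectory re-evaluates the tree each follow-up day (medication
activity = days' supply plus a grace period; symptoms within a rolling
look-back) and then applies the asymptomatic-correction ratchet: a symptomatic
(class II+) patient cannot return to class I unless an intervention — septal
reduction therapy, device insertion, or therapy initiation/augmentation —
occurred since they last entered the class being held.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._util import DAYS_PER_YEAR
from .treatments import build_exposure_intervals


@dataclass
class NYHARuleset:
    """Windows and rule parameters for the proxy classifier (day offsets)."""

    med_window_start: int = -2        # baseline medication window, from index
    med_window_end: int = 28          # inclusive
    baseline_symptom_start: int = -90
    baseline_symptom_end: int = 28    # inclusive
    daily_grace_days: int = 30        # medication active: supply + grace
    daily_symptom_lookback: int = 90
    hf_hosp_lookback: int = 90        # heart-failure hospitalization -> class IV
    symptom_threshold: int = 2        # distinct concepts for the +1 adjustment
    escalating_classes: tuple = ("BB", "CCB")        # single agent -> II
    high_intensity_classes: tuple = ("disopyramide", "loop_diuretic")  # -> III

    @classmethod
    def from_yaml(cls, path) -> "NYHARuleset":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("escalating_classes", "high_intensity_classes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: list(v) if isinstance(v, tuple) else v
                            for k, v in asdict(self).items()}, fh)


def _provisional(n_agents: int, has_high_intensity: bool, hf_hosp: bool,
                 n_symptom_concepts: int, threshold: int) -> int:
    if hf_hosp:
        cls = 4
    elif n_agents >= 2 or has_high_intensity:
        cls = 3
    elif n_agents == 1:
        cls = 2
    else:
        cls = 1
    if n_symptom_concepts >= threshold:
        cls = min(cls + 1, 4)
    return cls


def classify_baseline(index_date: pd.Timestamp, events: pd.DataFrame,
                      prescriptions: pd.DataFrame, drug_map: pd.DataFrame,
                      ruleset: NYHARuleset | None = None) -> tuple[int, str]:
    """Baseline class and provenance ('recorded' | 'proxy') for one patient.

    ``events`` must carry codelist annotations.  The closest recorded NYHA
    code on/before index wins; otherwise the decision tree runs on
    prescriptions in the medication window and symptoms in the baseline
    symptom window.
    """
    rs = ruleset or NYHARuleset()
    recorded = events[(events["nyha_class"] > 0) & (events["date"] <= index_date)]
    if not recorded.empty:
        return int(recorded.sort_values("date").iloc[-1]["nyha_class"]), "recorded"

    dm = drug_map.set_index("product")["therapy_class"]
    lo = index_date + pd.Timedelta(days=rs.med_window_start)
    hi = index_date + pd.Timedelta(days=rs.med_window_end)
    rx = prescriptions[(prescriptions["date"] >= lo) & (prescriptions["date"] <= hi)]
    classes = rx["product"].map(dm).dropna()
    products = set(rx.loc[classes.isin(rs.escalating_classes).to_numpy(), "product"])
    has_high = bool(classes.isin(rs.high_intensity_classes).any())

    s_lo = index_date + pd.Timedelta(days=rs.baseline_symptom_start)
    s_hi = index_date + pd.Timedelta(days=rs.baseline_symptom_end)
    sym = events[(events["symptom"] != "") & (events["date"] >= s_lo)
                 & (events["date"] <= s_hi)]
    n_sym = sym["symptom"].nunique()

    hf_lo = index_date - pd.Timedelta(days=rs.hf_hosp_lookback)
    hf = events[(events["condition"] == "heart_failure")
                & (events["setting"] == "secondary")
                & (events["date"] >= hf_lo) & (events["date"] <= index_date)]
    cls = _provisional(len(products), has_high, not hf.empty, n_sym,
                       rs.symptom_threshold)
    return cls, "proxy"


def _stamp(n_days: int, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Boolean per-day coverage of the union of half-open [start, end) spans."""
    diff = np.zeros(n_days + 1, dtype=np.int64)
    s = np.clip(starts, 0, n_days)
    e = np.clip(ends, 0, n_days)
    np.add.at(diff, s, 1)
    np.add.at(diff, e, -1)
    return np.cumsum(diff[:-1]) > 0


def classify_daily(index_date: pd.Timestamp, followup_end: pd.Timestamp,
                   events: pd.DataFrame, prescriptions: pd.DataFrame,
                   drug_map: pd.DataFrame,
                   ruleset: NYHARuleset | None = None) -> np.ndarray:
    """Raw (pre-ratchet) daily class series over [index, followup_end).

    Day 0 is the index day; the series is empty for zero-length follow-up.
    """
    rs = ruleset or NYHARuleset()
    n_days = (followup_end - index_date).days
    if n_days <= 0:
        return np.empty(0, dtype=np.int64)

    def day_of(dates) -> np.ndarray:
        return np.asarray((pd.to_datetime(dates) - index_date).dt.days)

    dm = drug_map.set_index("product")["therapy_class"]
    exposure = build_exposure_intervals(prescriptions, rs.daily_grace_days)
    n_agents = np.zeros(n_days, dtype=np.int64)
    has_high = np.zeros(n_days, dtype=bool)
    if not exposure.empty:
        exposure = exposure.assign(tclass=exposure["product"].map(dm))
        for (product, tclass), grp in exposure.groupby(["product", "tclass"]):
            active = _stamp(n_days, day_of(grp["start"]),
                            day_of(grp["end"]) + rs.daily_grace_days)
            if tclass in rs.escalating_classes:
                n_agents += active
            if tclass in rs.high_intensity_classes:
                has_high |= active

    n_sym = np.zeros(n_days, dtype=np.int64)
    sym = events[events["symptom"] != ""]
    for concept, grp in sym.groupby("symptom"):
        d = day_of(grp["date"])
        n_sym += _stamp(n_days, d, d + rs.daily_symptom_lookback)

    hf = events[(events["condition"] == "heart_failure")
                & (events["setting"] == "secondary")]
    d = day_of(hf["date"])
    hf_active = _stamp(n_days, d, d + rs.hf_hosp_lookback)

    raw = np.where(hf_active, 4,
                   np.where((n_agents >= 2) | has_high, 3,
                            np.where(n_agents == 1, 2, 1)))
    return np.minimum(raw + (n_sym >= rs.symptom_threshold), 4).astype(np.int64)


def intervention_days(index_date: pd.Timestamp, n_days: int, events: pd.DataFrame,
                      prescriptions: pd.DataFrame,
                      grace_days: int = 30) -> np.ndarray:
    """Boolean array of ratchet-releasing days.

    A day releases the ratchet if it carries a coded intervention (SRT, device
    insertion) or starts a new exposure interval for any product — therapy
    initiation or within/between-class augmentation.
    """
    flags = np.zeros(n_days, dtype=bool)
    coded = events[events["is_intervention"] == 1]
    d = np.asarray((coded["date"] - index_date).dt.days)
    flags[d[(d >= 0) & (d < n_days)]] = True
    exposure = build_exposure_intervals(prescriptions, grace_days)
    if not exposure.empty:
        d = np.asarray((pd.to_datetime(exposure["start"]) - index_date).dt.days)
        flags[d[(d >= 0) & (d < n_days)]] = True
    return flags


def apply_ratchet(raw: np.ndarray, interventions: np.ndarray | None = None,
                  baseline: tuple[int, str] | None = None,
                  recorded: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Asymptomatic correction plus recorded-code override, forward in time.

    Any II+ -> I transition is blocked (the held class persists) unless an
    intervention occurred strictly after the day the held class was entered.
    A recorded NYHA code overrides the proxy from its date forward until the
    raw series next changes value.  Returns (corrected series, recorded-
    provenance mask).
    """
    n = len(raw)
    corrected = np.empty(n, dtype=np.int64)
    prov_recorded = np.zeros(n, dtype=bool)
    if n == 0:
        return corrected, prov_recorded
    interventions = np.zeros(n, dtype=bool) if interventions is None else interventions
    recorded = np.zeros(n, dtype=np.int64) if recorded is None else recorded

    if recorded[0] > 0:
        cur, cur_recorded = int(recorded[0]), True
    elif baseline is not None:
        cur, cur_recorded = int(baseline[0]), baseline[1] == "recorded"
    else:
        cur, cur_recorded = int(raw[0]), False
    hold_since = 0
    last_intervention = -1
    override_raw = int(raw[0]) if cur_recorded else None

    for d in range(n):
        if interventions[d]:
            last_intervention = d
        if d > 0:
            if recorded[d] > 0:
                cur, cur_recorded = int(recorded[d]), True
                override_raw = int(raw[d])
                hold_since = d
            elif cur_recorded and int(raw[d]) != override_raw:
                cur_recorded = False  # rule-driven change releases the override
            if not cur_recorded:
                r = int(raw[d])
                if r == 1 and cur >= 2 and last_intervention <= hold_since:
                    pass  # ratchet holds the symptomatic class
                elif r != cur:
                    cur = r
                    if cur >= 2:
                        hold_since = d
        corrected[d] = cur
        prov_recorded[d] = cur_recorded
    return corrected, prov_recorded


def compress_to_intervals(corrected: np.ndarray, prov_recorded: np.ndarray,
                          index_date: pd.Timestamp, patient_id) -> pd.DataFrame:
    """Maximal equal-(class, provenance) runs as half-open dated intervals."""
    n = len(corrected)
    if n == 0:
        return pd.DataFrame(columns=["patient_id", "start", "end", "nyha_class",
                                     "provenance"])
    key = corrected * 2 + prov_recorded
    change = np.flatnonzero(np.diff(key)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    return pd.DataFrame({
        "patient_id": patient_id,
        "start": index_date + pd.to_timedelta(starts, unit="D"),
        "end": index_date + pd.to_timedelta(ends, unit="D"),
        "nyha_class": corrected[starts],
        "provenance": np.where(prov_recorded[starts], "recorded", "proxy"),
    })


def person_time_by_class(intervals: pd.DataFrame) -> pd.Series:
    """Years per NYHA class (index 1–4), exact at day resolution / 365.25."""
    if intervals.empty:
        return pd.Series(0.0, index=[1, 2, 3, 4], name="person_years")
    days = (intervals["end"] - intervals["start"]).dt.days
    py = days.groupby(intervals["nyha_class"]).sum() / DAYS_PER_YEAR
    return py.reindex([1, 2, 3, 4], fill_value=0.0).rename("person_years")


def build_trajectories(cohort: pd.DataFrame, annotated_events: pd.DataFrame,
                       prescriptions: pd.DataFrame, drug_map: pd.DataFrame,
                       ruleset: NYHARuleset | None = None) -> pd.DataFrame:
    """Per-patient NYHA interval trajectories for all included cohort rows.

    Trajectories exactly tile [index, followup_end) for each patient; day 0
    carries the baseline classification.
    """
    rs = ruleset or NYHARuleset()
    ev_by_pid = dict(tuple(annotated_events.groupby("patient_id")))
    rx_by_pid = dict(tuple(prescriptions.groupby("patient_id")))
    empty_ev = annotated_events.iloc[0:0]
    empty_rx = prescriptions.iloc[0:0]
    pieces = []
    for row in cohort[cohort["included"]].itertuples(index=False):
        events = ev_by_pid.get(row.patient_id, empty_ev)
        rx = rx_by_pid.get(row.patient_id, empty_rx)
        n_days = (row.followup_end - row.index_date).days
        if n_days <= 0:
            continue
        raw = classify_daily(row.index_date, row.followup_end, events, rx,
                             drug_map, rs)
        baseline = classify_baseline(row.index_date, events, rx, drug_map, rs)
        interv = intervention_days(row.index_date, n_days, events, rx,
                                   rs.daily_grace_days)
        rec = np.zeros(n_days, dtype=np.int64)
        in_fu = events[(events["nyha_class"] > 0) & (events["date"] > row.index_date)
                       & (events["date"] < row.followup_end)]
        for r in in_fu.itertuples(index=False):
            rec[(r.date - row.index_date).days] = r.nyha_class
        corrected, prov = apply_ratchet(raw, interv, baseline, rec)
        pieces.append(compress_to_intervals(corrected, prov, row.index_date,
                                            row.patient_id))
    if not pieces:
        return pd.DataFrame(columns=["patient_id", "start", "end", "nyha_class",
                                     "provenance"])
    return pd.concat(pieces, ignore_index=True)
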