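"""Therapy-exposure reconstruction and treatment-change taxonomy.

Prescriptions with a positive days' supply become per-product exposure
intervals (successive supplies of the same product merge across gaps up to a
grace period).  The concurrent-product timeline partitions into regimen
intervals; the first departure from the initial regimen is classified into a
mutually exclusive, exhaustive taxonomy: a ≥90-day no-treatment gap,
augmentation, discontinuation, or a switch (within class, between classes, or
with an addition).
"""

from __future__ import annotations

import warnings
from collections import Counter

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

DEFAULT_GRACE_DAYS = 30
DEFAULT_GAP_DAYS = 90

CHANGE_CATEGORIES = [
    "no_treatment_gap", "augment", "discontinuation",
    "switch_between_class", "switch_within_class", "switch_with_addition",
]

_EXPOSURE_COLUMNS = ["patient_id", "product", "start", "end"]
_REGIMEN_COLUMNS = ["patient_id", "start", "end", "products", "classes"]

_MULTIPLICITY = {1: "monotherapy", 2: "dual therapy", 3: "triple therapy"}
_CLASS_ORDER = {"BB": 0, "CCB": 1, "disopyramide": 2}


def build_exposure_intervals(prescriptions: pd.DataFrame,
                             grace_days: int = DEFAULT_GRACE_DAYS) -> pd.DataFrame:
    """Merge each product's supply spans into half-open exposure intervals.

    A row with ``days_supply`` d issued on day t covers [t, t+d); spans of the
    same product that overlap or fall within ``grace_days`` of each other
    merge.  Zero/missing supplies are dropped; negative supplies are rejected
    with a warning.
    """
    rx = prescriptions.copy()
    negative = rx["days_supply"] < 0
    if negative.any():
        warnings.warn(f"rejected {int(negative.sum())} prescriptions with "
                      "negative days_supply")
    rx = rx[rx["days_supply"].fillna(0) > 0]
    if rx.empty:
        return pd.DataFrame(columns=_EXPOSURE_COLUMNS)
    rx = rx.sort_values(["patient_id", "product", "date"])
    rx["span_end"] = rx["date"] + pd.to_timedelta(rx["days_supply"], unit="D")
    out = []
    for (pid, product), grp in rx.groupby(["patient_id", "product"], sort=False):
        start = end = None
        for date, span_end in zip(grp["date"], grp["span_end"]):
            if start is None:
                start, end = date, span_end
            elif (date - end).days <= grace_days:
                end = max(end, span_end)
            else:
                out.append((pid, product, start, end))
                start, end = date, span_end
        out.append((pid, product, start, end))
    return pd.DataFrame(out, columns=_EXPOSURE_COLUMNS)


def derive_regimens(exposure: pd.DataFrame, drug_map: pd.DataFrame,
                    hcm_specific_only: bool = True) -> pd.DataFrame:
    """Partition each patient's timeline at product starts/ends.

    Returns ordered, non-overlapping regimen intervals labelled with the
    concurrent product set (';'-joined, sorted) and therapy-class multiset.
    Adjacent segments with identical product sets merge.
    """
    dm = drug_map.set_index("product")
    exp = exposure
    if hcm_specific_only and not exposure.empty:
        specific = set(dm.index[dm["is_hcm_specific"] == 1])
        exp = exposure[exposure["product"].isin(specific)]
    rows = []
    for pid, grp in exp.groupby("patient_id", sort=True):
        bounds = np.unique(np.concatenate([grp["start"].to_numpy(),
                                           grp["end"].to_numpy()]))
        segments = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            active = grp[(grp["start"] <= lo) & (grp["end"] >= hi)]
            products = tuple(sorted(active["product"].unique()))
            if products:
                segments.append([lo, hi, products])
        merged = []
        for seg in segments:
            if merged and merged[-1][2] == seg[2] and merged[-1][1] == seg[0]:
                merged[-1][1] = seg[1]
            else:
                merged.append(seg)
        for lo, hi, products in merged:
            classes = sorted((dm.loc[p, "therapy_class"] for p in products),
                             key=lambda c: _CLASS_ORDER.get(c, 99))
            rows.append((pid, pd.Timestamp(lo), pd.Timestamp(hi),
                         ";".join(products), "+".join(classes)))
    return pd.DataFrame(rows, columns=_REGIMEN_COLUMNS)


def regimen_label(products, drug_map: pd.DataFrame) -> str | None:
    """Report-style label, e.g. 'BB monotherapy', 'BB + BB dual therapy'."""
    products = sorted(set(products))
    if not products:
        return None
    dm = drug_map.set_index("product")["therapy_class"]
    classes = sorted((dm[p] for p in products),
                     key=lambda c: _CLASS_ORDER.get(c, 99))
    multiplicity = _MULTIPLICITY.get(len(classes), f"{len(classes)}-agent therapy")
    return f"{' + '.join(classes)} {multiplicity}"


def initial_treatment(regimens: pd.DataFrame, drug_map: pd.DataFrame) -> str | None:
    """Label of the first on/after-index regimen, or None if never treated."""
    if regimens.empty:
        return None
    first = regimens.sort_values("start").iloc[0]
    return regimen_label(first["products"].split(";"), drug_map)


def classify_transition(from_products, to_products, drug_map: pd.DataFrame) -> str:
    """Category of a regimen composition change (products must differ)."""
    f, t = set(from_products), set(to_products)
    if f == t:
        raise ValueError("not a composition change: product sets are equal")
    dm = drug_map.set_index("product")["therapy_class"]
    if f < t:
        return "augment"
    if t < f:
        return "discontinuation"
    if Counter(dm[p] for p in f) == Counter(dm[p] for p in t):
        return "switch_within_class"
    if len(t) > len(f):
        return "switch_with_addition"
    # replacement at equal (or reduced) cardinality across therapy classes
    return "switch_between_class"


def detect_first_change(regimens: pd.DataFrame, followup_end: pd.Timestamp,
                        drug_map: pd.DataFrame,
                        gap_days: int = DEFAULT_GAP_DAYS) -> dict | None:
    """Earliest treatment change for one patient's regimen sequence.

    Scans forward from the initial regimen.  An exposure gap reaching
    ``gap_days`` is a no-treatment change dated at the last exposure end; a
    composition change occurring before any gap reaches ``gap_days`` wins and
    is classified by :func:`classify_transition`.
    """
    if regimens.empty:
        return None
    seq = regimens.sort_values("start").reset_index(drop=True)
    for i in range(len(seq)):
        end_i = seq.loc[i, "end"]
        from_products = seq.loc[i, "products"].split(";")
        if i + 1 < len(seq):
            nxt = seq.loc[i + 1]
            if (nxt["start"] - end_i).days >= gap_days:
                return {"date": end_i, "category": "no_treatment_gap",
                        "from_regimen": ";".join(from_products), "to_regimen": ""}
            to_products = nxt["products"].split(";")
            if set(to_products) != set(from_products):
                return {"date": nxt["start"],
                        "category": classify_transition(from_products, to_products, drug_map),
                        "from_regimen": ";".join(from_products),
                        "to_regimen": ";".join(to_products)}
        elif (followup_end - end_i).days >= gap_days:
            return {"date": end_i, "category": "no_treatment_gap",
                    "from_regimen": ";".join(from_products), "to_regimen": ""}
    return None


def change_summary(changes: pd.DataFrame, denominator: int) -> pd.DataFrame:
    """Per-category counts and percentages (1 dp) of ``denominator``."""
    if denominator == 0:
        raise ZeroDivisionError("change_summary requires a non-zero denominator")
    from ._util import percent
    counts = changes["category"].value_counts() if not changes.empty else pd.Series(dtype=int)
    rows = [(cat, int(counts.get(cat, 0)), percent(int(counts.get(cat, 0)), denominator))
            for cat in CHANGE_CATEGORIES]
    total = int(sum(n for _, n, _ in rows))
    rows.append(("any_change", total, percent(total, denominator)))
    return pd.DataFrame(rows, columns=["category", "n", "pct"])


def cumulative_risk_curve(durations, event_observed) -> pd.DataFrame:
    """1 − Kaplan–Meier survival as a right-continuous step function.

    ``durations`` are times from the start of the initial regimen to the first
    change (event) or end of follow-up (censored); must be non-negative.
    """
    durations = np.asarray(durations, dtype=float)
    event_observed = np.asarray(event_observed, dtype=bool)
    if (durations < 0).any():
        raise ValueError("durations must be non-negative")
    if len(durations) == 0:
        return pd.DataFrame(columns=["time", "risk", "n_at_risk"])
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed)
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index).ffill()
    return pd.DataFrame({"time": surv.index.to_numpy(dtype=float),
                         "risk": 1.0 - surv.to_numpy(),
                         "n_at_risk": at_risk.to_numpy(dtype=int)})


def classes_per_calendar_year(prescriptions: pd.DataFrame,
                              drug_map: pd.DataFrame) -> pd.DataFrame:
    """Mean distinct HCM-specific therapy classes per patient per calendar year."""
    dm = drug_map.set_index("product")
    specific = set(dm.index[dm["is_hcm_specific"] == 1])
    rx = prescriptions[prescriptions["product"].isin(specific)].copy()
    if rx.empty:
        return pd.DataFrame(columns=["year", "mean_classes"])
    rx["year"] = rx["date"].dt.year
    per = rx.groupby(["year", "patient_id"])["therapy_class"].nunique()
    out = per.groupby("year").mean().reset_index()
    out.columns = ["year", "mean_classes"]
    return out
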