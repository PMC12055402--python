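"""Builders and brute-force oracles shared across the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ohcm_burden import resources
from ohcm_burden.cohort import annotate_events

_CODELISTS = resources.default_codelists()
_DRUG_MAP = resources.default_drug_map().set_index("product")


def make_events(rows) -> pd.DataFrame:
    """Annotated clinical-event rows from (pid, date, concept[, setting])."""
    data = []
    for row in rows:
        pid, date, concept = row[:3]
        setting = row[3] if len(row) > 3 else "primary"
        ref = _CODELISTS[_CODELISTS["concept"] == concept].iloc[0]
        data.append(dict(patient_id=pid, date=pd.Timestamp(date),
                         vocabulary=ref["vocabulary"], code=ref["code"],
                         setting=setting))
    cols = ["patient_id", "date", "vocabulary", "code", "setting"]
    raw = pd.DataFrame(data, columns=cols)
    return annotate_events(raw, _CODELISTS)


def make_rx(rows) -> pd.DataFrame:
    """Prescription rows from (pid, date, product, days_supply)."""
    data = [dict(patient_id=pid, date=pd.Timestamp(date), product=product,
                 therapy_class=_DRUG_MAP.loc[product, "therapy_class"],
                 days_supply=supply)
            for pid, date, product, supply in rows]
    cols = ["patient_id", "date", "product", "therapy_class", "days_supply"]
    return pd.DataFrame(data, columns=cols)


def empty_events() -> pd.DataFrame:
    return make_events([])


def empty_rx() -> pd.DataFrame:
    return make_rx([])


def km_survival_oracle(times, events, t: float) -> float:
    """Product-limit survival at time t by explicit risk-set enumeration."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    s = 1.0
    for u in sorted(set(times[events])):
        if u > t:
            break
        at_risk = int((times >= u).sum())
        d = int(((times == u) & events).sum())
        s *= 1.0 - d / at_risk
    return s


def exposure_days_oracle(scripts, grace_days: int) -> set[int]:
    """Union of covered days for one product: [t, t+supply) joined across
    gaps <= grace, computed day by day."""
    covered: set[int] = set()
    for day, supply in scripts:
        covered.update(range(day, day + supply))
    # close gaps <= grace between consecutive covered runs
    days = sorted(covered)
    out = set(days)
    for a, b in zip(days[:-1], days[1:]):
        if 1 < b - a <= grace_days + 1:
            out.update(range(a + 1, b))
    return out


def ratchet_oracle(raw, interventions) -> list[int]:
    """Forward replay of the asymptomatic-correction rule."""
    out: list[int] = []
    cur = None
    hold_since = 0
    last_iv = -1
    for d, r in enumerate(raw):
        if interventions[d]:
            last_iv = d
        if cur is None:
            cur = r
        elif r == 1 and cur >= 2 and last_iv <= hold_since:
            pass
        elif r != cur:
            cur = r
            if cur >= 2:
                hold_since = d
        out.append(cur)
    return out
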