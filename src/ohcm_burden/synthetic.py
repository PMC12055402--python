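"""Seeded synthetic generator for CPRD/HES-like EHR extracts.

Each patient carries a latent NYHA severity path — a monthly Markov chain over
classes I–IV — and every observable stream (symptom codes, HCM-specific
prescriptions, consultations, hospital activity, clinical events) is drawn
with class-dependent rates.  The latent path and true event times are retained
as ground truth so downstream classifiers and estimators can be checked for
recovery.

Determinism: one global seed spawns per-patient ``numpy.random.SeedSequence``
children, so the same (config, seed) pair always regenerates byte-identical
tables and any single patient can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import resources
from ._util import DAYS_PER_YEAR, from_day
from .config import ConfigError, GeneratorConfig

MONTH_DAYS = 30  # latent-chain step on the day grid

_CONSULT_TYPES = {"gp", "nurse", "telephone", "out_of_hours"}
_HOSPITAL_TYPES = {"elective", "non_elective", "day_case", "outpatient", "ae", "critical_care"}
_INPATIENT_TYPES = {"elective", "non_elective", "day_case"}

PATIENT_COLUMNS = [
    "patient_id", "birth_year", "sex", "ethnicity", "reg_start", "reg_end",
    "practice_last_collection", "acceptable_quality", "linkage_eligible",
]


@dataclass
class SyntheticDataset:
    """Flat synthetic EHR tables plus per-patient latent ground truth."""

    patients: pd.DataFrame
    clinical_events: pd.DataFrame
    prescriptions: pd.DataFrame
    consultations: pd.DataFrame
    hospital_activity: pd.DataFrame
    deaths: pd.DataFrame
    truth_severity: pd.DataFrame  # patient_id, start, end, nyha_class (half-open)
    truth_events: pd.DataFrame    # patient_id, event, date
    config: GeneratorConfig = field(repr=False, default=None)

    TABLE_NAMES = (
        "patients", "clinical_events", "prescriptions", "consultations",
        "hospital_activity", "deaths", "truth_severity", "truth_events",
    )

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in self.TABLE_NAMES:
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)

    @classmethod
    def read(cls, in_dir) -> "SyntheticDataset":
        date_cols = {
            "patients": ["reg_start", "reg_end", "practice_last_collection"],
            "clinical_events": ["date"],
            "prescriptions": ["date"],
            "consultations": ["date"],
            "hospital_activity": ["admit_date", "discharge_date"],
            "deaths": ["date"],
            "truth_severity": ["start", "end"],
            "truth_events": ["date"],
        }
        tables = {}
        for name in cls.TABLE_NAMES:
            df = pd.read_csv(Path(in_dir) / f"{name}.csv")
            if "hrg_code" in df.columns:
                df["hrg_code"] = df["hrg_code"].fillna("")
            for col in date_cols[name]:
                if col in df.columns:
                    df[col] = pd.to_datetime(df[col])
            tables[name] = df
        return cls(**tables)


def simulate_severity_path(rng: np.random.Generator, n_days: int,
                           config: GeneratorConfig) -> np.ndarray:
    """Latent monthly NYHA path over a window of ``n_days`` days.

    Returns one class (1–4) per 30-day month; the step function is
    right-continuous on the day grid.  A zero-length window yields an empty
    path.
    """
    m = np.asarray(config.monthly_transition_matrix, dtype=float)
    if m.shape != (4, 4) or np.abs(m.sum(axis=1) - 1.0).max() > 1e-12:
        raise ConfigError("transition matrix must be 4x4 row-stochastic")
    n_months = -(-n_days // MONTH_DAYS) if n_days > 0 else 0
    path = np.empty(n_months, dtype=np.int64)
    if n_months == 0:
        return path
    cum0 = np.cumsum(config.initial_class_probs)
    cum = np.cumsum(m, axis=1)
    state = int(np.searchsorted(cum0, rng.random(), side="right"))
    u = rng.random(n_months)
    path[0] = state + 1
    for i in range(1, n_months):
        state = int(np.searchsorted(cum[state], u[i], side="right"))
        path[i] = state + 1
    return path


def _spells(path: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal class as (start_month, end_month, class)."""
    if len(path) == 0:
        return []
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(path)]))
    return [(int(s), int(e), int(path[s])) for s, e in zip(starts, ends)]


class _Accumulator:
    def __init__(self) -> None:
        self.rows: dict[str, list] = {
            name: [] for name in SyntheticDataset.TABLE_NAMES if name != "patients"
        }

    def add(self, table: str, **row) -> None:
        self.rows[table].append(row)


def emit_observations(patient_id: int, path: np.ndarray, reg_start_day: int,
                      reg_end_day: int, config: GeneratorConfig,
                      rng: np.random.Generator, acc: _Accumulator,
                      diag_day: int, subtype: str) -> None:
    """Emit one patient's observation rows given their latent path.

    Day offsets are absolute (days since study_start).  All rows fall inside
    the patient's registration window.
    """
    if len(path) == 0:
        return
    codelists = _CODELISTS
    n_months = len(path)
    month_start = reg_start_day + MONTH_DAYS * np.arange(n_months)
    month_end = np.minimum(month_start + MONTH_DAYS, reg_end_day)
    month_len = np.maximum(month_end - month_start, 0)
    cls_idx = path - 1  # 0-based

    def scatter(counts: np.ndarray) -> np.ndarray:
        """Random absolute days for per-month event counts."""
        months = np.repeat(np.arange(n_months), counts)
        offsets = rng.random(len(months)) * month_len[months]
        return (month_start[months] + offsets.astype(np.int64))

    # --- HCM diagnosis codes -------------------------------------------------
    vocab, code = _CODE[f"hcm_{subtype}"]
    acc.add("clinical_events", patient_id=patient_id, day=diag_day,
            vocabulary=vocab, code=code, setting="primary")
    if subtype == "obstructive" and rng.random() < config.prob_prior_nonobstructive:
        early = max(reg_start_day, diag_day - int(rng.integers(100, 600)))
        if early < diag_day:
            v2, c2 = _CODE["hcm_nonobstructive"]
            acc.add("clinical_events", patient_id=patient_id, day=early,
                    vocabulary=v2, code=c2, setting="primary")

    # --- symptoms ------------------------------------------------------------
    sym_rate = np.asarray(config.symptom_rate_by_class, dtype=float)[cls_idx]
    hits = rng.random(n_months) < sym_rate * (month_len / MONTH_DAYS)
    for day in scatter(hits.astype(np.int64)):
        n_concepts = 1 + int(rng.random() < 0.3)
        for concept in rng.choice(_SYMPTOM_CONCEPTS, size=n_concepts, replace=False):
            v, c = _CODE[concept]
            acc.add("clinical_events", patient_id=patient_id, day=int(day),
                    vocabulary=v, code=c, setting="primary")

    # --- prescriptions: HCM-specific therapy follows the latent class --------
    product_of = {
        "BB": rng.choice(["atenolol", "bisoprolol", "metoprolol"]),
        "CCB": rng.choice(["verapamil", "diltiazem"]),
        "disopyramide": "disopyramide",
    }
    for m0, m1, cls in _spells(path):
        policy = config.rx_policy_by_class[cls]
        u, csum = rng.random(), 0.0
        therapy: tuple[str, ...] = ()
        for tset, w in policy:
            csum += w
            if u < csum:
                therapy = tuple(tset)
                break
        start_day = int(month_start[m0])
        end_day = int(month_end[m1 - 1])
        if not config.rule_consistent and therapy and rng.random() < 0.10:
            # occasional within-class product churn to exercise switch detection
            if "BB" in therapy:
                product_of["BB"] = rng.choice(["atenolol", "bisoprolol", "metoprolol"])
        for day in range(start_day, end_day, 28):
            for tclass in therapy:
                acc.add("prescriptions", patient_id=patient_id, day=day,
                        product=str(product_of[tclass]), therapy_class=tclass,
                        days_supply=28)
        if cls == 4 and config.rule_consistent:
            # heart-failure hospitalization stream marks class IV for the proxy
            v, c = _CODE["heart_failure"]
            for day in range(start_day, end_day, 28):
                acc.add("clinical_events", patient_id=patient_id, day=day,
                        vocabulary=v, code=c, setting="secondary")

    # --- background cardiovascular prescribing -------------------------------
    if config.baseline_med_prob > 0 and rng.random() < config.baseline_med_prob:
        n_bg = 1 + int(rng.integers(0, 3))
        bg = rng.choice(["atorvastatin", "aspirin", "ramipril", "warfarin"],
                        size=n_bg, replace=False)
        drug_map = _DRUG_CLASS
        offset = int(rng.integers(0, 56))
        for day in range(reg_start_day + offset, reg_end_day, 56):
            for product in bg:
                acc.add("prescriptions", patient_id=patient_id, day=day,
                        product=str(product), therapy_class=drug_map[str(product)],
                        days_supply=56)

    # --- clinical events (ground truth retained) -----------------------------
    for event, rates in config.event_rates_by_class.items():
        lam = np.asarray(rates, dtype=float)[cls_idx] / 100.0 * month_len / DAYS_PER_YEAR
        counts = rng.poisson(lam)
        v, c = _CODE[event]
        setting = "secondary" if event == "heart_failure" else \
            ("secondary" if event in ("mi", "stroke", "cardiac_arrest") else "primary")
        for day in scatter(counts):
            acc.add("clinical_events", patient_id=patient_id, day=int(day),
                    vocabulary=v, code=c, setting=setting)
            acc.add("truth_events", patient_id=patient_id, event=event, day=int(day))

    # --- healthcare activity -------------------------------------------------
    hrg_codes = _HRG_CODES
    for category, rates in config.activity_rates_by_class.items():
        lam = np.asarray(rates, dtype=float)[cls_idx] * month_len / DAYS_PER_YEAR
        counts = rng.poisson(lam)
        days = scatter(counts)
        if category in _CONSULT_TYPES:
            for day in days:
                acc.add("consultations", patient_id=patient_id, day=int(day),
                        type=category)
        elif category in _HOSPITAL_TYPES:
            for day in days:
                los = int(rng.poisson(3)) + 1 if category in ("elective", "non_elective") else 0
                hrg = str(rng.choice(hrg_codes)) if category in _INPATIENT_TYPES else ""
                acc.add("hospital_activity", patient_id=patient_id, day=int(day),
                        discharge_day=int(min(day + los, reg_end_day)),
                        type=category, hrg_code=hrg)
        else:  # coded test/procedure
            v, c = _CODE[category]
            for day in days:
                acc.add("clinical_events", patient_id=patient_id, day=int(day),
                        vocabulary=v, code=c, setting="primary")

    # --- optional exclusion-condition noise ----------------------------------
    if not config.rule_consistent and rng.random() < 0.03:
        concept = str(rng.choice(["amyloidosis", "aortic_stenosis", "hypertensive_heart_disease"]))
        v, c = _CODE[concept]
        day = int(rng.integers(reg_start_day, reg_end_day))
        acc.add("clinical_events", patient_id=patient_id, day=day,
                vocabulary=v, code=c, setting="primary")

    # --- recorded NYHA codes -------------------------------------------------
    if config.prob_recorded_nyha > 0 and rng.random() < config.prob_recorded_nyha:
        month = min(int((diag_day - reg_start_day) // MONTH_DAYS), n_months - 1)
        v, c = _CODE[f"nyha_class_{int(path[month])}"]
        acc.add("clinical_events", patient_id=patient_id, day=diag_day,
                vocabulary=v, code=c, setting="primary")

    # --- death ---------------------------------------------------------------
    if config.death_rates_by_class is not None:
        hazard = np.asarray(config.death_rates_by_class, dtype=float)[cls_idx] \
            / 100.0 * month_len / DAYS_PER_YEAR
        dead = rng.random(n_months) < -np.expm1(-hazard)
        if dead.any():
            month = int(np.flatnonzero(dead)[0])
            day = int(month_start[month] + rng.integers(0, max(month_len[month], 1)))
            acc.add("deaths", patient_id=patient_id, day=day, cause_code="I42.1")


def generate_population(config: GeneratorConfig) -> SyntheticDataset:
    """Simulate ``config.n_patients`` independent patients."""
    if config.n_patients < 0:
        raise ConfigError("n_patients must be non-negative")
    study_start = pd.Timestamp(config.study_start)
    total_days = (pd.Timestamp(config.study_end) - study_start).days
    index_start_day = (pd.Timestamp(config.index_start) - study_start).days

    children = np.random.SeedSequence(config.seed).spawn(max(config.n_patients, 1))
    acc = _Accumulator()
    patient_rows = []
    for pid in range(config.n_patients):
        rng = np.random.default_rng(children[pid])
        reg_start_day = int(rng.integers(0, 4 * 365))
        reg_end_day = total_days
        # diagnosis: usually >=1y after registration and inside the index period
        lo = max(reg_start_day + 366, index_start_day)
        hi = max(total_days - 365, lo + 1)
        diag_day = int(rng.integers(lo, hi))
        if rng.random() < 0.05:  # short-registration patients (attrition fodder)
            diag_day = int(rng.integers(reg_start_day, reg_start_day + 366))
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 16, 95))
        birth_year = int((study_start + pd.Timedelta(days=diag_day)).year - age)
        sex = "M" if rng.random() < config.sex_fraction_male else "F"
        ethnicity = str(rng.choice(
            ["white", "asian", "black", "mixed", "other"],
            p=[0.791, 0.089, 0.063, 0.012, 0.045]))
        subtype = "obstructive" if rng.random() < config.frac_obstructive else \
            str(rng.choice(["nonobstructive", "unspecified"]))
        patient_rows.append(dict(
            patient_id=pid, birth_year=birth_year, sex=sex, ethnicity=ethnicity,
            reg_start_day=reg_start_day, reg_end_day=reg_end_day,
            acceptable_quality=int(rng.random() >= 0.02),
            linkage_eligible=int(rng.random() >= 0.03),
        ))
        path = simulate_severity_path(rng, reg_end_day - reg_start_day, config)
        emit_observations(pid, path, reg_start_day, reg_end_day, config, rng,
                          acc, diag_day, subtype)
        for m0, m1, cls in _spells(path):
            acc.add("truth_severity", patient_id=pid,
                    start_day=reg_start_day + m0 * MONTH_DAYS,
                    end_day=min(reg_start_day + m1 * MONTH_DAYS, reg_end_day),
                    nyha_class=cls)

    return _finalize(patient_rows, acc, config, study_start, total_days)


def _finalize(patient_rows, acc: _Accumulator, config, study_start, total_days
              ) -> SyntheticDataset:
    patients = pd.DataFrame(
        patient_rows,
        columns=["patient_id", "birth_year", "sex", "ethnicity", "reg_start_day",
                 "reg_end_day", "acceptable_quality", "linkage_eligible"],
    )
    patients["reg_start"] = from_day(patients["reg_start_day"], study_start)
    patients["reg_end"] = from_day(patients["reg_end_day"], study_start)
    patients["practice_last_collection"] = patients["reg_end"]
    patients = patients[PATIENT_COLUMNS]

    def table(name, day_cols, columns):
        df = pd.DataFrame(acc.rows[name])
        if df.empty:
            return pd.DataFrame(columns=columns)
        for day_col, date_col in day_cols.items():
            df[date_col] = from_day(df[day_col].to_numpy(), study_start)
        return df[columns]

    deaths = table("deaths", {"day": "date"}, ["patient_id", "date", "cause_code"])
    dataset = SyntheticDataset(
        patients=patients,
        clinical_events=table("clinical_events", {"day": "date"},
                              ["patient_id", "date", "vocabulary", "code", "setting"]),
        prescriptions=table("prescriptions", {"day": "date"},
                            ["patient_id", "date", "product", "therapy_class", "days_supply"]),
        consultations=table("consultations", {"day": "date"},
                            ["patient_id", "date", "type"]),
        hospital_activity=table("hospital_activity",
                                {"day": "admit_date", "discharge_day": "discharge_date"},
                                ["patient_id", "admit_date", "discharge_date", "type", "hrg_code"]),
        deaths=deaths,
        truth_severity=table("truth_severity", {"start_day": "start", "end_day": "end"},
                             ["patient_id", "start", "end", "nyha_class"]),
        truth_events=table("truth_events", {"day": "date"},
                           ["patient_id", "event", "date"]),
        config=config,
    )
    # censor all activity at death when the death process is on
    if not deaths.empty:
        death_date = deaths.set_index("patient_id")["date"]
        for name in ("clinical_events", "prescriptions", "consultations",
                     "hospital_activity", "truth_events"):
            df = getattr(dataset, name)
            col = "admit_date" if name == "hospital_activity" else "date"
            cutoff = df["patient_id"].map(death_date)
            keep = cutoff.isna() | (df[col] <= cutoff)
            setattr(dataset, name, df[keep].reset_index(drop=True))
    return dataset


def truth_trajectories(truth_severity: pd.DataFrame,
                       cohort: pd.DataFrame) -> pd.DataFrame:
    """Latent severity intervals clipped to each included patient's follow-up.

    Returns the NYHA-interval schema (patient_id, start, end, nyha_class,
    provenance='truth'), tiling [index, followup_end) exactly — the ground-
    truth counterpart of a classifier trajectory for recovery checks.
    """
    fu = cohort.loc[cohort["included"],
                    ["patient_id", "index_date", "followup_end"]]
    merged = truth_severity.merge(fu, on="patient_id", how="inner")
    start = merged[["start", "index_date"]].max(axis=1)
    end = merged[["end", "followup_end"]].min(axis=1)
    keep = start < end
    out = pd.DataFrame({
        "patient_id": merged.loc[keep, "patient_id"],
        "start": start[keep], "end": end[keep],
        "nyha_class": merged.loc[keep, "nyha_class"],
        "provenance": "truth",
    })
    return out.sort_values(["patient_id", "start"]).reset_index(drop=True)


# module-level lookup tables built once from the bundled resources
_CODELISTS = resources.default_codelists()
_CODE = {row.concept: (row.vocabulary, row.code)
         for row in _CODELISTS.itertuples()}
_SYMPTOM_CONCEPTS = np.array(sorted(
    _CODELISTS.loc[_CODELISTS["symptom"] != "", "concept"].unique()))
_DRUG_CLASS = dict(zip(resources.default_drug_map()["product"],
                       resources.default_drug_map()["therapy_class"]))
_HRG_CODES = resources.default_hrg_costs()["hrg_code"].to_numpy()
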