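"""Run configuration for the synthetic EHR generator.

The generator draws a latent NYHA severity path per patient (a monthly Markov
chain over classes I–IV) and emits coded observations — symptoms,
prescriptions, consultations, hospital activity, clinical events — whose rates
depend on the latent class.  The defaults below are the study conditions the
pipeline is exercised under: the baseline class mix, demographics and study
window follow the source cohort; transition and observation rates are chosen
once as plausible for a slowly progressive cardiomyopathy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

NYHA_CLASSES = (1, 2, 3, 4)

_DEFAULT_TRANSITION = (
    # monthly; progression-dominant, recovery to class I rare
    (0.975, 0.018, 0.006, 0.001),
    (0.003, 0.975, 0.020, 0.002),
    (0.001, 0.006, 0.980, 0.013),
    (0.000, 0.002, 0.018, 0.980),
)

_DEFAULT_RX_POLICY = {
    1: [((), 0.80), (("BB",), 0.20)],
    2: [(("BB",), 0.70), (("CCB",), 0.20), ((), 0.10)],
    3: [(("BB", "CCB"), 0.50), (("BB", "disopyramide"), 0.20), (("BB",), 0.20), (("CCB",), 0.10)],
    4: [(("BB", "CCB"), 0.60), (("BB", "CCB", "disopyramide"), 0.20), (("BB",), 0.20)],
}

_DEFAULT_EVENT_RATES = {
    # per 100 patient-years, by latent class I..IV
    "stroke": (2.0, 4.0, 8.0, 20.0),
    "af_flutter": (6.0, 8.0, 12.0, 19.0),
    "heart_failure": (2.0, 5.0, 10.0, 33.0),
    "mi": (3.0, 5.0, 9.0, 21.0),
}

_DEFAULT_ACTIVITY_RATES = {
    # per patient-year, by latent class I..IV
    "gp": (2.0, 3.0, 4.0, 6.0),
    "nurse": (1.0, 1.5, 2.0, 3.0),
    "telephone": (1.0, 1.5, 2.0, 3.0),
    "out_of_hours": (0.1, 0.2, 0.3, 0.5),
    "outpatient": (1.0, 2.0, 3.0, 5.0),
    "ae": (0.2, 0.4, 0.7, 1.5),
    "elective": (0.10, 0.20, 0.30, 0.50),
    "non_elective": (0.10, 0.20, 0.50, 1.20),
    "day_case": (0.20, 0.30, 0.40, 0.60),
    "critical_care": (0.01, 0.02, 0.05, 0.20),
    # coded tests/procedures (routed to clinical_events, costed separately)
    "echocardiogram": (0.30, 0.50, 0.80, 1.20),
    "ecg": (0.50, 1.00, 1.50, 2.00),
}

_DEFAULT_UNIT_COST_SEED = {
    "gp": 39.0, "nurse": 11.0, "telephone": 15.0, "outpatient": 150.0,
    "ae": 180.0, "critical_care": 1500.0,
}


class ConfigError(ValueError):
    """Invalid generator or run configuration."""


@dataclass
class GeneratorConfig:
    n_patients: int = 500
    study_start: str = "2007-04-01"
    study_end: str = "2020-10-30"
    index_start: str = "2009-04-01"  # earliest admissible index date (2y look-back)
    age_mean: float = 61.0
    age_sd: float = 15.6
    sex_fraction_male: float = 0.619
    frac_obstructive: float = 0.579
    initial_class_probs: Sequence[float] = (0.259, 0.339, 0.377, 0.025)
    monthly_transition_matrix: Sequence[Sequence[float]] = _DEFAULT_TRANSITION
    symptom_rate_by_class: Sequence[float] = (0.02, 0.12, 0.25, 0.45)
    rx_policy_by_class: Mapping[int, list] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_RX_POLICY.items()}
    )
    event_rates_by_class: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(_DEFAULT_EVENT_RATES)
    )
    activity_rates_by_class: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(_DEFAULT_ACTIVITY_RATES)
    )
    unit_cost_seed_table: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_UNIT_COST_SEED)
    )
    death_rates_by_class: Sequence[float] | None = None  # per 100 PY; None = off
    prob_recorded_nyha: float = 0.0  # chance a patient carries recorded NYHA codes
    prob_prior_nonobstructive: float = 0.05  # dual-coded patients (non-obs then obs)
    baseline_med_prob: float = 0.5  # chance of a background CV prescription stream
    rule_consistent: bool = False   # emit observations that encode the latent class exactly
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be non-negative")
        if pd.Timestamp(self.study_start) >= pd.Timestamp(self.study_end):
            raise ConfigError("study_start must precede study_end")
        p = np.asarray(self.initial_class_probs, dtype=float)
        if p.shape != (4,) or abs(p.sum() - 1.0) > 1e-12 or (p < 0).any():
            raise ConfigError("initial_class_probs must be a 4-vector summing to 1")
        m = np.asarray(self.monthly_transition_matrix, dtype=float)
        if m.shape != (4, 4) or (m < 0).any() or np.abs(m.sum(axis=1) - 1.0).max() > 1e-12:
            raise ConfigError("monthly_transition_matrix must be 4x4 row-stochastic")
        if (np.asarray(self.symptom_rate_by_class, dtype=float) < 0).any():
            raise ConfigError("symptom rates must be non-negative")
        for cls, policy in self.rx_policy_by_class.items():
            tot = sum(w for _, w in policy)
            if abs(tot - 1.0) > 1e-12:
                raise ConfigError(f"rx policy for class {cls} must sum to 1 (got {tot})")
        for name, rates in self.event_rates_by_class.items():
            if (np.asarray(rates, dtype=float) < 0).any():
                raise ConfigError(f"event rates for {name} must be non-negative")
        for name, rates in self.activity_rates_by_class.items():
            if (np.asarray(rates, dtype=float) < 0).any():
                raise ConfigError(f"activity rates for {name} must be non-negative")

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "rx_policy_by_class" in raw:
            raw["rx_policy_by_class"] = {
                int(k): [(tuple(sets), float(w)) for sets, w in v]
                for k, v in raw["rx_policy_by_class"].items()
            }
        return cls(**raw)


def rule_consistent_config(**overrides) -> GeneratorConfig:
    """Conditions under which observations encode the latent class exactly.

    Therapy per class is fixed (I: none, II: BB, III: BB+CCB, IV: BB+CCB plus a
    heart-failure hospitalization stream), symptoms and background prescribing
    are off, and the chain never returns to class I — so the proxy classifier's
    asymptomatic-correction ratchet cannot hold a stale class.  Transitions are
    rare, leaving the days'-supply/grace tail after a regimen step-down as the
    only source of classifier disagreement.
    """
    matrix = (
        (0.990, 0.008, 0.002, 0.000),
        (0.000, 0.992, 0.007, 0.001),
        (0.000, 0.004, 0.990, 0.006),
        (0.000, 0.000, 0.008, 0.992),
    )
    policy = {
        1: [((), 1.0)],
        2: [(("BB",), 1.0)],
        3: [(("BB", "CCB"), 1.0)],
        4: [(("BB", "CCB"), 1.0)],
    }
    cfg = GeneratorConfig(
        monthly_transition_matrix=matrix,
        rx_policy_by_class=policy,
        symptom_rate_by_class=(0.0, 0.0, 0.0, 0.0),
        baseline_med_prob=0.0,
        prob_recorded_nyha=0.0,
        prob_prior_nonobstructive=0.0,
        rule_consistent=True,
    )
    return cfg.with_(**overrides) if overrides else cfg
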