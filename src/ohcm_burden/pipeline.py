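"""End-to-end pipeline: simulate → cohort → NYHA → treatments → outcomes → costs → report.

Each stage is a pure function of the previous stages' tables; any failure
aborts with a stage-tagged error.  ``run_pipeline`` returns every artifact as
a DataFrame and optionally writes them as CSVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import costing, nyha, outcomes, reporting, resources, treatments
from ._util import DAYS_PER_YEAR
from .config import GeneratorConfig
from .synthetic import SyntheticDataset, generate_population

log = logging.getLogger("ohcm_burden")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: dict | None = None   # GeneratorConfig overrides; None -> ehr_dir
    ehr_dir: str | None = None
    grace_days: int = treatments.DEFAULT_GRACE_DAYS
    gap_days: int = treatments.DEFAULT_GAP_DAYS
    inflation_factor: float = 1.0
    incidence_method: str = "poisson_exact"
    missing_hrg_policy: str = "drop"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - stage-tagged rethrow
                raise StageError(name, exc) from exc
            return out
        return wrapped
    return deco


@_stage("simulate")
def _simulate(cfg: PipelineConfig) -> SyntheticDataset:
    if cfg.ehr_dir is not None:
        dataset = SyntheticDataset.read(cfg.ehr_dir)
    else:
        gen = GeneratorConfig(**{**(cfg.simulate or {}), "seed": cfg.seed})
        dataset = generate_population(gen)
    for name in SyntheticDataset.TABLE_NAMES:
        log.info("table %s: %d rows", name, len(getattr(dataset, name)))
    return dataset


def treatment_stage(dataset: SyntheticDataset, cohort: pd.DataFrame,
                    drug_map: pd.DataFrame, grace_days: int, gap_days: int
                    ) -> dict[str, pd.DataFrame]:
    """Per-patient regimens, initial treatment, first changes and risk curve."""
    included = cohort[cohort["included"]]
    rx_by_pid = dict(tuple(dataset.prescriptions.groupby("patient_id")))
    empty_rx = dataset.prescriptions.iloc[0:0]
    regimen_frames, initial_rows, change_rows, duration_rows = [], [], [], []
    for row in included.itertuples(index=False):
        rx = rx_by_pid.get(row.patient_id, empty_rx)
        rx = rx[(rx["date"] >= row.index_date) & (rx["date"] < row.followup_end)]
        exposure = treatments.build_exposure_intervals(rx, grace_days)
        regimens = treatments.derive_regimens(exposure, drug_map)
        label = treatments.initial_treatment(regimens, drug_map)
        initial_rows.append((row.patient_id, label))
        if regimens.empty:
            continue
        regimen_frames.append(regimens)
        change = treatments.detect_first_change(regimens, row.followup_end,
                                                drug_map, gap_days)
        start = regimens["start"].min()
        if change is not None:
            change_rows.append({"patient_id": row.patient_id, **change})
            duration = (change["date"] - start).days / DAYS_PER_YEAR
            duration_rows.append((row.patient_id, max(duration, 0.0), True))
        else:
            duration = (row.followup_end - start).days / DAYS_PER_YEAR
            duration_rows.append((row.patient_id, max(duration, 0.0), False))
    regimens = pd.concat(regimen_frames, ignore_index=True) if regimen_frames \
        else pd.DataFrame(columns=["patient_id", "start", "end", "products", "classes"])
    initial = pd.DataFrame(initial_rows, columns=["patient_id", "initial_treatment"])
    changes = pd.DataFrame(change_rows, columns=["patient_id", "date", "category",
                                                 "from_regimen", "to_regimen"])
    durations = pd.DataFrame(duration_rows,
                             columns=["patient_id", "years", "changed"])
    treated = int(initial["initial_treatment"].notna().sum())
    summary = treatments.change_summary(changes, treated) if treated else \
        pd.DataFrame(columns=["category", "n", "pct"])
    curve = treatments.cumulative_risk_curve(durations["years"],
                                             durations["changed"]) \
        if not durations.empty else pd.DataFrame(columns=["time", "risk", "n_at_risk"])
    return {"regimens": regimens, "initial_treatment": initial,
            "treatment_changes": changes, "change_summary": summary,
            "change_durations": durations, "cumulative_risk": curve}


def run_pipeline(config: PipelineConfig | dict | str | Path,
                 out_dir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Execute every stage; returns (and optionally writes) all artifacts."""
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig(**config)

    codelists = resources.default_codelists()
    drug_map = resources.default_drug_map()
    unit_costs = resources.default_unit_costs()
    hrg_costs = resources.default_hrg_costs()

    dataset = _simulate(config)

    cohort = _stage("build-cohort")(cohort_mod.build_cohort)(dataset, codelists)
    attrition = _stage("build-cohort")(cohort_mod.attrition_report)(cohort)
    annotated = cohort_mod.annotate_events(dataset.clinical_events, codelists)
    obstructive = cohort[cohort["included"] & (cohort["cohort"] == "obstructive")]
    log.info("cohort: %d identified, %d included, %d obstructive",
             len(cohort), int(cohort["included"].sum()), len(obstructive))

    trajectories = _stage("classify-nyha")(nyha.build_trajectories)(
        obstructive, annotated, dataset.prescriptions, drug_map)

    rx_arts = _stage("treatments")(treatment_stage)(
        dataset, obstructive, drug_map, config.grace_days, config.gap_days)

    events = _stage("outcomes")(outcomes.collect_events)(
        obstructive, annotated, deaths=dataset.deaths)
    slices, labelled = _stage("outcomes")(outcomes.split_person_time)(
        trajectories, events)
    incidence = _stage("outcomes")(outcomes.estimate_incidence)(
        slices, labelled, config.incidence_method)

    procedures = annotated[annotated["is_procedure"] == 1][
        ["patient_id", "date", "concept"]]
    activity = _stage("costs")(costing.count_activity)(
        dataset.consultations, dataset.hospital_activity, procedures, obstructive)
    items = pd.concat([
        _stage("costs")(costing.cost_non_inpatient)(
            activity, unit_costs, config.inflation_factor),
        _stage("costs")(costing.cost_inpatient)(
            activity, hrg_costs, config.missing_hrg_policy),
    ], ignore_index=True)
    costs = _stage("costs")(costing.stratified_costs)(items, trajectories)

    report = _stage("report")(_build_report)(obstructive, trajectories)

    artifacts = {
        "cohort": cohort, "attrition": attrition, "nyha_intervals": trajectories,
        **rx_arts, "events": events, "person_time": slices,
        "incidence": incidence, "costs": costs, **report,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dataset.write(out / "ehr")
        for name, df in artifacts.items():
            df.to_csv(out / f"{name}.csv", index=False)
        log.info("wrote %d artifacts to %s", len(artifacts) + 8, out)
    return artifacts


def _build_report(obstructive: pd.DataFrame, trajectories: pd.DataFrame
                  ) -> dict[str, pd.DataFrame]:
    if trajectories.empty:
        empty = pd.DataFrame()
        return {"nyha_distribution": empty, "nyha_distribution_suppressed": empty}
    by_patient = trajectories.sort_values("start").groupby("patient_id")
    baseline = by_patient["nyha_class"].first().value_counts().sort_index()
    end = by_patient["nyha_class"].last().value_counts().sort_index()
    pt = nyha.person_time_by_class(trajectories)
    dist = reporting.nyha_distribution_report(baseline, end, pt)
    counts = pd.DataFrame({
        "baseline": baseline.reindex([1, 2, 3, 4], fill_value=0),
        "end_of_followup": end.reindex([1, 2, 3, 4], fill_value=0),
    }).astype(int)
    state = reporting.suppress_small_cells(counts)
    return {"nyha_distribution": dist,
            "nyha_distribution_suppressed": reporting.render_suppressed(counts, state)}
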