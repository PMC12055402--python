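"""Bundled synthetic reference tables: codelists, drug map, cost tables.

These are deliberately small, synthetic stand-ins for the licensed UK coding
dictionaries (Read/SNOMED/ICD-10/OPCS codelists, BNF product lists, the NHS
National Schedule of unit costs and the HRG casemix tariff).  They carry the
*structure* the pipeline needs — concept flags, therapy classes, unit prices —
not clinically validated content.  Every table can be replaced by a user CSV
with the same columns.
"""

from __future__ import annotations

import pandas as pd

# ---------------------------------------------------------------------------
# Codelists
# ---------------------------------------------------------------------------

#: concept, vocabulary, code, hcm_subtype, is_exclusion, condition, symptom,
#: is_intervention, nyha_class (0 = not an NYHA record), is_procedure
_CODELIST_ROWS = [
    # HCM diagnoses
    ("hcm_obstructive", "ICD10", "I42.1", "obstructive", 0, "", "", 0, 0, 0),
    ("hcm_obstructive", "READ", "G554100", "obstructive", 0, "", "", 0, 0, 0),
    ("hcm_nonobstructive", "ICD10", "I42.2", "nonobstructive", 0, "", "", 0, 0, 0),
    ("hcm_nonobstructive", "READ", "G554200", "nonobstructive", 0, "", "", 0, 0, 0),
    ("hcm_unspecified", "READ", "G554z00", "unspecified", 0, "", "", 0, 0, 0),
    ("hcm_unspecified", "SNOMED", "233873004", "unspecified", 0, "", "", 0, 0, 0),
    # Exclusion conditions
    ("hypertensive_heart_disease", "ICD10", "I11", "", 1, "", "", 0, 0, 0),
    ("aortic_stenosis", "ICD10", "I35.0", "", 1, "", "", 0, 0, 0),
    ("athletes_heart", "READ", "ATHL001", "", 1, "", "", 0, 0, 0),
    ("storage_disease", "ICD10", "E74.8", "", 1, "", "", 0, 0, 0),
    ("takotsubo", "ICD10", "I42.8", "", 1, "", "", 0, 0, 0),
    ("anderson_fabry", "ICD10", "E75.2", "", 1, "", "", 0, 0, 0),
    ("pompe_disease", "ICD10", "E74.0", "", 1, "", "", 0, 0, 0),
    ("amyloidosis", "ICD10", "E85", "", 1, "", "", 0, 0, 0),
    # Symptoms used by the proxy NYHA algorithm
    ("breathlessness", "ICD10", "R06.0", "", 0, "", "breathlessness", 0, 0, 0),
    ("fatigue", "ICD10", "R53", "", 0, "", "fatigue", 0, 0, 0),
    ("oedema", "ICD10", "R60", "", 0, "", "oedema", 0, 0, 0),
    ("palpitations", "ICD10", "R00.2", "", 0, "", "palpitations", 0, 0, 0),
    ("dizziness", "ICD10", "R42", "", 0, "", "dizziness", 0, 0, 0),
    ("syncope", "ICD10", "R55", "", 0, "", "syncope", 0, 0, 0),
    ("chest_pain", "ICD10", "R07.4", "", 0, "", "chest_pain", 0, 0, 0),
    ("angina", "ICD10", "I20", "", 0, "", "angina", 0, 0, 0),
    ("presyncope", "READ", "PRESYN01", "", 0, "", "presyncope", 0, 0, 0),
    ("tachycardia", "ICD10", "R00.0", "", 0, "", "tachycardia", 0, 0, 0),
    # Baseline / outcome conditions
    ("asthma", "ICD10", "J45", "", 0, "asthma", "", 0, 0, 0),
    ("af_flutter", "ICD10", "I48", "", 0, "af_flutter", "", 0, 0, 0),
    ("cardiac_arrest", "ICD10", "I46", "", 0, "cardiac_arrest", "", 0, 0, 0),
    ("cardiac_dysrhythmias", "ICD10", "I49", "", 0, "cardiac_dysrhythmias", "", 0, 0, 0),
    ("ckd", "ICD10", "N18", "", 0, "ckd", "", 0, 0, 0),
    ("conduction_disorders", "ICD10", "I44", "", 0, "conduction_disorders", "", 0, 0, 0),
    ("copd", "ICD10", "J44", "", 0, "copd", "", 0, 0, 0),
    ("dvt_pe", "ICD10", "I26", "", 0, "dvt_pe", "", 0, 0, 0),
    ("depression", "ICD10", "F32", "", 0, "depression", "", 0, 0, 0),
    ("dilated_cardiomyopathy", "ICD10", "I42.0", "", 0, "dilated_cardiomyopathy", "", 0, 0, 0),
    ("heart_failure", "ICD10", "I50", "", 0, "heart_failure", "", 0, 0, 0),
    ("heart_transplant", "ICD10", "Z94.1", "", 0, "heart_transplant", "", 0, 0, 0),
    ("vad", "ICD10", "Z95.8", "", 0, "vad", "", 0, 0, 0),
    ("stroke", "ICD10", "I63", "", 0, "stroke", "", 0, 0, 0),
    ("tia", "ICD10", "G45", "", 0, "tia", "", 0, 0, 0),
    ("pvd", "ICD10", "I73", "", 0, "pvd", "", 0, 0, 0),
    ("ihd", "ICD10", "I25", "", 0, "ihd", "", 0, 0, 0),
    ("mi", "ICD10", "I21", "", 0, "mi", "", 0, 0, 0),
    ("ventricular_tachycardia", "ICD10", "I47.2", "", 0, "ventricular_tachycardia", "", 0, 0, 0),
    ("t1dm", "ICD10", "E10", "", 0, "t1dm", "", 0, 0, 0),
    ("t2dm", "ICD10", "E11", "", 0, "t2dm", "", 0, 0, 0),
    ("hypertension", "ICD10", "I10", "", 0, "hypertension", "", 0, 0, 0),
    ("hcm_family_history", "ICD10", "Z82.4", "", 0, "hcm_family_history", "", 0, 0, 0),
    # Interventions (release the asymptomatic-correction ratchet)
    ("srt", "OPCS", "K24.1", "", 0, "srt", "", 1, 0, 1),
    ("icd_insertion", "OPCS", "K59.1", "", 0, "icd_insertion", "", 1, 0, 1),
    ("pacemaker", "OPCS", "K60.1", "", 0, "pacemaker", "", 1, 0, 1),
    # Recorded NYHA class codes (rare in primary care, but authoritative)
    ("nyha_class_1", "READ", "662f.00", "", 0, "", "", 0, 1, 0),
    ("nyha_class_2", "READ", "662g.00", "", 0, "", "", 0, 2, 0),
    ("nyha_class_3", "READ", "662h.00", "", 0, "", "", 0, 3, 0),
    ("nyha_class_4", "READ", "662i.00", "", 0, "", "", 0, 4, 0),
    # Tests / procedures priced in the costing layer
    ("echocardiogram", "OPCS", "U20.1", "", 0, "", "", 0, 0, 1),
    ("ecg", "READ", "321..00", "", 0, "", "", 0, 0, 1),
    ("cardiac_mri", "OPCS", "U10.1", "", 0, "", "", 0, 0, 1),
]

_CODELIST_COLUMNS = [
    "concept", "vocabulary", "code", "hcm_subtype", "is_exclusion",
    "condition", "symptom", "is_intervention", "nyha_class", "is_procedure",
]


def default_codelists() -> pd.DataFrame:
    """Synthetic codelist table; one row per (vocabulary, code)."""
    df = pd.DataFrame(_CODELIST_ROWS, columns=_CODELIST_COLUMNS)
    df["is_hcm"] = (df["hcm_subtype"] != "").astype(int)
    return df


def code_for(concept: str, codelists: pd.DataFrame | None = None) -> tuple[str, str]:
    """First (vocabulary, code) pair for a concept — convenience for generators."""
    cl = default_codelists() if codelists is None else codelists
    row = cl[cl["concept"] == concept].iloc[0]
    return row["vocabulary"], row["code"]


# ---------------------------------------------------------------------------
# Drug map
# ---------------------------------------------------------------------------

_DRUG_ROWS = [
    # product, therapy_class, is_hcm_specific, is_non_dihydropyridine
    ("atenolol", "BB", 1, 0),
    ("bisoprolol", "BB", 1, 0),
    ("metoprolol", "BB", 1, 0),
    ("propranolol", "BB", 1, 0),
    ("verapamil", "CCB", 1, 1),
    ("diltiazem", "CCB", 1, 1),
    ("disopyramide", "disopyramide", 1, 0),
    ("amlodipine", "dihydropyridine_ccb", 0, 0),
    ("furosemide", "loop_diuretic", 0, 0),
    ("ramipril", "bp_lowering", 0, 0),
    ("atorvastatin", "statin", 0, 0),
    ("simvastatin", "statin", 0, 0),
    ("aspirin", "antiplatelet", 0, 0),
    ("clopidogrel", "antiplatelet", 0, 0),
    ("warfarin", "anticoagulant", 0, 0),
    ("amiodarone", "amiodarone", 0, 0),
]


def default_drug_map() -> pd.DataFrame:
    return pd.DataFrame(
        _DRUG_ROWS,
        columns=["product", "therapy_class", "is_hcm_specific", "is_non_dihydropyridine"],
    )


# ---------------------------------------------------------------------------
# Cost tables (synthetic unit costs in the spirit of the NHS National Schedule)
# ---------------------------------------------------------------------------

def default_unit_costs() -> pd.DataFrame:
    """activity category -> unit cost (GBP, reference year 2019/20)."""
    rows = [
        ("gp", 39.0, 2019),
        ("nurse", 11.0, 2019),
        ("telephone", 15.0, 2019),
        ("outpatient", 150.0, 2019),
        ("ae", 180.0, 2019),
        ("critical_care", 1500.0, 2019),
        ("echocardiogram", 80.0, 2019),
        ("ecg", 40.0, 2019),
        ("cardiac_mri", 350.0, 2019),
    ]
    return pd.DataFrame(rows, columns=["category", "unit_cost", "year"])


def default_hrg_costs() -> pd.DataFrame:
    """HRG currency code -> episode cost (GBP). Synthetic cardiac-flavoured codes."""
    rows = [
        ("EB03A", 4200.0),  # complex cardiac admission
        ("EB07B", 2600.0),  # heart-failure admission
        ("EB10C", 1800.0),  # arrhythmia admission
        ("EY50A", 900.0),   # cardiac day case
        ("EY51B", 650.0),   # minor day case
    ]
    return pd.DataFrame(rows, columns=["hrg_code", "cost"])


# ---------------------------------------------------------------------------
# Clinical-event rules (first-occurrence vs repeatable)
# ---------------------------------------------------------------------------

FIRST_ONLY_EVENTS = [
    "af_flutter", "cardiac_dysrhythmias", "conduction_disorders", "heart_failure",
    "dilated_cardiomyopathy", "all_cause_mortality", "icd_insertion", "pacemaker",
]
REPEATABLE_EVENTS = [
    "mi", "stroke", "ventricular_tachycardia", "srt", "dvt_pe", "cardiac_arrest",
]


# Classic Charlson weights restricted to the conditions this pipeline flags.
DEFAULT_CCI_WEIGHTS = {
    "mi": 1,
    "heart_failure": 1,
    "pvd": 1,
    "stroke": 1,
    "tia": 1,
    "copd": 1,
    "asthma": 1,
    "t1dm": 1,
    "t2dm": 1,
    "ckd": 2,
}
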