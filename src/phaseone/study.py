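"""Recorded inputs of the motivating phase I docetaxel + lycopene trial.

The trial escalated daily oral lycopene (30, 90, 150 mg/day) against a fixed
docetaxel backbone with a BMA-CRM design.  This module collects the design
constants, the published per-patient posterior trace, the reconstructed
enrollment sequence consistent with that trace, and the published paired
geometric means of the docetaxel exposure parameters.  These are the only
patient-level-free inputs the study provides; everything else in the package
is computed, or simulated by :mod:`phaseone.simulate`.

The enrollment sequence is a reconstruction, not a published listing: three
patients per cohort at levels 1 and 2 with no DLT, the remainder at level 3
with a single DLT carried by the 13th evaluable patient, and one
non-evaluable withdrawal (the patient absent from the published trace).  It
is the only assignment/outcome sequence consistent with the published
per-row "patients used" counts and estimates.
"""

from __future__ import annotations

from .crm import BmaCrmModel, ToxicityTally
from .trial import PatientRecord

__all__ = [
    "DOSE_GRID_MG",
    "SKELETONS",
    "TARGET_TOXICITY",
    "OVERDOSE_THRESHOLD",
    "default_model",
    "study_records",
    "FINAL_TALLY",
    "RECORDED_TRACE",
    "PK_GEOMETRIC_MEANS",
    "PK_PRINTED_RATIOS",
]

DOSE_GRID_MG = (30.0, 90.0, 150.0)
SKELETONS = ((0.05, 0.10, 0.20), (0.08, 0.20, 0.40))
TARGET_TOXICITY = 0.2
OVERDOSE_THRESHOLD = 0.85


def default_model(**overrides) -> BmaCrmModel:
    """The study's BMA-CRM design (optionally with configuration overrides)."""
    model = BmaCrmModel()
    return model.replace(**overrides) if overrides else model


def study_records() -> list[PatientRecord]:
    """Reconstructed enrollment sequence of the 18-patient escalation cohort.

    Patient 13 withdrew before DLT assessment and contributes no toxicity
    information; the single DLT (a pulmonary embolus at 150 mg/day) is
    carried by patient 14, the 13th evaluable patient.
    """
    records = []
    order = 0
    for pid in range(1, 19):
        order += 1
        level = 1 if pid <= 3 else 2 if pid <= 6 else 3
        records.append(
            PatientRecord(
                patient_id=str(pid),
                enrollment_order=order,
                dose_level=level,
                dlt=(pid == 14),
                evaluable=(pid != 13),
            )
        )
    return records


#: Final evaluable tally: 3 at level 1 (0 DLT), 3 at level 2 (0 DLT),
#: 11 at level 3 (1 DLT).
FINAL_TALLY = ToxicityTally((3, 3, 11), (0, 0, 1))

#: Published per-update posterior trace: (n_used, (n per dose), (DLT per
#: dose), published per-dose toxicity estimates).  Only rows at which the
#: published table shows a fresh computation are listed (the table repeats
#: stale rows inside completed cohorts).
RECORDED_TRACE = (
    (0, (0, 0, 0), (0, 0, 0), (0.065, 0.150, 0.300)),
    (1, (1, 0, 0), (0, 0, 0), (0.041, 0.116, 0.264)),
    (2, (2, 0, 0), (0, 0, 0), (0.029, 0.097, 0.242)),
    (3, (3, 0, 0), (0, 0, 0), (0.022, 0.085, 0.227)),
    (6, (3, 3, 0), (0, 0, 0), (0.006, 0.037, 0.147)),
    (9, (3, 3, 3), (0, 0, 0), (0.001, 0.009, 0.064)),
    (12, (3, 3, 6), (0, 0, 0), (0.000, 0.003, 0.037)),
    (13, (3, 3, 7), (0, 0, 1), (0.002, 0.023, 0.165)),
    (14, (3, 3, 8), (0, 0, 1), (0.001, 0.019, 0.149)),
    (15, (3, 3, 9), (0, 0, 1), (0.001, 0.016, 0.135)),
    (16, (3, 3, 10), (0, 0, 1), (0.001, 0.013, 0.124)),
    (17, (3, 3, 11), (0, 0, 1), (0.001, 0.011, 0.114)),
)

#: Published per-occasion geometric means of the docetaxel exposure
#: parameters (docetaxel alone vs docetaxel plus lycopene, n = 5 paired
#: subjects).  The published Cmax row repeats the AUC_last geometric means
#: while printing a different ratio; it is internally inconsistent and kept
#: here only so that the inconsistency can be demonstrated.
PK_GEOMETRIC_MEANS = {
    "auc_last": (2810.0, 2968.0),
    "auc_inf": (3024.0, 3311.0),
    "cmax": (2810.0, 2968.0),
}

#: Ratios as printed alongside the geometric means above.
PK_PRINTED_RATIOS = {"auc_last": 1.056, "auc_inf": 1.095, "cmax": 1.151}
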