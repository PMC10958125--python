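"""Sequential trial conduct: replay of a recorded enrollment and simulation.

``replay_trial`` regenerates the per-patient posterior trace from an ordered
enrollment record, exactly as the design would have computed it at the time;
``simulate_trial`` and ``operating_characteristics`` run the design forward
under a specified true dose-toxicity scenario.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crm import (
    BmaCrmModel,
    DoseDecision,
    ToxicityTally,
    bma_toxicity_estimates,
    next_dose,
    select_mtd,
    should_terminate,
)

__all__ = [
    "PatientRecord",
    "TraceRow",
    "EscalationTrace",
    "ScenarioSpec",
    "TrialResult",
    "OperatingCharacteristics",
    "replay_trial",
    "simulate_trial",
    "operating_characteristics",
    "read_trial_records",
    "write_trial_records",
    "write_trace",
]

log = logging.getLogger(__name__)

RECORD_COLUMNS = ["patient_id", "enrollment_order", "dose_level", "dlt", "evaluable"]


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    enrollment_order: int
    dose_level: int  # 1-based level in the dose grid
    dlt: bool
    evaluable: bool

    def __post_init__(self):
        if self.dose_level < 1:
            raise ValueError("dose_level is a 1-based grid index")
        if not self.evaluable and self.dlt:
            raise ValueError("a non-evaluable record carries no DLT information")


@dataclass(frozen=True)
class TraceRow:
    order: int          # enrollment order of the patient this row precedes; 0 = final row marker
    n_used: int         # evaluable patients contributing to the estimates
    pi_hat: tuple[float, ...]
    p_overdose_lowest: float
    assigned_level: int | None
    decision: str       # "assign", "final" or "terminate"


@dataclass(frozen=True)
class EscalationTrace:
    rows: tuple[TraceRow, ...]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = {"order": r.order, "n_used": r.n_used}
            rec.update({f"pi_hat_{j + 1}": v for j, v in enumerate(r.pi_hat)})
            rec["p_overdose_lowest"] = r.p_overdose_lowest
            rec["assigned_level"] = r.assigned_level
            rec["decision"] = r.decision
            recs.append(rec)
        return pd.DataFrame(recs)


@dataclass(frozen=True)
class ScenarioSpec:
    """True per-dose DLT probabilities for forward simulation."""

    true_toxicity: tuple[float, ...]
    max_patients: int = 18
    cohort_size: int = 3
    seed: int = 0

    def __post_init__(self):
        if any(not 0.0 <= p <= 1.0 for p in self.true_toxicity):
            raise ValueError("true toxicity probabilities must lie in [0,1]")
        if self.max_patients < self.cohort_size:
            raise ValueError("max_patients must be at least one cohort")


@dataclass(frozen=True)
class TrialResult:
    trace: EscalationTrace
    tally: ToxicityTally
    mtd: DoseDecision          # terminate=True when the trial stopped early
    terminated_early: bool


@dataclass(frozen=True)
class OperatingCharacteristics:
    selection_frequency: tuple[float, ...]   # per dose level
    termination_frequency: float
    mean_patients: tuple[float, ...]         # per dose level
    mean_dlt: float
    n_sim: int


def _estimate_row(model: BmaCrmModel, tally: ToxicityTally, order: int,
                  assigned: int | None, decision: str) -> TraceRow:
    s = bma_toxicity_estimates(model, tally)
    return TraceRow(
        order=order,
        n_used=tally.n_patients,
        pi_hat=s.pi_hat,
        p_overdose_lowest=s.p_lowest_overdose,
        assigned_level=assigned,
        decision=decision,
    )


def replay_trial(model: BmaCrmModel, records: list[PatientRecord],
                 cadence: str = "per-patient") -> EscalationTrace:
    """Regenerate the escalation trace from an ordered enrollment record.

    Row ``i`` reports the estimates available when patient ``i`` enrolled,
    i.e. computed from the evaluable records preceding that patient; a final
    row uses all evaluable records.  With ``cadence="per-cohort"`` the
    estimates are refreshed only when a multiple of ``model.cohort_size``
    evaluable outcomes has accumulated, mirroring designs that re-estimate
    at cohort boundaries; rows in between repeat the last refresh.

    Dose assignments in the record are audited against the no-skipping
    constraint; violations are logged, not fatal.
    """
    if cadence not in ("per-patient", "per-cohort"):
        raise ValueError("cadence must be 'per-patient' or 'per-cohort'")
    records = sorted(records, key=lambda r: r.enrollment_order)
    tally = ToxicityTally.empty(model.n_doses)
    highest = 0
    rows: list[TraceRow] = []
    last_row: TraceRow | None = None
    for rec in records:
        if rec.dose_level > model.n_doses:
            raise ValueError(f"record {rec.patient_id}: dose level outside the grid")
        if rec.dose_level > highest + 1:
            log.warning(
                "record %s assigned level %d, skipping over untried level %d",
                rec.patient_id, rec.dose_level, highest + 1,
            )
        fresh = (
            cadence == "per-patient"
            or last_row is None
            or tally.n_patients % model.cohort_size == 0
        )
        if fresh:
            row = _estimate_row(model, tally, rec.enrollment_order, rec.dose_level, "assign")
        else:
            row = TraceRow(rec.enrollment_order, last_row.n_used, last_row.pi_hat,
                           last_row.p_overdose_lowest, rec.dose_level, "assign")
        rows.append(row)
        if fresh:
            last_row = row
        highest = max(highest, rec.dose_level)
        if rec.evaluable:
            tally = tally.add(rec.dose_level - 1, rec.dlt)
    rows.append(_estimate_row(model, tally, 0, None, "final"))
    return EscalationTrace(tuple(rows))


def simulate_trial(model: BmaCrmModel, scenario: ScenarioSpec,
                   rng: np.random.Generator | None = None) -> TrialResult:
    """Run one trial forward under the scenario's true dose-toxicity curve.

    Cohorts are assigned by the design's dose-assignment rule; DLTs are
    independent Bernoulli draws at the assigned dose's true probability.
    The same seed yields an identical trial.
    """
    if len(scenario.true_toxicity) != model.n_doses:
        raise ValueError("scenario must give a true toxicity per dose level")
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    tally = ToxicityTally.empty(model.n_doses)
    rows: list[TraceRow] = []
    highest: int | None = None
    order = 0
    terminated = False
    while tally.n_patients < scenario.max_patients:
        decision = next_dose(model, tally, highest)
        if decision.terminate:
            terminated = True
            rows.append(_estimate_row(model, tally, order + 1, None, "terminate"))
            break
        level = decision.dose_level
        assert level is not None
        size = min(scenario.cohort_size, scenario.max_patients - tally.n_patients)
        for _ in range(size):
            order += 1
            rows.append(_estimate_row(model, tally, order, level, "assign"))
            dlt = bool(rng.random() < scenario.true_toxicity[level - 1])
            tally = tally.add(level - 1, dlt)
        highest = level if highest is None else max(highest, level)
    if not terminated:
        mtd = select_mtd(model, tally)
        terminated = mtd.terminate
        rows.append(_estimate_row(model, tally, 0, None,
                                  "terminate" if terminated else "final"))
    else:
        mtd = DoseDecision(terminate=True)
    return TrialResult(EscalationTrace(tuple(rows)), tally, mtd, terminated)


def operating_characteristics(model: BmaCrmModel, scenario: ScenarioSpec,
                              n_sim: int) -> OperatingCharacteristics:
    """Aggregate ``n_sim`` independent simulated trials.

    Per-replicate generators are spawned from a master ``SeedSequence`` so
    replicates are statistically independent yet individually reproducible.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be at least 1")
    master = np.random.SeedSequence(scenario.seed)
    children = master.spawn(n_sim)
    K = model.n_doses
    selected = np.zeros(K)
    terminated = 0
    patients = np.zeros(K)
    dlts = 0.0
    for child in children:
        result = simulate_trial(model, scenario, rng=np.random.default_rng(child))
        if result.terminated_early:
            terminated += 1
        else:
            selected[result.mtd.dose_level - 1] += 1
        patients += np.asarray(result.tally.n, dtype=float)
        dlts += result.tally.n_dlt
    return OperatingCharacteristics(
        selection_frequency=tuple(selected / n_sim),
        termination_frequency=terminated / n_sim,
        mean_patients=tuple(patients / n_sim),
        mean_dlt=dlts / n_sim,
        n_sim=n_sim,
    )


# ---------------------------------------------------------------------------
# delimited-text IO
# ---------------------------------------------------------------------------

def read_trial_records(path, n_doses: int | None = None) -> list[PatientRecord]:
    """Read enrollment records from delimited text.

    Expected header: ``patient_id,enrollment_order,dose_level,dlt,evaluable``
    with the booleans encoded 0/1.  Errors name the offending line.
    """
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    records = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        for flag in ("dlt", "evaluable"):
            if row[flag] not in (0, 1):
                raise ValueError(f"{path}, line {line}: {flag} must be 0 or 1, got {row[flag]!r}")
        level = int(row["dose_level"])
        if n_doses is not None and not 1 <= level <= n_doses:
            raise ValueError(
                f"{path}, line {line}: dose_level {level} outside the {n_doses}-dose grid"
            )
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                enrollment_order=int(row["enrollment_order"]),
                dose_level=level,
                dlt=bool(row["dlt"]),
                evaluable=bool(row["evaluable"]),
            )
        )
    return records


def write_trial_records(records: list[PatientRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "enrollment_order": r.enrollment_order,
                "dose_level": r.dose_level,
                "dlt": int(r.dlt),
                "evaluable": int(r.evaluable),
            }
            for r in records
        ],
        columns=RECORD_COLUMNS,
    )
    df.to_csv(path, index=False)


def write_trace(trace: EscalationTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False)
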