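"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the motivating study's data-generating conditions:

* Bernoulli DLT outcomes under a monotone true dose-toxicity curve;
* docetaxel-like concentration–time profiles from a two-compartment model
  with a 1-hour constant-rate infusion, sampled at the protocol times with
  multiplicative lognormal residual error and an LLOQ cut;
* dose-group-dependent biomarker trajectories: plasma lycopene rising to a
  dose-independent plateau (faster at higher dose), VEGF-A log-slope
  flipping sign across the dose groups (negative at 30, flat at 90,
  positive at 150 mg/day), a transient circulating-endothelial-cell
  excursion peaking near day 57 (a nadir in the 30 mg/day group), a late
  decline of the ligand-dependent IGF-1R phosphorylation ratio at the top
  dose only, and PSA series declining toward a subject-specific nadir.

Every generator is a pure function of its parameters and seed; lognormal
noise is used throughout because concentrations and biomarker levels are
positive and right-skewed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .correlative import BiomarkerSeries, PhosphoAssay, PsaSeries, PROTOCOL_DAYS
from .nca import ConcentrationProfile, profiles_to_frame
from .trial import PatientRecord, ScenarioSpec, write_trial_records
from . import study

__all__ = [
    "PkSimParams",
    "BiomarkerSimParams",
    "PROTOCOL_TIMES_H",
    "two_compartment_infusion_concentration",
    "generate_dlt_outcomes",
    "generate_pk_profiles",
    "generate_biomarker_panel",
    "generate_trial_dataset",
]

#: Protocol sampling times in hours after the start of the 1-h infusion.
PROTOCOL_TIMES_H = (0.0, 0.5, 0.75, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)


@dataclass(frozen=True)
class PkSimParams:
    """Two-compartment infusion parameters, docetaxel-like by default.

    Defaults give central exposure in the low-thousands ng·h/mL at a
    75 mg/m²-scale dose (illustrative population values, not fitted to any
    patient data).  ``occasion_ratio`` multiplies the exposure on the
    combination occasion (the paired-design effect size);
    ``between_subject_cv`` is the lognormal CV of clearance across
    subjects (shared between a subject's two occasions).
    """

    clearance_l_h: float = 45.0
    v_central_l: float = 8.0
    v_peripheral_l: float = 35.0
    q_intercomp_l_h: float = 13.0
    infusion_h: float = 1.0
    dose_mg: float = 140.0
    residual_cv: float = 0.20
    between_subject_cv: float = 0.30
    occasion_ratio: float = 1.10
    lloq_ng_ml: float = 8.5

    def __post_init__(self):
        for name in ("clearance_l_h", "v_central_l", "v_peripheral_l",
                     "q_intercomp_l_h", "infusion_h", "dose_mg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.residual_cv < 1:
            raise ValueError("residual CV must lie in [0,1)")
        if self.occasion_ratio <= 0:
            raise ValueError("occasion_ratio must be positive")


def two_compartment_infusion_concentration(
    times_h, params: PkSimParams, clearance_l_h: float | None = None
) -> np.ndarray:
    """Noiseless central concentration (ng/mL) under constant-rate infusion.

    Closed-form solution of the linear two-compartment system via
    eigendecomposition of the 2×2 micro-rate matrix; valid during and after
    the infusion.  Dose in mg over ``infusion_h`` hours gives ng/mL when
    volumes are litres (mg/L ≡ µg/mL; the factor 1000 converts to ng/mL).
    """
    cl = params.clearance_l_h if clearance_l_h is None else clearance_l_h
    k10 = cl / params.v_central_l
    k12 = params.q_intercomp_l_h / params.v_central_l
    k21 = params.q_intercomp_l_h / params.v_peripheral_l
    M = np.array([[-(k10 + k12), k21], [k12, -k21]])
    lam, P = np.linalg.eig(M)
    Pinv = np.linalg.inv(P)
    rate = params.dose_mg / params.infusion_h  # mg/h into the central compartment
    u = np.array([rate, 0.0])

    t = np.asarray(times_h, dtype=float)
    tau = np.minimum(t, params.infusion_h)

    # during infusion: A(tau) = P diag((exp(lam*tau)-1)/lam) Pinv u
    phi = (np.exp(np.outer(tau, lam)) - 1.0) / lam  # (nt, 2)
    a_inf = np.einsum("ij,tj,jk,k->ti", P, phi, Pinv, u)
    # after the infusion: propagate A(T) by exp(M (t-T))
    dt = np.clip(t - params.infusion_h, 0.0, None)
    prop = np.exp(np.outer(dt, lam))
    a = np.einsum("ij,tj,jk,tk->ti", P, prop, Pinv, a_inf)
    conc_mg_l = a[:, 0] / params.v_central_l
    return np.maximum(conc_mg_l.real, 0.0) * 1000.0


def generate_dlt_outcomes(scenario: ScenarioSpec, assignments, seed: int) -> list[PatientRecord]:
    """Independent Bernoulli DLT flags for the given 1-based dose assignments."""
    rng = np.random.default_rng(seed)
    records = []
    for i, level in enumerate(assignments, start=1):
        p = scenario.true_toxicity[int(level) - 1]
        records.append(
            PatientRecord(
                patient_id=str(i),
                enrollment_order=i,
                dose_level=int(level),
                dlt=bool(rng.random() < p),
                evaluable=True,
            )
        )
    return records


def generate_pk_profiles(
    params: PkSimParams,
    n_subjects: int = 6,
    occasions: tuple[str, str] = ("alone", "combination"),
    times=PROTOCOL_TIMES_H,
    seed: int = 0,
) -> list[ConcentrationProfile]:
    """Paired two-occasion concentration profiles with lognormal noise.

    The combination occasion's exposure is multiplied by
    ``params.occasion_ratio`` (applied to the whole curve); each subject
    carries a lognormal clearance deviate shared across occasions, so the
    paired design cancels it.  Samples below the LLOQ are flagged BLQ.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    profiles = []
    sd_bsv = math.sqrt(math.log(1 + params.between_subject_cv ** 2))
    sd_res = math.sqrt(math.log(1 + params.residual_cv ** 2))
    for s in range(1, n_subjects + 1):
        cl_s = params.clearance_l_h * float(
            np.exp(rng.normal(-0.5 * sd_bsv ** 2, sd_bsv))
        ) if params.between_subject_cv > 0 else params.clearance_l_h
        base = two_compartment_infusion_concentration(t, params, clearance_l_h=cl_s)
        for occ in occasions:
            mult = params.occasion_ratio if occ == occasions[1] else 1.0
            curve = base * mult
            if params.residual_cv > 0:
                curve = curve * np.exp(rng.normal(0.0, sd_res, size=len(t)))
            conc = np.where(curve >= params.lloq_ng_ml, curve, np.nan)
            profiles.append(
                ConcentrationProfile(
                    subject=f"S{s:02d}",
                    occasion=occ,
                    times=tuple(t),
                    concentrations=tuple(conc),
                    dose_mg=params.dose_mg,
                    lloq=params.lloq_ng_ml,
                )
            )
    return profiles


@dataclass(frozen=True)
class BiomarkerSimParams:
    """Per-dose-group trajectory parameters for the biomarker panel.

    Keys of the per-group mappings are dose groups in mg/day.  Amplitudes
    are positive; ``cec_direction`` carries the sign of the transient
    excursion (a nadir in the lowest group, a peak above it).
    """

    dose_groups: tuple[float, ...] = (30.0, 90.0, 150.0)
    # plasma lycopene (µmol/L): common plateau, dose-dependent rise rate /day
    lycopene_baseline: float = 0.48
    lycopene_plateau_gain: float = 0.40
    lycopene_rise_per_day: dict = field(
        default_factory=lambda: {30.0: 0.02, 90.0: 0.045, 150.0: 0.07}
    )
    # VEGF-A (pg/mL): baseline and log-slope per day, sign flips across dose
    vegf_baseline: float = 352.9
    vegf_log_slope_per_day: dict = field(
        default_factory=lambda: {30.0: -0.004, 90.0: 0.0, 150.0: 0.004}
    )
    # CECs (cells/4 mL): transient log-scale excursion
    cec_baseline: float = 788.0
    cec_peak_day: float = 57.0
    cec_width_days: float = 25.0
    cec_amplitude: dict = field(
        default_factory=lambda: {30.0: 0.35, 90.0: 0.55, 150.0: 0.40}
    )
    cec_direction: dict = field(
        default_factory=lambda: {30.0: -1.0, 90.0: 1.0, 150.0: 1.0}
    )
    # ligand-dependent pIGF-1R(Y1131) stimulation ratio
    phospho_baseline_ratio: float = 10.9
    phospho_baseline_sdlog: float = 0.8
    phospho_decline_onset_day: float = 57.0
    phospho_decline_per_day: dict = field(
        default_factory=lambda: {30.0: 0.0, 90.0: 0.0, 150.0: 0.012}
    )
    # PSA (µg/L)
    psa_baseline_median: float = 19.2
    psa_baseline_sdlog: float = 1.4
    psa_nadir_fraction_median: float = 0.27
    psa_nadir_fraction_sdlog: float = 1.0
    noise_cv: float = 0.15

    def __post_init__(self):
        if any(v <= 0 for v in self.cec_amplitude.values()):
            raise ValueError("CEC amplitudes must be positive")
        if self.lycopene_plateau_gain <= 0:
            raise ValueError("lycopene plateau gain must be positive")


def _lognoise(rng, cv, size=None):
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sd = math.sqrt(math.log(1 + cv ** 2))
    return np.exp(rng.normal(-0.5 * sd ** 2, sd, size=size))


def generate_biomarker_panel(
    params: BiomarkerSimParams,
    n_per_group: dict | int = 4,
    days=PROTOCOL_DAYS,
    seed: int = 0,
):
    """Longitudinal biomarker panel for all dose groups.

    Returns ``(biomarker_series, phospho_assays, psa_series)``.  Trajectory
    shapes are deterministic per group; subject-level lognormal noise with
    CV ``params.noise_cv`` multiplies every observation (``noise_cv = 0``
    gives the exact group-level curves).
    """
    rng = np.random.default_rng(seed)
    if isinstance(n_per_group, int):
        n_per_group = {g: n_per_group for g in params.dose_groups}
    days = np.asarray(days, dtype=float)
    series: list[BiomarkerSeries] = []
    phospho: list[PhosphoAssay] = []
    psa: list[PsaSeries] = []
    sid = 0
    for group in params.dose_groups:
        for _ in range(int(n_per_group[group])):
            sid += 1
            subject = f"B{sid:02d}"
            elapsed = days - days[0]  # treatment exposure in days since baseline

            rise = params.lycopene_rise_per_day[group]
            lyco = params.lycopene_baseline + params.lycopene_plateau_gain * (
                1.0 - np.exp(-rise * elapsed)
            )
            lyco = lyco * _lognoise(rng, params.noise_cv, len(days))

            vegf = params.vegf_baseline * np.exp(
                params.vegf_log_slope_per_day[group] * elapsed
            ) * _lognoise(rng, params.noise_cv, len(days))

            bump = params.cec_direction[group] * params.cec_amplitude[group] * np.exp(
                -(((days - params.cec_peak_day) / params.cec_width_days) ** 2)
            )
            bump[0] = 0.0  # baseline is by definition the pre-treatment level
            cec = params.cec_baseline * np.exp(bump) * _lognoise(rng, params.noise_cv, len(days))

            for analyte, values in (("lycopene", lyco), ("vegf_a", vegf), ("cec", cec)):
                series.append(
                    BiomarkerSeries(subject=subject, dose_group_mg=group,
                                    analyte=analyte, days=tuple(int(d) for d in days),
                                    values=tuple(float(v) for v in values))
                )

            base_ratio = params.phospho_baseline_ratio * float(
                np.exp(rng.normal(-0.5 * params.phospho_baseline_sdlog ** 2,
                                  params.phospho_baseline_sdlog))
            )
            decline = params.phospho_decline_per_day[group]
            for d in days:
                fold = math.exp(-decline * max(0.0, d - params.phospho_decline_onset_day))
                unstim = 1.0 * float(_lognoise(rng, params.noise_cv))
                stim = unstim * base_ratio * fold * float(_lognoise(rng, params.noise_cv))
                phospho.append(
                    PhosphoAssay(subject=subject, day=int(d),
                                 stimulated=stim, unstimulated=unstim)
                )

            base_psa = params.psa_baseline_median * float(
                np.exp(rng.normal(0.0, params.psa_baseline_sdlog))
            )
            frac = min(3.0, float(
                np.exp(rng.normal(math.log(params.psa_nadir_fraction_median),
                                  params.psa_nadir_fraction_sdlog))
            ))
            follow_days = elapsed[1:]
            traj = base_psa * frac ** (follow_days / follow_days[-1])
            traj = traj * _lognoise(rng, params.noise_cv, len(traj))
            psa.append(PsaSeries(subject=subject, baseline=base_psa,
                                 follow_up=tuple(float(v) for v in traj)))
    return series, phospho, psa


def generate_trial_dataset(master_seed: int = 0, out_dir=None) -> dict:
    """One coherent end-to-end fixture bundle from a single master seed.

    Contains the recorded-study replay fixture (deterministic), simulated PK
    and biomarker tables, and the model/scenario configuration documents.
    With ``out_dir`` set, also writes the bundle as CSV/JSON files.
    """
    ss = np.random.SeedSequence(master_seed)
    pk_seed, bio_seed = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(2)]

    model = study.default_model()
    records = study.study_records()
    pk_params = PkSimParams()
    profiles = generate_pk_profiles(pk_params, seed=pk_seed)
    bio_params = BiomarkerSimParams()
    series, phospho, psa = generate_biomarker_panel(
        bio_params, n_per_group={30.0: 3, 90.0: 3, 150.0: 12}, seed=bio_seed
    )
    scenario = ScenarioSpec(true_toxicity=(0.05, 0.10, 0.20), seed=master_seed)

    bundle = {
        "model": model,
        "records": records,
        "scenario": scenario,
        "pk_params": pk_params,
        "profiles": profiles,
        "biomarkers": series,
        "phospho": phospho,
        "psa": psa,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        model.to_json(out / "model.json")
        write_trial_records(records, out / "trial.csv")
        profiles_to_frame(profiles).to_csv(out / "pk.csv", index=False)
        pd.DataFrame(
            [
                {"subject": s.subject, "dose_group": s.dose_group_mg,
                 "analyte": s.analyte, "day": d, "value": v}
                for s in series
                for d, v in zip(s.days, s.values)
            ]
        ).to_csv(out / "biomarkers.csv", index=False)
        pd.DataFrame(
            [
                {"subject": a.subject, "day": a.day,
                 "stimulated": a.stimulated, "unstimulated": a.unstimulated}
                for a in phospho
            ]
        ).to_csv(out / "phospho.csv", index=False)
        pd.DataFrame(
            [
                {"subject": p.subject, "baseline": p.baseline,
                 **{f"fu_{i + 1}": v for i, v in enumerate(p.follow_up)}}
                for p in psa
            ]
        ).to_csv(out / "psa.csv", index=False)
        import json as _json
        with open(out / "scenario.json", "w") as fh:
            _json.dump(
                {"true_toxicity": list(scenario.true_toxicity),
                 "max_patients": scenario.max_patients,
                 "cohort_size": scenario.cohort_size,
                 "seed": scenario.seed},
                fh, indent=2,
            )
    return bundle
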