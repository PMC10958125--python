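# phaseone

Dose-finding, pharmacokinetic and correlative-statistics machinery for a
phase I trial of daily oral lycopene combined with fixed-dose docetaxel in
metastatic prostate cancer, rebuilt as a tested, reusable Python package.
It is aimed at trial statisticians and pharmacometricians who want to
replay, audit or simulate this class of design rather than re-derive it ad
hoc.

## What it implements

**Bayesian model-averaging continual reassessment method (BMA-CRM).**
The dose-toxicity model is the one-parameter power model

    π_{k,j} = p_{k,j}^{exp(α)},      α ~ N(0, σ²),

where `p_{k,j}` is skeleton *k*'s prior DLT probability at dose level *j*
(defaults: skeletons (.05, .10, .20) and (.08, .20, .40) over
{30, 90, 150} mg/day). Each skeleton's posterior is computed by
deterministic trapezoidal quadrature; posterior model probabilities
`w_k ∝ P(M_k)·∫L_k(α)φ(α)dα` average the per-model curves into
`π̂_j = Σ_k w_k p_{k,j}^{exp(α̂_k)}`. The next cohort receives the dose with
`π̂_j` closest to the target rate φ = .20 (no skipping of untried levels);
the trial stops early if `Pr(π₁ > φ | data) > .85`; the MTD is the highest
dose whose final estimate is closest to φ. `phaseone.trial` replays a
recorded enrollment or simulates operating characteristics under arbitrary
true dose-toxicity scenarios.

**Non-compartmental PK + paired geometric-mean ratio.** Cmax/Tmax,
linear and linear-up/log-down trapezoidal AUC to the last quantifiable
sample, terminal slope λz by best-adjusted-R² log-linear regression,
extrapolated AUC∞ = AUC_last + C_last/λz, dose normalisation, and the
paired crossover comparison `GMR = exp(mean(log x_combo − log x_alone))`
with a log-scale t interval.

**Correlative statistics.** Baseline fold-change normalisation of
longitudinal biomarkers (VEGF-A, circulating endothelial cells, plasma
lycopene), the ligand-dependent IGF-1R(Y1131) phosphorylation ratio
(stimulated/unstimulated), one-sided paired t, exact Wilcoxon signed-rank
(full sign enumeration with midranked ties, n ≤ 25), and the ≥50% PSA
decline response rule.

**Synthetic data.** Seeded generators for every input: Bernoulli DLT
outcomes, two-compartment 1-h-infusion docetaxel-like profiles with
lognormal error and an LLOQ cut, and dose-group-dependent biomarker
trajectories. See `docs/methods.md` for the model details and defaults.

## Worked example

```python
from phaseone import study
from phaseone.crm import ToxicityTally, bma_toxicity_estimates, select_mtd
from phaseone.calibration import calibrate_estimator
from phaseone.trial import replay_trial

model = study.default_model()

# zero-data (prior) estimates: the equal-weight skeleton average
print(bma_toxicity_estimates(model, ToxicityTally.empty(3)).pi_hat)
# (0.065, 0.15, 0.3)

# calibrate the point-estimator convention against the recorded trace,
# then replay the reconstructed 18-patient enrollment
cal = calibrate_estimator()
print(cal.best.estimator, cal.best.alpha_prior_sd, round(cal.best.max_abs_deviation, 4))
# plugin-mode 0.85 0.0239
trace = replay_trial(cal.calibrated_model(), study.study_records())
print([round(v, 3) for v in trace.rows[-1].pi_hat])
# [0.008, 0.03, 0.104]

# MTD on the final tally (3+3+11 evaluable patients, one DLT at the top dose)
print(select_mtd(model, study.FINAL_TALLY))
# DoseDecision(terminate=False, dose_level=3, dose=150.0)
```

The prior row is the analytic skeleton average; the calibration scan
reports the estimator convention closest to the recorded per-patient
estimates together with its worst deviation; and the final-tally selection
returns 150 mg/day, the dose whose estimated DLT probability is nearest
the .20 target.

A command-line interface wraps the same functions:

```sh
phaseone synth --seed 42 --out fixtures/          # synthetic input bundle
phaseone replay --records fixtures/trial.csv --out trace.csv
phaseone simulate --scenario fixtures/scenario.json --nsim 1000 --seed 7 --out oc.json
phaseone nca --in fixtures/pk.csv --out results/
phaseone correlate --in fixtures/biomarkers.csv --out fold_changes.csv
```

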