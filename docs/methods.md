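# Methods

## Dose-toxicity model and posterior computation

The engine implements the Bayesian model-averaging continual reassessment
method with the one-parameter power model `π_{k,j} = p_{k,j}^{exp(α)}` and a
zero-mean normal prior on α. The binomial tally `(n_j, y_j)` of evaluable
patients and DLTs per dose is sufficient for the likelihood, so every
posterior quantity is invariant to patient ordering.

All integrals are computed by fixed-grid trapezoidal quadrature on
`α ∈ [−8σ, 8σ]` with 8193 nodes (configurable through `QuadratureSpec`),
with log-space accumulation for the marginal likelihoods. This grid is
symmetric, so prior expectations of odd functions vanish exactly, and it is
dense enough that doubling the node count changes posterior means, log
marginals, model-averaged estimates and the overdose tail probability by
less than 1e-6 (asserted in the tests). Marginal likelihoods are
normalised by the prior mass inside the truncated grid so an empty tally
gives exactly log 1 = 0. The overdose probability
`Pr(π₁ > φ | data)` is an exact posterior tail integral: under model *k*
the event is `α < log(log φ / log p_{k,1})`, and the grid integral is cut
exactly at that threshold; for a single skeleton and no data it reproduces
the closed form `Φ(log(log φ / log p₁)/σ)` to 1e-6.

Dose assignment picks the dose with estimate closest to the target, with
two deliberate conventions: assignments may not exceed one level above the
highest dose already tried (the recorded study treated its second cohort at
the middle dose even though the top dose was nearest the target, which
forces this constraint), and distance ties break toward the higher dose,
matching the "highest dose closest to the target" MTD wording. Patients
who withdraw before DLT assessment contribute nothing to the tally. DLT
outcomes are binary flags already adjudicated for the protocol's assessment
window; no time-to-event structure is modelled.

## Estimator-convention calibration

The study report states the model, skeletons, prior and decision rules, but
two things are under-determined: how the "probability of toxicity" columns
of its per-patient table were point-estimated, and whether "N(0, 2)" means
variance 2 (σ = √2, the package default) or σ = 2. The package therefore
exposes four estimator variants — plug-in at the posterior mean, mode or
median of α, and the posterior mean of π itself — and
`phaseone.calibration` replays the recorded tallies under each variant
crossed with a prior-σ grid (0.5–2.5, including both readings of the stated
prior), ranking conventions by worst absolute deviation from the recorded
estimates.

The calibration's outcome: the plug-in-at-posterior-mode variant with
σ = 0.85 comes closest, with a maximum deviation of .024 — an order of
magnitude above printed rounding. No convention in the scanned family can
do better, and the post-DLT rows of the recorded table are provably outside
the whole model family: the per-dose effective exponents they imply
*increase* as the skeleton probability decreases, while any posterior
functional of `p^{exp(α)}` (and any two-model mixture of them) forces the
opposite ordering. The recorded table also disagrees with its own
companion text in places (its final row versus the quoted final
probabilities, and its lowest-dose overdose column versus the stated rule).
The package consequently implements the literal stated model, reports the
calibrated convention, and treats the residual disagreement as a property
of the recorded table rather than something to be fitted away. The
zero-data row and the MTD selection are insensitive to the convention: all
plug-in variants give the exact skeleton average (.065, .15, .30) with no
data, and every scanned convention selects 150 mg/day on the final tally.

## Trial replay and simulation

`replay_trial` recomputes estimates from the evaluable records preceding
each patient (per-patient cadence) or at cohort boundaries (per-cohort
cadence, provided because recorded tables of this design often repeat rows
within cohorts); a final row uses all data. The reconstructed enrollment
shipped in `phaseone.study` — three patients per cohort at levels 1 and 2
with no DLT, the rest at level 3 with a single DLT in the 13th evaluable
patient, one non-evaluable withdrawal — is an inference from the recorded
per-row patient counts, not a published listing.

`simulate_trial` draws Bernoulli DLTs at the assigned dose's true
probability and follows the design's assignment/stopping rules exactly.
Replicates in `operating_characteristics` derive their generators from a
master `SeedSequence`, so runs are independent yet individually
reproducible. Estimates used for assignment are those available when a
cohort opens; a partial final cohort is allowed at the patient ceiling.

## Non-compartmental analysis

Default trapezoid is linear-up/log-down (log trapezoid on strictly
declining positive segments), with pure linear available; the two coincide
on non-decreasing segments and on constant profiles. BLQ policy:
pre-first-quantifiable samples count as zero, embedded and trailing BLQ
samples are excluded from AUC and λz — the conventional, conservative
choice. λz candidates are the last *m* quantifiable points after and
excluding Tmax, 3 ≤ m, selected by maximal adjusted R²; non-negative
slopes are rejected and the chosen point count and adjusted R² are reported
for audit. `AUC_inf = AUC_last + C_last/λz` uses the observed last
quantifiable concentration, and extrapolated fractions above 20% are
logged. Geometric-mean ratios use natural-log paired differences with a
t interval on n−1 degrees of freedom at 95% by default. Dose
normalisation is per administered mg; body-surface dosing is upstream of
this module.

On noiseless mono-exponential data the full chain reproduces closed-form
Cmax, λz and AUC to numerical precision (the AUC closed forms are exact
from the first sample onward; sampling density controls the remaining
quadrature error, bounded in the tests at 0.5–2%).

## Correlative statistics

Fold change divides by the day-1 baseline and is idempotent and
scale-invariant, as is the stimulated/unstimulated phosphorylation ratio.
The exact Wilcoxon signed-rank test drops zero differences, midranks ties,
and enumerates all 2ⁿ sign assignments for n ≤ 25 (collapsed to a
subset-sum convolution over doubled midranks, which is arithmetic-identical
to the literal enumeration and verified against it); beyond 25 it uses the
tie-corrected normal approximation with continuity correction. The paired
t test is the classical closed form with one-sided p. PSA response takes
the nadir as the minimum over all follow-ups and counts a decline of
exactly 50% as a response. Mixed-effects modelling of the VEGF-A/CEC
panels is deliberately out of scope — those are routine off-the-shelf fits;
this module supplies the transformations that feed them.

## Synthetic data

Generators are pure functions of (parameters, seed); all noise is
lognormal because the quantities are positive and right-skewed.

PK: a two-compartment constant-rate-infusion model solved in closed form by
eigendecomposition of the 2×2 micro-rate matrix. Defaults are
docetaxel-like illustrative population values, not fitted to any patient
data: CL 45 L/h, V1 8 L, V2 35 L, Q 13 L/h, 140 mg over a 1-h infusion,
20% residual CV, 30% between-subject CV on clearance (shared across a
subject's occasions, so the paired design cancels it), LLOQ 8.5 ng/mL,
protocol sampling at 0, .5, .75, 1, 2, 4, 8, 12, 24 h. They give total
exposure near dose/CL ≈ 3100 ng·h/mL, the low-thousands scale of the
study's exposure table. The combination occasion multiplies the whole
curve by `occasion_ratio` (default 1.10, the scale of the observed exposure
shift).

Biomarkers (per dose group, six protocol days): plasma lycopene rises to a
common plateau (+0.40 µmol/L over a 0.48 baseline) with dose-dependent rate,
emulating the observed plateau in peak level with faster attainment at
higher dose; VEGF-A follows `exp(slope·day)` with slope −0.004/0/+0.004
per day at 30/90/150 mg/day (the sign flip across dose); CECs follow a
log-scale Gaussian excursion centred on day 57 (width 25 days) that is a
nadir at 30 mg/day and a peak at 90/150; the ligand-dependent
phosphorylation ratio starts at 10.9-fold (lognormal across subjects,
σ_log 0.8) and declines after day 57 only at 150 mg/day (0.012/day, ≈40%
down by day 99). PSA baselines are lognormal around a 19.2 µg/L median and
decline toward a subject-specific nadir fraction with median 0.27 (−73%
median change); the reported response frequency and median decline of the
study cannot both be matched by a unimodal lognormal, so the median is
matched and the response frequency lands near 0.6.

What the generators deliberately do not emulate: correlation between
biomarkers within a subject, accrual timing, dropout beyond the evaluable
flag, assay drift, and any real covariance between toxicity and PK.
Passing tests therefore demonstrate that the estimators recover the
structure the generators encode (slope signs, exposure ratios, toxicity
rates), not that they would be unbiased on real trial data.

## Problem sizes used in the automated checks

Operating characteristics run at tens to hundreds of replicates in the test
suite (the modal-MTD check under a skeleton-matching truth uses 300); the
paired-GMR coverage check uses 10,000 direct lognormal replicates at n=5
and a 60-replicate end-to-end recovery run through the full NCA chain;
Wilcoxon exactness is enumerated for all n ≤ 10. These sizes keep every
check deterministic (fixed seeds) and give binomial/Monte-Carlo error well
inside the asserted tolerances.

## Known limitations

The recorded-trace disagreement documented above is the main one. Others:
the quadrature assumes the posterior is negligible outside ±8σ (true for
any realistic phase I tally); λz selection by adjusted R² can choose short
terminal windows on noisy profiles (the point count is reported for audit);
the exact Wilcoxon cost grows with the sum of ranks (quadratic in n), which
is irrelevant at n ≤ 25; and the simulator models no inter-patient
heterogeneity in toxicity probability beyond the dose effect.
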