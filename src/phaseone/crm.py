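"""Bayesian model-averaging continual reassessment method (BMA-CRM).

The dose-toxicity model is the one-parameter power ("empiric") CRM model

    pi_{k,j} = p_{k,j} ** exp(alpha),

where ``p_{k,j}`` is the prior guess (skeleton) of the DLT probability at
dose level ``j`` under candidate model ``k`` and ``alpha`` has a zero-mean
normal prior.  Several skeletons are entertained simultaneously; their
posterior model probabilities (proportional to prior model weight times the
marginal likelihood of the accumulated binomial toxicity data) weight the
per-model dose-toxicity estimates into a single model-averaged curve.  The
next patient is assigned to the dose whose estimated toxicity probability is
closest to the target rate, without skipping an untried level, and the trial
stops early if the lowest dose is estimated to be excessively toxic.

All posterior quantities are computed by deterministic fixed-grid
quadrature, so results are reproducible to floating-point precision.
"""

from __future__ import annotations

import json
import math
from functools import lru_cache
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.special import xlog1py, xlogy
from scipy.stats import norm

__all__ = [
    "Skeleton",
    "QuadratureSpec",
    "BmaCrmModel",
    "ToxicityTally",
    "PosteriorSummary",
    "DoseDecision",
    "TERMINATE",
    "ESTIMATOR_VARIANTS",
    "toxicity_probability",
    "log_likelihood",
    "posterior_alpha_mean",
    "posterior_alpha_mode",
    "posterior_alpha_median",
    "log_marginal_likelihood",
    "model_weights",
    "bma_toxicity_estimates",
    "overdose_probability_lowest_dose",
    "should_terminate",
    "next_dose",
    "select_mtd",
]

#: Supported point-estimator variants for the per-dose toxicity estimate.
#: ``plugin-*`` variants plug a posterior point estimate of alpha into the
#: power model; ``posterior-pi-mean`` averages pi itself over the posterior.
ESTIMATOR_VARIANTS = (
    "plugin-mean",
    "plugin-mode",
    "plugin-median",
    "posterior-pi-mean",
)


class CrmNumericalError(RuntimeError):
    """Raised when posterior quadrature fails (e.g. total underflow)."""


@dataclass(frozen=True)
class Skeleton:
    """Ordered prior toxicity probabilities, one per dose level."""

    probabilities: tuple[float, ...]

    def __init__(self, probabilities: Sequence[float]):
        object.__setattr__(self, "probabilities", tuple(float(p) for p in probabilities))
        p = self.probabilities
        if len(p) == 0:
            raise ValueError("skeleton must contain at least one dose level")
        if any(not (0.0 < v < 1.0) for v in p):
            raise ValueError(f"skeleton probabilities must lie strictly in (0,1): {p}")
        if any(b <= a for a, b in zip(p, p[1:])):
            raise ValueError(f"skeleton probabilities must be strictly increasing: {p}")

    def __len__(self) -> int:
        return len(self.probabilities)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.probabilities, dtype=float)


@dataclass(frozen=True)
class QuadratureSpec:
    """Deterministic trapezoidal quadrature grid for the alpha posterior.

    ``bound_sds`` is the half-width of the integration interval in prior
    standard deviations; ``nodes`` the number of grid points.  The grid is
    symmetric about zero, which makes prior expectations of odd functions
    vanish exactly.
    """

    bound_sds: float = 8.0
    nodes: int = 8193
    rtol: float = 1e-8

    def __post_init__(self):
        if self.bound_sds < 6.0:
            raise ValueError("integration bounds must cover at least ±6 prior sd")
        if self.nodes < 64:
            raise ValueError("quadrature needs at least 64 nodes")

    def grid(self, prior_sd: float) -> np.ndarray:
        b = self.bound_sds * prior_sd
        return np.linspace(-b, b, int(self.nodes))


@dataclass(frozen=True)
class ToxicityTally:
    """Per-dose counts of evaluable patients (``n``) and DLTs (``y``).

    The binomial counts are sufficient for the CRM likelihood, so every
    posterior quantity depends on the enrollment history only through this
    tally.
    """

    n: tuple[int, ...]
    y: tuple[int, ...]

    def __init__(self, n: Sequence[int], y: Sequence[int]):
        object.__setattr__(self, "n", tuple(int(v) for v in n))
        object.__setattr__(self, "y", tuple(int(v) for v in y))
        if len(self.n) != len(self.y):
            raise ValueError("n and y must have equal length")
        for nj, yj in zip(self.n, self.y):
            if nj < 0 or yj < 0 or yj > nj:
                raise ValueError(f"need 0 <= y_j <= n_j at every dose: n={self.n} y={self.y}")

    @classmethod
    def empty(cls, n_doses: int) -> "ToxicityTally":
        return cls((0,) * n_doses, (0,) * n_doses)

    def add(self, dose_level: int, dlt: bool) -> "ToxicityTally":
        """Return a new tally with one evaluable patient added at ``dose_level`` (0-based)."""
        n = list(self.n)
        y = list(self.y)
        n[dose_level] += 1
        if dlt:
            y[dose_level] += 1
        return ToxicityTally(n, y)

    @property
    def n_patients(self) -> int:
        return sum(self.n)

    @property
    def n_dlt(self) -> int:
        return sum(self.y)


@dataclass(frozen=True)
class BmaCrmModel:
    """Configuration of the BMA-CRM design.

    Defaults are the design of the motivating phase I trial of daily oral
    lycopene combined with fixed-dose docetaxel: dose grid {30, 90, 150}
    mg/day, skeletons (.05,.1,.2) and (.08,.2,.4) with equal prior weight,
    alpha ~ N(0, 2) (``alpha_prior_sd`` = sqrt(2)), target DLT rate .2,
    early stop when Pr(pi_1 > .2 | data) > .85, cohorts of three, 18
    patients maximum.
    """

    dose_grid: tuple[float, ...] = (30.0, 90.0, 150.0)
    skeletons: tuple[Skeleton, ...] = (
        Skeleton((0.05, 0.10, 0.20)),
        Skeleton((0.08, 0.20, 0.40)),
    )
    prior_model_probs: tuple[float, ...] = (0.5, 0.5)
    alpha_prior_sd: float = math.sqrt(2.0)
    target_toxicity: float = 0.2
    overdose_threshold: float = 0.85
    cohort_size: int = 3
    max_patients: int = 18
    estimator: str = "plugin-mean"
    quadrature: QuadratureSpec = field(default_factory=QuadratureSpec)

    def __post_init__(self):
        k = len(self.dose_grid)
        if k == 0:
            raise ValueError("dose grid must not be empty")
        if any(len(s) != k for s in self.skeletons):
            raise ValueError("every skeleton must match the dose-grid length")
        w = np.asarray(self.prior_model_probs, dtype=float)
        if len(w) != len(self.skeletons):
            raise ValueError("one prior model probability per skeleton required")
        if np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("prior model probabilities must be non-negative and sum to 1")
        if not self.alpha_prior_sd > 0:
            raise ValueError("alpha_prior_sd must be positive")
        if not 0.0 < self.target_toxicity < 1.0:
            raise ValueError("target_toxicity must lie in (0,1)")
        if not 0.0 < self.overdose_threshold <= 1.0:
            raise ValueError("overdose_threshold must lie in (0,1]")
        if self.cohort_size < 1 or self.max_patients < self.cohort_size:
            raise ValueError("need cohort_size >= 1 and max_patients >= cohort_size")
        if self.estimator not in ESTIMATOR_VARIANTS:
            raise ValueError(f"unknown estimator {self.estimator!r}; choose from {ESTIMATOR_VARIANTS}")

    @property
    def n_doses(self) -> int:
        return len(self.dose_grid)

    @property
    def n_models(self) -> int:
        return len(self.skeletons)

    def replace(self, **kwargs) -> "BmaCrmModel":
        cfg = self.to_dict()
        cfg.update(kwargs)
        return BmaCrmModel.from_dict(cfg)

    # -- JSON configuration document ------------------------------------
    def to_dict(self) -> dict:
        return {
            "dose_grid": list(self.dose_grid),
            "skeletons": [list(s.probabilities) for s in self.skeletons],
            "prior_model_probs": list(self.prior_model_probs),
            "alpha_prior_sd": self.alpha_prior_sd,
            "target_toxicity": self.target_toxicity,
            "overdose_threshold": self.overdose_threshold,
            "cohort_size": self.cohort_size,
            "max_patients": self.max_patients,
            "estimator": self.estimator,
            "quadrature": asdict(self.quadrature),
        }

    @classmethod
    def from_dict(cls, cfg: dict) -> "BmaCrmModel":
        cfg = dict(cfg)
        if "skeletons" in cfg:
            cfg["skeletons"] = tuple(
                s if isinstance(s, Skeleton) else Skeleton(s) for s in cfg["skeletons"]
            )
        if "dose_grid" in cfg:
            cfg["dose_grid"] = tuple(float(d) for d in cfg["dose_grid"])
        if "prior_model_probs" in cfg:
            cfg["prior_model_probs"] = tuple(float(w) for w in cfg["prior_model_probs"])
        if "quadrature" in cfg and not isinstance(cfg["quadrature"], QuadratureSpec):
            cfg["quadrature"] = QuadratureSpec(**cfg["quadrature"])
        return cls(**cfg)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "BmaCrmModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-model posterior summaries and the model-averaged toxicity curve."""

    alpha_hat: tuple[float, ...]
    log_marginal: tuple[float, ...]
    model_weights: tuple[float, ...]
    pi_hat: tuple[float, ...]
    p_lowest_overdose: float


#: Sentinel decision returned when the early-termination rule fires.
TERMINATE = "terminate"


@dataclass(frozen=True)
class DoseDecision:
    """Outcome of a dose-assignment query: a dose level or termination."""

    terminate: bool
    dose_level: int | None = None  # 1-based level
    dose: float | None = None      # amount in the grid's units


# ---------------------------------------------------------------------------
# core model functions
# ---------------------------------------------------------------------------

def toxicity_probability(alpha: float, skeleton_prob: float) -> float:
    """Dose-toxicity model: ``skeleton_prob ** exp(alpha)``.

    Decreasing in ``alpha``; the identity at ``alpha = 0``.
    """
    if not 0.0 < skeleton_prob < 1.0:
        raise ValueError(f"skeleton probability must lie strictly in (0,1), got {skeleton_prob}")
    return float(skeleton_prob) ** math.exp(alpha)


def log_likelihood(alpha, skeleton: Skeleton, tally: ToxicityTally):
    """Binomial log likelihood of the tally under one skeleton.

    Product over dose levels of ``pi^y (1-pi)^(n-y)`` with
    ``pi = p_j^exp(alpha)``; an empty tally gives exactly 0.  ``alpha`` may
    be a scalar or an array (vectorised over the quadrature grid).
    """
    a = np.asarray(alpha, dtype=float)
    n = np.asarray(tally.n, dtype=float)
    y = np.asarray(tally.y, dtype=float)
    if len(n) != len(skeleton):
        raise ValueError("tally length must match skeleton length")
    p = skeleton.array
    pi = p[None, :] ** np.exp(np.atleast_1d(a))[:, None]
    ll = (xlogy(y[None, :], pi) + xlog1py(n[None, :] - y[None, :], -pi)).sum(axis=1)
    return float(ll[0]) if a.ndim == 0 else ll


@lru_cache(maxsize=4096)
def _log_posterior_cached(skeleton: Skeleton, tally: ToxicityTally,
                          prior_sd: float, quad: QuadratureSpec):
    """Unnormalised log posterior of alpha on the quadrature grid (memoised).

    All inputs are immutable value objects, so the posterior depends on
    nothing else; the returned arrays are marked read-only.
    """
    grid = quad.grid(prior_sd)
    lp = log_likelihood(grid, skeleton, tally) + norm.logpdf(grid, 0.0, prior_sd)
    grid.setflags(write=False)
    lp.setflags(write=False)
    return grid, lp


def _log_posterior(model: BmaCrmModel, k: int, tally: ToxicityTally):
    return _log_posterior_cached(
        model.skeletons[k], tally, model.alpha_prior_sd, model.quadrature
    )


def _density(lp: np.ndarray):
    """Shifted posterior density values and the log of the shift."""
    shift = float(np.max(lp))
    if not np.isfinite(shift):
        raise CrmNumericalError("posterior log density is not finite anywhere on the grid")
    d = np.exp(lp - shift)
    return d, shift


def posterior_alpha_mean(skeleton: Skeleton, tally: ToxicityTally,
                         prior_sd: float = math.sqrt(2.0),
                         quad: QuadratureSpec | None = None) -> float:
    """Posterior mean of alpha by deterministic trapezoidal quadrature."""
    quad = quad or QuadratureSpec()
    grid, lp = _log_posterior_cached(skeleton, tally, prior_sd, quad)
    d, _ = _density(lp)
    z = np.trapezoid(d, grid)
    if z <= 0 or not np.isfinite(z):
        raise CrmNumericalError(f"posterior normalising constant underflowed (z={z})")
    return float(np.trapezoid(grid * d, grid) / z)


def posterior_alpha_mode(skeleton: Skeleton, tally: ToxicityTally,
                         prior_sd: float = math.sqrt(2.0),
                         quad: QuadratureSpec | None = None) -> float:
    """Posterior mode of alpha: grid argmax refined by quadratic interpolation."""
    quad = quad or QuadratureSpec()
    grid, lp = _log_posterior_cached(skeleton, tally, prior_sd, quad)
    i = int(np.argmax(lp))
    i = min(max(i, 1), len(grid) - 2)
    y0, y1, y2 = lp[i - 1], lp[i], lp[i + 1]
    denom = y0 - 2.0 * y1 + y2
    h = grid[1] - grid[0]
    off = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    return float(grid[i] + off * h)


def posterior_alpha_median(skeleton: Skeleton, tally: ToxicityTally,
                           prior_sd: float = math.sqrt(2.0),
                           quad: QuadratureSpec | None = None) -> float:
    """Posterior median of alpha from the interpolated grid CDF."""
    quad = quad or QuadratureSpec()
    grid, lp = _log_posterior_cached(skeleton, tally, prior_sd, quad)
    d, _ = _density(lp)
    seg = 0.5 * (d[1:] + d[:-1]) * np.diff(grid)
    cdf = np.concatenate([[0.0], np.cumsum(seg)])
    cdf /= cdf[-1]
    return float(np.interp(0.5, cdf, grid))


def log_marginal_likelihood(skeleton: Skeleton, tally: ToxicityTally,
                            prior_sd: float = math.sqrt(2.0),
                            quad: QuadratureSpec | None = None) -> float:
    """log of the marginal likelihood of the tally: log ∫ L(alpha) prior(alpha) dalpha.

    Exactly 0 for an empty tally (the likelihood is identically 1 and the
    prior integrates to 1 up to quadrature truncation).
    """
    quad = quad or QuadratureSpec()
    grid, lp = _log_posterior_cached(skeleton, tally, prior_sd, quad)
    d, shift = _density(lp)
    z = np.trapezoid(d, grid)
    if z <= 0 or not np.isfinite(z):
        raise CrmNumericalError(f"marginal likelihood underflowed (z={z})")
    # normalise by the prior mass actually inside the truncated grid so that
    # an empty tally gives exactly log(1) = 0
    prior_mass = np.trapezoid(norm.pdf(grid, 0.0, prior_sd), grid)
    return float(np.log(z) + shift - np.log(prior_mass))


def model_weights(model: BmaCrmModel, tally: ToxicityTally) -> np.ndarray:
    """Posterior model probabilities: prior weight times marginal likelihood.

    Combined in log space so that simultaneous underflow of all marginals is
    detected rather than silently renormalised.
    """
    logm = np.array([
        log_marginal_likelihood(s, tally, model.alpha_prior_sd, model.quadrature)
        for s in model.skeletons
    ])
    logw = np.log(np.asarray(model.prior_model_probs, dtype=float)) + logm
    w = np.exp(logw - logw.max())
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise CrmNumericalError("all model marginal likelihoods underflowed")
    return w / total


def _alpha_point_estimate(model: BmaCrmModel, k: int, tally: ToxicityTally) -> float:
    fn = {
        "plugin-mean": posterior_alpha_mean,
        "plugin-mode": posterior_alpha_mode,
        "plugin-median": posterior_alpha_median,
        "posterior-pi-mean": posterior_alpha_mean,  # reported alongside pi means
    }[model.estimator]
    return fn(model.skeletons[k], tally, model.alpha_prior_sd, model.quadrature)


def bma_toxicity_estimates(model: BmaCrmModel, tally: ToxicityTally) -> PosteriorSummary:
    """Model-averaged per-dose toxicity estimates.

    Plug-in variants use ``pi_hat_{k,j} = p_{k,j} ** exp(alpha_hat_k)`` with
    ``alpha_hat_k`` the chosen posterior point estimate; the
    ``posterior-pi-mean`` variant averages ``pi_{k,j}`` over each model's
    posterior.  Either way the per-model curves are combined with the
    posterior model weights.
    """
    if len(tally.n) != model.n_doses:
        raise ValueError("tally length must match the dose grid")
    w = model_weights(model, tally)
    alpha_hat = [_alpha_point_estimate(model, k, tally) for k in range(model.n_models)]
    logm = [
        log_marginal_likelihood(s, tally, model.alpha_prior_sd, model.quadrature)
        for s in model.skeletons
    ]
    if model.estimator == "posterior-pi-mean":
        per_model = []
        for k, s in enumerate(model.skeletons):
            grid, lp = _log_posterior(model, k, tally)
            d, _ = _density(lp)
            z = np.trapezoid(d, grid)
            pi = s.array[None, :] ** np.exp(grid)[:, None]
            per_model.append(np.trapezoid(pi * d[:, None], grid, axis=0) / z)
    else:
        per_model = [
            s.array ** math.exp(alpha_hat[k]) for k, s in enumerate(model.skeletons)
        ]
    pi_hat = np.einsum("k,kj->j", w, np.asarray(per_model))
    return PosteriorSummary(
        alpha_hat=tuple(alpha_hat),
        log_marginal=tuple(logm),
        model_weights=tuple(float(v) for v in w),
        pi_hat=tuple(float(v) for v in pi_hat),
        p_lowest_overdose=overdose_probability_lowest_dose(model, tally),
    )


def overdose_probability_lowest_dose(model: BmaCrmModel, tally: ToxicityTally) -> float:
    """Pr(pi_1 > target | data), model-averaged.

    Under model ``k`` the event ``p_{k,1}^exp(alpha) > target`` is
    ``alpha < log(log(target)/log(p_{k,1}))``, so each term is a posterior
    tail probability, integrated on the quadrature grid with an exact cut at
    the threshold.
    """
    if model.target_toxicity >= 1.0:
        return 0.0
    w = model_weights(model, tally)
    total = 0.0
    for k, s in enumerate(model.skeletons):
        p1 = s.probabilities[0]
        cut = math.log(math.log(model.target_toxicity) / math.log(p1))
        grid, lp = _log_posterior(model, k, tally)
        d, _ = _density(lp)
        z = np.trapezoid(d, grid)
        if cut <= grid[0]:
            tail = 0.0
        elif cut >= grid[-1]:
            tail = 1.0
        else:
            j = int(np.searchsorted(grid, cut))
            # full trapezoids below the cut plus the partial last trapezoid
            mass = np.trapezoid(d[:j], grid[:j]) if j >= 2 else 0.0
            d_cut = np.exp(
                log_likelihood(cut, model.skeletons[k], tally)
                + norm.logpdf(cut, 0.0, model.alpha_prior_sd)
                - (lp.max())
            )
            mass += 0.5 * (d[j - 1] + d_cut) * (cut - grid[j - 1])
            tail = mass / z
        total += w[k] * min(max(tail, 0.0), 1.0)
    return float(min(max(total, 0.0), 1.0))


def should_terminate(model: BmaCrmModel, tally: ToxicityTally) -> bool:
    """Early-termination rule: lowest dose excessively toxic."""
    return overdose_probability_lowest_dose(model, tally) > model.overdose_threshold


def next_dose(model: BmaCrmModel, tally: ToxicityTally,
              highest_tried: int | None) -> DoseDecision:
    """Dose for the next patient (1-based level), or termination.

    The candidate is the dose whose estimated toxicity probability is
    closest to the target (ties toward the higher dose), constrained to at
    most one level above the highest level already tried.  At trial start
    (``highest_tried`` is None) the design begins at level 1.
    """
    if highest_tried is not None and not 1 <= highest_tried <= model.n_doses:
        raise ValueError(f"highest_tried must be a 1-based level in the grid, got {highest_tried}")
    if should_terminate(model, tally):
        return DoseDecision(terminate=True)
    if highest_tried is None:
        return DoseDecision(terminate=False, dose_level=1, dose=model.dose_grid[0])
    summary = bma_toxicity_estimates(model, tally)
    cap = min(model.n_doses, highest_tried + 1)
    level = _closest_to_target(summary.pi_hat[:cap], model.target_toxicity)
    return DoseDecision(terminate=False, dose_level=level, dose=model.dose_grid[level - 1])


def _closest_to_target(pi_hat: Sequence[float], target: float) -> int:
    """1-based index of the estimate closest to target; ties go to the higher dose."""
    dist = np.abs(np.asarray(pi_hat, dtype=float) - target)
    best = np.flatnonzero(dist <= dist.min() + 1e-12)
    return int(best[-1]) + 1


def select_mtd(model: BmaCrmModel, tally: ToxicityTally) -> DoseDecision:
    """MTD on the final data: highest dose with estimate closest to target."""
    if tally.n_patients == 0:
        raise ValueError("MTD selection requires at least one treated patient")
    if should_terminate(model, tally):
        return DoseDecision(terminate=True)
    summary = bma_toxicity_estimates(model, tally)
    level = _closest_to_target(summary.pi_hat, model.target_toxicity)
    return DoseDecision(terminate=False, dose_level=level, dose=model.dose_grid[level - 1])
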