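"""Correlative biomarker statistics.

Baseline fold-change normalisation of longitudinal analytes, the
ligand-dependent IGF-1R(Y1131) phosphorylation ratio, exact small-sample
paired tests (one-sided paired t; exact Wilcoxon signed-rank with midranked
ties by full sign enumeration), and the PSA response rule (≥50% decline
from baseline to nadir).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BiomarkerSeries",
    "PhosphoAssay",
    "PsaSeries",
    "fold_change",
    "ligand_dependent_phosphorylation",
    "wilcoxon_signed_rank_exact",
    "paired_t_one_sided",
    "psa_response",
    "read_biomarker_table",
]

#: Protocol observation days of the motivating study (day 1 is baseline,
#: before the first lycopene dose).
PROTOCOL_DAYS = (1, 15, 36, 57, 78, 99)


@dataclass(frozen=True)
class BiomarkerSeries:
    """Per-subject longitudinal values of one analyte."""

    subject: str
    dose_group_mg: float
    analyte: str
    days: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self):
        if len(self.days) != len(self.values):
            raise ValueError("days and values must have equal length")
        if len(self.days) == 0:
            raise ValueError("series must not be empty")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")

    @property
    def baseline(self) -> float | None:
        try:
            return self.values[self.days.index(1)]
        except ValueError:
            return None


@dataclass(frozen=True)
class PhosphoAssay:
    """Stimulated and unstimulated phospho-IGF-1R(Y1131) signals on one day."""

    subject: str
    day: int
    stimulated: float
    unstimulated: float

    def __post_init__(self):
        if self.stimulated <= 0 or self.unstimulated <= 0:
            raise ValueError("assay signals must be strictly positive")


@dataclass(frozen=True)
class PsaSeries:
    subject: str
    baseline: float
    follow_up: tuple[float, ...]

    def __post_init__(self):
        if self.baseline <= 0:
            raise ValueError("baseline PSA must be positive")


def fold_change(series: BiomarkerSeries) -> BiomarkerSeries:
    """Normalise every value to the day-1 baseline (baseline maps to 1).

    Idempotent: renormalising a fold-change series leaves it unchanged.
    """
    base = series.baseline
    if base is None or base <= 0:
        raise ValueError(
            f"{series.subject}/{series.analyte}: day-1 baseline missing or non-positive"
        )
    return BiomarkerSeries(
        subject=series.subject,
        dose_group_mg=series.dose_group_mg,
        analyte=series.analyte,
        days=series.days,
        values=tuple(v / base for v in series.values),
    )


def ligand_dependent_phosphorylation(assay: PhosphoAssay) -> float:
    """Stimulated-to-unstimulated phospho-signal ratio (scale invariant)."""
    return assay.stimulated / assay.unstimulated


def _signed_rank_statistic(d: np.ndarray):
    """W+ and the midranks of |d| after dropping zeros."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all differences are zero; the signed-rank test is undefined")
    ranks = stats.rankdata(np.abs(d))  # midranks on ties
    w_plus = float(ranks[d > 0].sum())
    return w_plus, ranks, d


def _exact_tail_probs(ranks: np.ndarray):
    """Exact distribution of W+ over all 2^n sign assignments.

    Collapsed to a subset-sum convolution over doubled midranks (midranks
    are half-integer on ties, so doubling makes them integers); this
    enumerates exactly the 2^n equally likely sign vectors.
    """
    r2 = np.rint(2 * np.asarray(ranks)).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    return counts  # counts[s] = Pr(2*W+ = s)


def wilcoxon_signed_rank_exact(differences: Sequence[float],
                               alternative: str = "two-sided",
                               exact_max_n: int = 25):
    """Wilcoxon signed-rank test with an exact small-sample p value.

    Zero differences are dropped; ties receive midranks.  For ``n`` (after
    dropping zeros) up to ``exact_max_n`` the p value is exact over all
    2^n sign assignments; beyond that a normal approximation with tie
    correction and continuity correction is used.  Returns ``(W+, p)``.
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError("alternative must be 'two-sided', 'less' or 'greater'")
    w_plus, ranks, d = _signed_rank_statistic(differences)
    n = len(d)
    if n <= exact_max_n:
        probs = _exact_tail_probs(ranks)
        s = int(round(2 * w_plus))
        p_le = float(probs[: s + 1].sum())
        p_ge = float(probs[s:].sum())
        if alternative == "less":
            p = p_le
        elif alternative == "greater":
            p = p_ge
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
        sd = math.sqrt(var)
        if alternative == "less":
            p = stats.norm.cdf((w_plus - mean + 0.5) / sd)
        elif alternative == "greater":
            p = stats.norm.sf((w_plus - mean - 0.5) / sd)
        else:
            z = (w_plus - mean - math.copysign(0.5, w_plus - mean)) / sd
            p = 2.0 * stats.norm.sf(abs(z))
            p = min(1.0, p)
    return w_plus, float(p)


def paired_t_one_sided(x: Sequence[float], y: Sequence[float],
                       direction: str = "greater"):
    """Classical paired t test on ``y − x`` with a one-sided p value.

    ``direction='greater'`` tests whether ``y`` exceeds ``x`` on average.
    Returns ``(t, p)``; degenerate zero-variance differences raise.
    """
    if direction not in ("less", "greater"):
        raise ValueError("direction must be 'less' or 'greater'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need equal-length 1-D samples with n >= 2")
    d = y - x
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("differences have zero variance; t statistic undefined")
    t = d.mean() / (sd / math.sqrt(len(d)))
    df = len(d) - 1
    p = stats.t.sf(t, df) if direction == "greater" else stats.t.cdf(t, df)
    return float(t), float(p)


def psa_response(series: PsaSeries) -> tuple[float, bool]:
    """Percent change from baseline to nadir and the ≥50%-decline flag.

    The nadir is the minimum over all recorded follow-up values; a decline
    of exactly 50% counts as a response (boundary inclusive).
    """
    if len(series.follow_up) == 0:
        raise ValueError(f"{series.subject}: no follow-up PSA values")
    nadir = min(series.follow_up)
    change = (nadir - series.baseline) / series.baseline * 100.0
    return float(change), bool(change <= -50.0)


def read_biomarker_table(path) -> list[BiomarkerSeries]:
    """Read a long-format biomarker CSV: subject,dose_group,analyte,day,value."""
    df = pd.read_csv(path)
    required = ["subject", "dose_group", "analyte", "day", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    out = []
    for (subj, group, analyte), g in df.groupby(["subject", "dose_group", "analyte"], sort=True):
        g = g.sort_values("day")
        out.append(
            BiomarkerSeries(
                subject=str(subj),
                dose_group_mg=float(group),
                analyte=str(analyte),
                days=tuple(int(d) for d in g["day"]),
                values=tuple(float(v) for v in g["value"]),
            )
        )
    return out
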