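"""Non-compartmental PK analysis and paired geometric-mean-ratio estimation.

Implements the standard NCA parameter set for a concentration–time profile —
Cmax/Tmax, trapezoidal AUC to the last quantifiable sample (linear or
linear-up/log-down), terminal slope ``lambda_z`` chosen by adjusted R² over
the last-m log-linear fits, and the extrapolated AUC to infinity — plus the
paired log-scale geometric-mean-ratio comparison used for the
docetaxel-alone versus docetaxel-plus-lycopene crossover.

BLQ policy: samples below the lower limit of quantification before the first
quantifiable sample are treated as zero; embedded and trailing BLQ samples
are excluded from AUC and terminal-slope fitting.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcentrationProfile",
    "NcaResult",
    "GmrEstimate",
    "cmax_tmax",
    "auc_last",
    "fit_lambda_z",
    "auc_inf",
    "paired_gmr",
    "percent_change",
    "summarize_pk_cohort",
    "read_pk_table",
    "profiles_to_frame",
]

log = logging.getLogger(__name__)

PK_COLUMNS = ["subject", "occasion", "time_h", "conc_ng_ml", "dose_mg", "lloq_ng_ml"]


@dataclass(frozen=True)
class ConcentrationProfile:
    """One subject-occasion concentration–time series.

    ``concentrations`` below ``lloq`` (or encoded as NaN) are flagged BLQ.
    Times are hours after the start of the infusion; concentrations ng/mL.
    """

    subject: str
    occasion: str
    times: tuple[float, ...]
    concentrations: tuple[float, ...]  # NaN marks BLQ
    dose_mg: float
    lloq: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if len(t) != len(c):
            raise ValueError("times and concentrations must have equal length")
        if len(t) < 3:
            raise ValueError("a profile needs at least 3 samples")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if np.any(c[np.isfinite(c)] < 0):
            raise ValueError("concentrations must be non-negative or BLQ")
        if self.dose_mg <= 0:
            raise ValueError("dose must be positive")

    @property
    def quantifiable(self) -> np.ndarray:
        c = np.asarray(self.concentrations, dtype=float)
        return np.isfinite(c) & (c >= self.lloq) & (c > 0)

    def _analysis_arrays(self):
        """Times/concentrations with the BLQ policy applied.

        Leading BLQ samples are set to 0 and retained; embedded and trailing
        BLQ samples are dropped.
        """
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        q = self.quantifiable
        if not q.any():
            return np.array([]), np.array([])
        first = int(np.argmax(q))
        last = len(q) - 1 - int(np.argmax(q[::-1]))
        keep = np.zeros(len(t), dtype=bool)
        keep[: first + 1] = True            # leading BLQ -> 0
        keep[first:last + 1] = q[first:last + 1]  # drop embedded BLQ
        cc = np.where(q, c, 0.0)
        return t[keep], cc[keep]


@dataclass(frozen=True)
class NcaResult:
    subject: str
    occasion: str
    dose_mg: float
    cmax: float
    tmax: float
    auc_last: float
    lambda_z: float | None
    lambda_z_n_points: int | None
    lambda_z_adj_r2: float | None
    auc_inf: float | None
    extrapolated_fraction: float | None

    @property
    def cmax_per_mg(self) -> float:
        return self.cmax / self.dose_mg

    @property
    def auc_last_per_mg(self) -> float:
        return self.auc_last / self.dose_mg

    @property
    def auc_inf_per_mg(self) -> float | None:
        return None if self.auc_inf is None else self.auc_inf / self.dose_mg


class BelowLimitError(ValueError):
    """Profile has too few quantifiable samples for the requested parameter."""


def cmax_tmax(profile: ConcentrationProfile) -> tuple[float, float]:
    """Maximum observed concentration and its earliest time."""
    c = np.asarray(profile.concentrations, dtype=float)
    t = np.asarray(profile.times, dtype=float)
    q = profile.quantifiable
    if not q.any():
        raise BelowLimitError(f"{profile.subject}/{profile.occasion}: all samples BLQ")
    cmax = float(np.max(c[q]))
    tmax = float(t[q][int(np.flatnonzero(c[q] == cmax)[0])])  # earliest time on ties
    return cmax, tmax


def auc_last(profile: ConcentrationProfile, method: str = "linuplogdown") -> float:
    """Trapezoidal AUC from time zero to the last quantifiable sample.

    ``linear`` uses linear trapezoids everywhere; ``linuplogdown`` uses the
    logarithmic trapezoid on strictly declining positive segments (standard
    practice for the post-peak decline) and linear trapezoids elsewhere.
    """
    if method not in ("linear", "linuplogdown"):
        raise ValueError("method must be 'linear' or 'linuplogdown'")
    t, c = profile._analysis_arrays()
    if (np.asarray(c) > 0).sum() < 2:
        raise BelowLimitError(
            f"{profile.subject}/{profile.occasion}: need >=2 quantifiable samples"
        )
    total = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if method == "linuplogdown" and c1 > c2 > 0:
            total += dt * (c1 - c2) / math.log(c1 / c2)
        else:
            total += dt * (c1 + c2) / 2.0
    return float(total)


def fit_lambda_z(profile: ConcentrationProfile) -> tuple[float, int, float]:
    """Terminal elimination rate by best-adjusted-R² log-linear regression.

    Candidate point sets are the last ``m`` quantifiable samples after (and
    excluding) Tmax, ``m >= 3``; the set maximising the adjusted R² of the
    log-linear fit is selected.  Returns ``(lambda_z, n_points, adj_r2)``.
    """
    t, c = profile._analysis_arrays()
    pos = c > 0
    t, c = t[pos], c[pos]
    if len(t) == 0:
        raise BelowLimitError(f"{profile.subject}/{profile.occasion}: all samples BLQ")
    imax = int(np.flatnonzero(c == c.max())[0])
    tt, cc = t[imax + 1:], c[imax + 1:]
    best = None
    for m in range(3, len(tt) + 1):
        x, y = tt[-m:], np.log(cc[-m:])
        res = stats.linregress(x, y)
        if res.slope >= 0:
            continue
        r2 = res.rvalue ** 2
        adj = 1.0 - (1.0 - r2) * (m - 1) / (m - 2)
        if best is None or adj > best[2] + 1e-12:
            best = (-res.slope, m, adj)
    if best is None:
        raise BelowLimitError(
            f"{profile.subject}/{profile.occasion}: no declining terminal phase with >=3 points"
        )
    return best


def auc_inf(profile: ConcentrationProfile, method: str = "linuplogdown") -> NcaResult:
    """Full NCA chain: Cmax/Tmax, AUC_last, lambda_z and extrapolated AUC.

    ``AUC_inf = AUC_last + C_last / lambda_z`` with the last observed
    quantifiable concentration; the extrapolated fraction is logged when it
    exceeds 20%.  Terminal-fit failures propagate as None fields.
    """
    cmax, tmax = cmax_tmax(profile)
    auc = auc_last(profile, method)
    try:
        lz, npts, adj = fit_lambda_z(profile)
    except BelowLimitError:
        return NcaResult(profile.subject, profile.occasion, profile.dose_mg,
                         cmax, tmax, auc, None, None, None, None, None)
    t, c = profile._analysis_arrays()
    c_last = float(c[np.flatnonzero(c > 0)[-1]])
    total = auc + c_last / lz
    frac = 1.0 - auc / total
    if frac > 0.2:
        log.warning("%s/%s: %.1f%% of AUC_inf is extrapolated",
                    profile.subject, profile.occasion, 100 * frac)
    return NcaResult(profile.subject, profile.occasion, profile.dose_mg,
                     cmax, tmax, auc, lz, npts, adj, total, frac)


@dataclass(frozen=True)
class GmrEstimate:
    """Paired geometric-mean ratio with its log-scale t confidence interval."""

    n: int
    geomean_alone: float
    geomean_combo: float
    ratio: float
    ci_lower: float | None
    ci_upper: float | None
    level: float = 0.95


def paired_gmr(values_alone: Sequence[float], values_combo: Sequence[float],
               level: float = 0.95) -> GmrEstimate:
    """Geometric mean ratio of paired positive measurements.

    ``ratio = exp(mean(log combo − log alone))`` with the confidence
    interval from the t distribution on the paired log differences
    (n − 1 degrees of freedom).
    """
    a = np.asarray(values_alone, dtype=float)
    b = np.asarray(values_combo, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and of equal length")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("geometric-mean ratios require strictly positive values")
    n = len(a)
    d = np.log(b) - np.log(a)
    ratio = float(np.exp(d.mean()))
    if n < 2:
        return GmrEstimate(n, float(np.exp(np.log(a).mean())), float(np.exp(np.log(b).mean())),
                           ratio, None, None, level)
    se = d.std(ddof=1) / math.sqrt(n)
    tcrit = stats.t.ppf(0.5 + level / 2.0, n - 1)
    return GmrEstimate(
        n=n,
        geomean_alone=float(np.exp(np.log(a).mean())),
        geomean_combo=float(np.exp(np.log(b).mean())),
        ratio=ratio,
        ci_lower=float(np.exp(d.mean() - tcrit * se)),
        ci_upper=float(np.exp(d.mean() + tcrit * se)),
        level=level,
    )


def percent_change(ratio: float) -> float:
    """Ratio expressed as percent change: ``(ratio − 1) · 100``."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return (ratio - 1.0) * 100.0


def summarize_pk_cohort(profiles: Sequence[ConcentrationProfile],
                        method: str = "linuplogdown",
                        level: float = 0.95,
                        occasions: tuple[str, str] = ("alone", "combination"),
                        ) -> pd.DataFrame:
    """Per-parameter paired GMR table across a cohort of paired profiles.

    Parameters are dose-normalised before pairing.  Subjects missing either
    occasion are excluded and logged.  Returns a tidy frame with one row per
    parameter (``auc_last``, ``auc_inf``, ``cmax``).
    """
    results: dict[tuple[str, str], NcaResult] = {}
    for p in profiles:
        results[(p.subject, p.occasion)] = auc_inf(p, method)
    subjects = sorted({s for s, _ in results})
    complete = []
    for s in subjects:
        if all((s, occ) in results for occ in occasions):
            complete.append(s)
        else:
            log.warning("subject %s lacks one occasion; excluded from the paired analysis", s)
    if not complete:
        raise ValueError("no subject has both occasions; paired analysis impossible")
    rows = []
    params = {
        "auc_last": lambda r: r.auc_last_per_mg,
        "auc_inf": lambda r: r.auc_inf_per_mg,
        "cmax": lambda r: r.cmax_per_mg,
    }
    for name, get in params.items():
        pairs = [
            (get(results[(s, occasions[0])]), get(results[(s, occasions[1])]))
            for s in complete
        ]
        pairs = [(x, y) for x, y in pairs if x is not None and y is not None]
        if len(pairs) == 0:
            continue
        est = paired_gmr([x for x, _ in pairs], [y for _, y in pairs], level)
        rows.append({
            "parameter": name, "n": est.n,
            "geomean_alone": est.geomean_alone, "geomean_combo": est.geomean_combo,
            "ratio": est.ratio, "ci_lower": est.ci_lower, "ci_upper": est.ci_upper,
            "level": est.level,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# delimited-text IO
# ---------------------------------------------------------------------------

def read_pk_table(path) -> list[ConcentrationProfile]:
    """Read concentration–time data from delimited text.

    Columns: ``subject,occasion,time_h,conc_ng_ml,dose_mg,lloq_ng_ml``.
    BLQ may be encoded as the string ``BLQ`` or a negative sentinel; both
    are normalised to the NaN flag on read.
    """
    df = pd.read_csv(path)
    missing = [c for c in PK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    conc = pd.to_numeric(
        df["conc_ng_ml"].replace({"BLQ": np.nan, "blq": np.nan}), errors="coerce"
    )
    conc = conc.where(conc >= 0, np.nan)
    df = df.assign(conc_ng_ml=conc)
    profiles = []
    for (subj, occ), g in df.groupby(["subject", "occasion"], sort=True):
        g = g.sort_values("time_h")
        profiles.append(
            ConcentrationProfile(
                subject=str(subj),
                occasion=str(occ),
                times=tuple(g["time_h"].astype(float)),
                concentrations=tuple(g["conc_ng_ml"].astype(float)),
                dose_mg=float(g["dose_mg"].iloc[0]),
                lloq=float(g["lloq_ng_ml"].iloc[0]),
            )
        )
    return profiles


def profiles_to_frame(profiles: Sequence[ConcentrationProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for t, c in zip(p.times, p.concentrations):
            rows.append({
                "subject": p.subject, "occasion": p.occasion, "time_h": t,
                "conc_ng_ml": "BLQ" if not np.isfinite(c) else c,
                "dose_mg": p.dose_mg, "lloq_ng_ml": p.lloq,
            })
    return pd.DataFrame(rows, columns=PK_COLUMNS)
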