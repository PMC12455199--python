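"""Clinical renal endpoints: CKD-EPI eGFR, baseline kidney-function class,
per-patient eGFR slope and rapid-progressor labels.

Baseline class is "late" CKD when baseline eGFR < 60 mL/min/1.73 m^2 and
"early" otherwise (60 itself is early). A patient is a rapid progressor
when the fitted eGFR slope declines faster than 3 mL/min/1.73 m^2 per year,
i.e. slope < -3; a slope of exactly -3 is non-rapid.

Slopes are estimated by ordinary least squares of eGFR on time in years
from the first visit, restricted to patients with at least three creatinine
values spanning at least six months; excluded patients are reported with
the reason rather than silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PatientRecord",
    "EndpointLabels",
    "egfr_ckd_epi",
    "invert_ckd_epi",
    "egfr_slope",
    "classify_baseline",
    "classify_progression",
    "mic_class",
    "derive_endpoints",
    "BASELINE_CUTOFF",
    "RAPID_THRESHOLD",
    "MIN_VISITS",
    "MIN_SPAN_MONTHS",
]

BASELINE_CUTOFF = 60.0  # mL/min/1.73 m^2
RAPID_THRESHOLD = 3.0  # mL/min/1.73 m^2 per year of decline
MIN_VISITS = 3
MIN_SPAN_MONTHS = 6.0


@dataclass
class PatientRecord:
    patient_id: str
    age: float  # years at baseline
    sex: str  # "M" | "F"
    height_m: float
    creatinine: list[tuple[float, float]]  # (months from baseline, mg/dL)
    ht_tkv: float | None = None  # mL per metre of height
    tolvaptan: bool = False
    mic: str | None = None

    def __post_init__(self) -> None:
        times = [t for t, _ in self.creatinine]
        if any(v <= 0 for _, v in self.creatinine):
            raise ValueError(f"{self.patient_id}: creatinine values must be positive")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"{self.patient_id}: visit times must be strictly increasing")
        if self.ht_tkv is not None and self.ht_tkv <= 0:
            raise ValueError(f"{self.patient_id}: ht-TKV must be positive")
        if self.sex not in ("M", "F"):
            raise ValueError(f"{self.patient_id}: sex must be 'M' or 'F'")


@dataclass
class EndpointLabels:
    patient_id: str
    egfr0: float
    baseline_class: str  # "early" | "late"
    slope: float | None  # mL/min/1.73 m^2 per year
    progression_class: str | None  # "rapid" | "non-rapid" | None if ineligible
    n_visits: int
    span_months: float
    exclusion_reason: str | None = field(default=None)


def egfr_ckd_epi(creatinine: float, age: float, sex: str, equation: str = "2009") -> float:
    """Estimated GFR (mL/min/1.73 m^2) from serum creatinine (mg/dL).

    ``equation="2009"`` is the CKD-EPI creatinine equation without the race
    coefficient (the default); ``"2021"`` selects the race-free refit.
    """
    if creatinine <= 0:
        raise ValueError("creatinine must be positive")
    if not (18 <= age <= 110):
        raise ValueError("age outside the adult range 18-110")
    if sex not in ("M", "F"):
        raise ValueError("sex must be 'M' or 'F'")
    female = sex == "F"
    kappa = 0.7 if female else 0.9
    r = creatinine / kappa
    if equation == "2009":
        alpha = -0.329 if female else -0.411
        g = 141.0 * min(r, 1.0) ** alpha * max(r, 1.0) ** -1.209 * 0.993**age
        if female:
            g *= 1.018
    elif equation == "2021":
        alpha = -0.241 if female else -0.302
        g = 142.0 * min(r, 1.0) ** alpha * max(r, 1.0) ** -1.200 * 0.9938**age
        if female:
            g *= 1.012
    else:
        raise ValueError(f"unknown CKD-EPI equation vintage {equation!r}")
    return float(g)


def invert_ckd_epi(
    egfr: float,
    age: float,
    sex: str,
    equation: str = "2009",
    lo: float = 0.2,
    hi: float = 20.0,
    tol: float = 1e-8,
) -> float:
    """Serum creatinine (mg/dL) that yields the target eGFR, by bisection.

    The equation is strictly decreasing in creatinine, so bisection on
    [0.2, 20] mg/dL converges; targets outside the achievable range are
    capped at the nearer bound with a warning.
    """
    g_lo = egfr_ckd_epi(lo, age, sex, equation)  # highest achievable eGFR
    g_hi = egfr_ckd_epi(hi, age, sex, equation)  # lowest achievable eGFR
    if egfr >= g_lo:
        logger.warning("target eGFR %.1f above achievable range; creatinine capped at %.2f", egfr, lo)
        return lo
    if egfr <= g_hi:
        logger.warning("target eGFR %.1f below achievable range; creatinine capped at %.2f", egfr, hi)
        return hi
    a, b = lo, hi
    while b - a > tol:
        mid = 0.5 * (a + b)
        if egfr_ckd_epi(mid, age, sex, equation) > egfr:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


def egfr_slope(series: list[tuple[float, float]]) -> tuple[float, float]:
    """OLS slope (per year) and intercept of eGFR on time in years.

    ``series`` holds (time in years from first visit, eGFR) pairs; at least
    three points spanning at least six months are required.
    """
    if len(series) < MIN_VISITS:
        raise ValueError(f"need at least {MIN_VISITS} eGFR values")
    t = np.asarray([p[0] for p in series], dtype=float)
    g = np.asarray([p[1] for p in series], dtype=float)
    if (t.max() - t.min()) * 12.0 < MIN_SPAN_MONTHS:
        raise ValueError(f"follow-up shorter than {MIN_SPAN_MONTHS} months")
    res = stats.linregress(t, g)
    return float(res.slope), float(res.intercept)


def classify_baseline(egfr0: float, cutoff: float = BASELINE_CUTOFF) -> str:
    """"late" CKD below the cutoff, "early" at or above it."""
    return "late" if egfr0 < cutoff else "early"


def classify_progression(slope: float, threshold: float = RAPID_THRESHOLD) -> str:
    """"rapid" when the decline exceeds the threshold (slope < -threshold)."""
    return "rapid" if slope < -threshold else "non-rapid"


# theoretical ht-TKV growth rates (fraction/year) separating the five
# age-adjusted risk classes; the reference trajectory starts at 150 mL/m
# at age 20
_MIC_RATES = (0.015, 0.03, 0.045, 0.06)
_MIC_CLASSES = ("1A", "1B", "1C", "1D", "1E")


def mic_class(ht_tkv: float, age: float) -> str:
    """Age/ht-TKV risk class 1A..1E from theoretical growth trajectories.

    The class boundaries are the curves 150*(1+r)^(age-20) for yearly
    growth rates r of 1.5%, 3%, 4.5% and 6%; values on a boundary take the
    lower class.
    """
    if ht_tkv <= 0:
        raise ValueError("ht-TKV must be positive")
    for rate, cls in zip(_MIC_RATES, _MIC_CLASSES):
        if ht_tkv <= 150.0 * (1.0 + rate) ** (age - 20.0):
            return cls
    return _MIC_CLASSES[-1]


def derive_endpoints(
    clinical: pd.DataFrame,
    equation: str = "2009",
    baseline_cutoff: float = BASELINE_CUTOFF,
    rapid_threshold: float = RAPID_THRESHOLD,
) -> pd.DataFrame:
    """Endpoint table from a long-format clinical table.

    ``clinical`` needs columns patient_id, age, sex, visit_month,
    creatinine_mg_dl (one row per creatinine measurement; age is the
    baseline age). Returns one row per patient with egfr0, baseline_class,
    slope, progression_class, n_visits, span_months and, for patients not
    eligible for slope estimation, the exclusion reason.
    """
    rows = []
    for pid, grp in clinical.groupby("patient_id", sort=True):
        grp = grp.sort_values("visit_month")
        age = float(grp["age"].iloc[0])
        sex = str(grp["sex"].iloc[0])
        months = grp["visit_month"].to_numpy(dtype=float)
        creat = grp["creatinine_mg_dl"].to_numpy(dtype=float)
        egfr = np.array([egfr_ckd_epi(c, age, sex, equation) for c in creat])
        egfr0 = float(egfr[0])
        span = float(months[-1] - months[0])
        n_vis = len(months)

        slope = None
        prog = None
        reason = None
        if n_vis < MIN_VISITS:
            reason = f"only {n_vis} creatinine values (minimum {MIN_VISITS})"
        elif span < MIN_SPAN_MONTHS:
            reason = f"follow-up {span:.1f} months (minimum {MIN_SPAN_MONTHS:.0f})"
        else:
            years = (months - months[0]) / 12.0
            slope, _ = egfr_slope(list(zip(years, egfr)))
            prog = classify_progression(slope, rapid_threshold)
        if reason is not None:
            logger.info("patient %s excluded from slope analysis: %s", pid, reason)

        rows.append(
            {
                "patient_id": pid,
                "egfr0": egfr0,
                "baseline_class": classify_baseline(egfr0, baseline_cutoff),
                "slope": np.nan if slope is None else slope,
                "progression_class": prog,
                "n_visits": n_vis,
                "span_months": span,
                "exclusion_reason": reason,
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")
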