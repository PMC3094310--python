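"""First-order depuration kinetics.

Tissue concentration during the clean-water phase is modelled as
C_t = C_0 * exp(-k t) with elimination rate constant k (per day).  The default
fit is ordinary least squares of ln C on t (closed form, exact maximum
likelihood under multiplicative lognormal error); a nonlinear raw-scale fit
seeded by the log-linear solution is also available.  Half-life is ln(2)/k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import DomainError, ValidationError

LOG_LINEAR = "log_linear"
NONLINEAR = "nonlinear"

__all__ = [
    "EliminationSeries",
    "EliminationFit",
    "fit_elimination",
    "half_life",
    "LOG_LINEAR",
    "NONLINEAR",
]


@dataclass
class EliminationSeries:
    """Depuration time course: times in days since transfer to clean water."""

    chemical_id: str
    times: np.ndarray
    concentrations: np.ndarray
    provenance: Optional[dict] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape:
            raise ValidationError("times and concentrations must align")
        if np.unique(self.times).size < 3:
            raise ValidationError("need at least 3 distinct time points")
        if np.any(np.diff(self.times) < 0):
            raise ValidationError("times must be sorted (replicates per time allowed)")
        if np.any(self.times < 0):
            raise ValidationError("times must be non-negative")
        if np.any(self.concentrations <= 0):
            raise ValidationError("concentrations must be positive")


@dataclass(frozen=True)
class EliminationFit:
    chemical_id: str
    k: float
    c0: float
    r2: float
    method: str
    half_life: Optional[float]
    no_elimination: bool

    def to_record(self) -> dict:
        return {
            "chemical": self.chemical_id,
            "k_per_day": self.k,
            "C0": self.c0,
            "R2": self.r2,
            "half_life_days": self.half_life,
            "method": self.method,
            "no_elimination": self.no_elimination,
        }


def half_life(k: float) -> float:
    """Half-life ln(2)/k in days; defined only for k > 0."""
    if k <= 0:
        raise DomainError("half-life requires a positive elimination constant")
    return math.log(2.0) / k


def fit_elimination(series: EliminationSeries, method: str = LOG_LINEAR) -> EliminationFit:
    """Fit C_t = C0 * exp(-k t).

    log_linear: OLS of ln C on t; k = -slope, C0 = exp(intercept), R2 on the
    log scale.  nonlinear: raw-scale least squares seeded by the log-linear
    fit, R2 on the raw scale.  A non-positive k is returned but flagged
    (no elimination).
    """
    t = series.times
    c = series.concentrations
    if method not in (LOG_LINEAR, NONLINEAR):
        raise ValidationError(f"unknown method {method!r}")
    if np.any(c <= 0):
        raise DomainError("log-linear elimination fit requires positive concentrations")

    logc = np.log(c)
    if np.ptp(logc) == 0:  # constant series: no information about elimination
        return EliminationFit(
            chemical_id=series.chemical_id,
            k=0.0,
            c0=float(c[0]),
            r2=0.0,
            method=method,
            half_life=None,
            no_elimination=True,
        )

    slope, intercept = np.polyfit(t, logc, 1)
    k = -float(slope)
    c0 = float(math.exp(intercept))
    if method == LOG_LINEAR:
        fitted = intercept + slope * t
        ss_res = float(np.sum((logc - fitted) ** 2))
        ss_tot = float(np.sum((logc - logc.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    else:
        popt, _ = curve_fit(
            lambda tt, c0_, k_: c0_ * np.exp(-k_ * tt), t, c, p0=[c0, k], maxfev=10000
        )
        c0, k = float(popt[0]), float(popt[1])
        fitted = c0 * np.exp(-k * t)
        ss_res = float(np.sum((c - fitted) ** 2))
        ss_tot = float(np.sum((c - c.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    flagged = k <= 0
    return EliminationFit(
        chemical_id=series.chemical_id,
        k=k,
        c0=c0,
        r2=r2,
        method=method,
        half_life=half_life(k) if k > 0 else None,
        no_elimination=flagged,
    )
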