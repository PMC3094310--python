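"""Single-chemical log-logistic dose-response curves, ECx inversion, toxic units
and the fixed equitoxic mixture design.

The working model for a biomarker endpoint y measured at exposure concentration
c is the two- (optionally three-) parameter log-logistic

    decreasing:  y(c) = theta_min + (theta_max - theta_min) / (1 + (c/EC50)^beta)
    increasing:  y(c) = theta_min + (theta_max - theta_min) * (c/EC50)^beta / (1 + (c/EC50)^beta)

so that the control response (c = 0) sits at the unharmed extreme and the
response at c = EC50 is the midpoint.  On the *effect fraction* scale

    x(c) = (c/EC50)^beta / (1 + (c/EC50)^beta)

both directions share the same closed-form inversion

    ECx = EC50 * (x / (100 - x))^(1/beta),   x in percent.

Toxic units are linear in concentration (TU = c / EC50).  The equitoxic
mixture design follows the convention that a nominal mixture level of T toxic
units is obtained by combining each of the n components at its EC(50*T/n):
a 1.0 TU binary mixture pairs the two EC25 concentrations, a 0.5 TU mixture
the two EC12.5 concentrations, and a single chemical at 1.0 TU is its EC50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .exceptions import (
    ConvergenceError,
    DomainError,
    IdentifiabilityError,
    ValidationError,
)

DECREASING = "decreasing"
INCREASING = "increasing"
_DIRECTIONS = (DECREASING, INCREASING)

__all__ = [
    "DECREASING",
    "INCREASING",
    "DoseResponseData",
    "DoseResponseModel",
    "ECEstimate",
    "FitStats",
    "MixtureDesign",
    "design_equitoxic_mixture",
    "ec_x",
    "fit_loglogistic",
    "toxic_units",
]


@dataclass
class DoseResponseData:
    """A concentration-response table for one chemical and one endpoint."""

    chemical_id: str
    concentrations: np.ndarray
    responses: np.ndarray
    replicate_id: Optional[Sequence] = None
    provenance: Optional[dict] = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValidationError("concentrations and responses must align")
        if self.concentrations.size == 0:
            raise ValidationError("empty dose-response table")
        if np.any(self.concentrations < 0):
            raise ValidationError("concentrations must be non-negative")
        if not np.all(np.isfinite(self.responses)):
            raise ValidationError("responses must be finite")
        distinct = np.unique(self.concentrations)
        if distinct.size < 3 or 0.0 not in distinct:
            raise ValidationError(
                "need at least 3 distinct concentrations including a control at 0"
            )

    @property
    def n(self) -> int:
        return int(self.responses.size)


@dataclass(frozen=True)
class DoseResponseModel:
    """Fitted (or postulated) log-logistic curve for one chemical/endpoint."""

    theta_max: float
    ec50: float
    beta: float
    theta_min: float = 0.0
    direction: str = DECREASING
    chemical_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValidationError("ec50 must be positive")
        if self.beta <= 0:
            raise ValidationError("beta must be positive")
        if self.theta_max == self.theta_min:
            raise ValidationError("theta_max must differ from theta_min")
        if self.direction not in _DIRECTIONS:
            raise ValidationError(f"direction must be one of {_DIRECTIONS}")

    def predict(self, c):
        """Predicted response at concentration(s) ``c``."""
        c = np.asarray(c, dtype=float)
        frac = self._effect_fraction_raw(c)
        if self.direction == DECREASING:
            y = self.theta_max - (self.theta_max - self.theta_min) * frac
        else:
            y = self.theta_min + (self.theta_max - self.theta_min) * frac
        return y if y.shape else float(y)

    def effect_fraction(self, c):
        """Fraction of the maximal effect (0 at control, 1 at full effect)."""
        frac = self._effect_fraction_raw(np.asarray(c, dtype=float))
        return frac if frac.shape else float(frac)

    def _effect_fraction_raw(self, c: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            r = np.power(np.where(c > 0, c, np.nan) / self.ec50, self.beta)
        frac = np.where(np.asarray(c) > 0, r / (1.0 + r), 0.0)
        return frac


@dataclass(frozen=True)
class ECEstimate:
    """Concentration producing x% of the maximal effect."""

    x: float
    concentration: float


@dataclass(frozen=True)
class FitStats:
    ss_res: float
    r2: float
    n: int


def _predict_vec(p, c, direction, free_theta_min):
    theta_max, log_ec50, log_beta = p[0], p[1], p[2]
    theta_min = p[3] if free_theta_min else 0.0
    m = DoseResponseModel.__new__(DoseResponseModel)
    object.__setattr__(m, "theta_max", theta_max)
    object.__setattr__(m, "ec50", math.exp(log_ec50))
    object.__setattr__(m, "beta", math.exp(log_beta))
    object.__setattr__(m, "theta_min", theta_min)
    object.__setattr__(m, "direction", direction)
    object.__setattr__(m, "chemical_id", None)
    return m.predict(c)


def fit_loglogistic(
    data: DoseResponseData,
    direction: str = DECREASING,
    free_theta_min: bool = False,
    ss_tol: float = 1e-10,
):
    """Least-squares fit of the log-logistic curve.

    Additive Gaussian error on the response scale is assumed, so least squares
    is the maximum-likelihood fit.  theta_min is fixed at 0 unless
    ``free_theta_min``; freeing it requires at least 4 distinct concentrations.
    A small multi-start grid (log-spaced EC50 seeds crossed with slope seeds
    beta in {0.5, 1, 2, 4}) guards against local minima.

    Returns ``(DoseResponseModel, FitStats)``.
    """
    if direction not in _DIRECTIONS:
        raise ValidationError(f"direction must be one of {_DIRECTIONS}")
    c = data.concentrations
    y = data.responses
    if np.ptp(y) == 0:
        raise IdentifiabilityError("all responses equal: curve parameters not identifiable")
    n_distinct = np.unique(c).size
    if free_theta_min and n_distinct < 4:
        raise IdentifiabilityError(
            "freeing theta_min requires at least 4 distinct concentrations"
        )

    pos = c[c > 0]
    lo, hi = float(pos.min()), float(pos.max())
    ec50_seeds = np.exp(np.linspace(math.log(lo), math.log(hi), 2)) if hi > lo else [lo, lo]
    beta_seeds = (0.5, 1.0, 2.0, 4.0)
    theta0 = float(y[c == 0].mean()) if direction == DECREASING else float(y[c == c.max()].mean())
    if theta0 == 0:
        theta0 = float(np.max(np.abs(y))) or 1.0

    span = float(np.max(np.abs(y))) or 1.0
    bounds_lo = [-10 * span, math.log(lo) - 8.0, math.log(0.05)]
    bounds_hi = [10 * span, math.log(hi) + 8.0, math.log(50.0)]
    if free_theta_min:
        bounds_lo.append(-10 * span)
        bounds_hi.append(10 * span)

    def resid(p):
        return _predict_vec(p, c, direction, free_theta_min) - y

    best = None
    failures = []
    for e0 in ec50_seeds:
        for b0 in beta_seeds:
            p0 = [theta0, math.log(e0), math.log(b0)]
            if free_theta_min:
                p0.append(float(y.min()) if direction == DECREASING else float(y[c == 0].mean()))
            p0 = np.clip(p0, bounds_lo, bounds_hi)
            try:
                sol = least_squares(
                    resid, p0, bounds=(bounds_lo, bounds_hi), ftol=1e-14, xtol=1e-14, gtol=1e-14
                )
            except Exception as exc:  # pragma: no cover - defensive
                failures.append(str(exc))
                continue
            ss = float(np.sum(sol.fun**2))
            if best is None or ss < best[0] - 0.0:
                best = (ss, sol)
            if ss <= ss_tol:
                break
        else:
            continue
        break

    if best is None:
        raise ConvergenceError(f"all multi-starts failed: {failures}")
    ss, sol = best
    p = sol.x
    model = DoseResponseModel(
        theta_max=float(p[0]),
        ec50=float(math.exp(p[1])),
        beta=float(math.exp(p[2])),
        theta_min=float(p[3]) if free_theta_min else 0.0,
        direction=direction,
        chemical_id=data.chemical_id,
    )
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss / ss_tot if ss_tot > 0 else float("nan")
    return model, FitStats(ss_res=ss, r2=r2, n=data.n)


def ec_x(model: DoseResponseModel, x: float) -> ECEstimate:
    """Closed-form ECx inversion: EC50 * (x/(100-x))^(1/beta), x in (0, 100)."""
    if not 0 < x < 100:
        raise DomainError("effect level x must lie strictly between 0 and 100 (%)")
    conc = model.ec50 * (x / (100.0 - x)) ** (1.0 / model.beta)
    return ECEstimate(x=float(x), concentration=float(conc))


def toxic_units(c: float, model: DoseResponseModel) -> float:
    """Concentration expressed in toxic units, TU = c / EC50."""
    if c < 0:
        raise DomainError("concentration must be non-negative")
    return float(c) / model.ec50


@dataclass(frozen=True)
class MixtureDesign:
    """Per-component concentrations realizing a nominal mixture TU level."""

    tu_level: float
    component_concentrations: Mapping[str, float]
    effect_level_per_component: float = field(default=float("nan"))


def design_equitoxic_mixture(
    models: Optional[Mapping[str, DoseResponseModel]] = None,
    ecx_table: Optional[Mapping[str, Mapping[float, float]]] = None,
    tu_level: float = 1.0,
) -> MixtureDesign:
    """Equitoxic mixture design at a nominal total ``tu_level``.

    Each of the n components contributes tu_level/n toxic units, i.e. is dosed
    at its EC(50*tu_level/n): a 1.0 TU binary mixture combines the two EC25
    values, a 0.5 TU mixture the two EC12.5 values, and a single chemical at
    1.0 TU is dosed at its EC50.

    An explicit ``ecx_table`` (chemical -> {effect level x -> concentration})
    takes precedence over model inversion.
    """
    source = ecx_table if ecx_table is not None else models
    if not source:
        raise ValidationError("provide models or an ecx_table")
    chemicals = list(source)
    x = 50.0 * tu_level / len(chemicals)
    if not 0 < x < 100:
        raise DomainError(
            f"per-component effect level {x}% outside (0, 100); tu_level infeasible"
        )
    comps = {}
    for chem in chemicals:
        if ecx_table is not None:
            table = ecx_table[chem]
            match = [xv for xv in table if math.isclose(float(xv), x, rel_tol=1e-9, abs_tol=1e-9)]
            if not match:
                raise LookupError(f"no EC{x:g} entry for {chem!r} in ecx_table")
            comps[chem] = float(table[match[0]])
        else:
            if models is None or chem not in models:
                raise LookupError(f"no model for chemical {chem!r}")
            comps[chem] = ec_x(models[chem], x).concentration
    return MixtureDesign(
        tu_level=float(tu_level),
        component_concentrations=comps,
        effect_level_per_component=x,
    )
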