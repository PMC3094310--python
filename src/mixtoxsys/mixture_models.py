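"""Binary-mixture response surfaces under Concentration Addition (CA) and
Independent Action (IA), with parametric deviation terms and the nested
likelihood-ratio ladder that classifies interactions.

Both reference models are driven by the single-chemical log-logistic marginals
(theta_max, EC50_i, beta_i) on a *decreasing* response scale (increasing
endpoints are flipped to theta_ref - y before fitting).

Concentration Addition.  The predicted response y at (c1, c2) solves

    c1/ECy_1 + c2/ECy_2 = exp(G),      ECy_i = EC50_i * ((theta_max - y)/y)^(1/beta_i)

i.e. components act as dilutions of one another; with G = 0 the toxic-unit sum
at the predicted effect level is 1.  The left side is strictly increasing in y,
so the root is found by bisection.

Independent Action.  With unaffected fractions q_i = 1/(1 + (c_i/EC50_i)^beta_i),

    y = theta_max * (q1 * q2)^(exp(-G))

so G = 0 recovers the independence product and the surface reduces to the
single-chemical curve on each axis.

Deviation function.  G is built from EC50-based toxic-unit shares
z_i = (c_i/EC50_i) / TU_total, TU_total = sum_i c_i/EC50_i:

    NONE   G = 0
    SA     G = a * z1 * z2                      (overall synergism/antagonism)
    DR     G = (a + b*z1) * z1 * z2             (dose-ratio dependent)
    DL     G = a * z1 * z2 * (1 - b*TU_total)   (dose-level dependent; the
                                                 deviation changes sign at
                                                 TU_total = 1/b)

Sign convention: a > 0 pushes the surface *above* the reference (higher
response = less toxic = antagonism); a < 0 encodes synergism.  G vanishes on
the axes (z1*z2 = 0), so deviations never distort the marginals.

Nested fits (reference -> SA -> DL) are compared with the Gaussian
profiled-variance likelihood-ratio statistic chi2 = n*ln(SS_reduced/SS_full)
against a chi-square with df = delta parameter count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .exceptions import (
    ConvergenceError,
    NumericalError,
    ValidationError,
)

CA = "CA"
IA = "IA"
_FRAMEWORKS = (CA, IA)

NONE = "NONE"
SA = "SA"
DR = "DR"
DL = "DL"
_KINDS = (NONE, SA, DR, DL)

ANTAGONISM = "antagonism"
SYNERGISM = "synergism"
NO_INTERACTION = "no_interaction"

__all__ = [
    "CA", "IA", "NONE", "SA", "DR", "DL",
    "ANTAGONISM", "SYNERGISM", "NO_INTERACTION",
    "MixturePoint", "SurfaceParams", "SurfaceFit", "LRTestResult",
    "InteractionVerdict", "InteractionAnalysis",
    "deviation_G", "predict_ca", "predict_ia", "predict_surface",
    "fit_surface", "lr_test", "reference_significance",
    "classify_interaction", "verdict_from_evidence", "to_decreasing",
]


@dataclass(frozen=True)
class MixturePoint:
    c1: float
    c2: float
    response: float


@dataclass(frozen=True)
class SurfaceParams:
    """Joint surface parameters: shared plateau, two marginals, deviations."""

    theta_max: float
    ec50_1: float
    beta_1: float
    ec50_2: float
    beta_2: float
    deviation: str = NONE
    a: Optional[float] = None
    b: Optional[float] = None

    def __post_init__(self) -> None:
        if self.deviation not in _KINDS:
            raise ValidationError(f"deviation must be one of {_KINDS}")
        for name in ("ec50_1", "beta_1", "ec50_2", "beta_2"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.theta_max <= 0:
            raise ValidationError("theta_max must be positive")
        if self.deviation == NONE and self.a is not None:
            raise ValidationError("a given but deviation is NONE")
        if self.deviation != NONE and self.a is None:
            raise ValidationError(f"deviation {self.deviation} requires a")
        if self.deviation in (DR, DL) and self.b is None:
            raise ValidationError(f"deviation {self.deviation} requires b")
        if self.deviation in (NONE, SA) and self.b is not None:
            raise ValidationError("b only meaningful for DR/DL deviations")

    @property
    def k_params(self) -> int:
        return 5 + (self.a is not None) + (self.b is not None)


def deviation_G(a, b, z1, z2, tu_total, kind: str):
    """Deviation term G evaluated at toxic-unit shares (z1, z2) and TU_total."""
    if kind not in _KINDS:
        raise ValidationError(f"unknown deviation kind {kind!r}")
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if kind == NONE:
        out = np.zeros(np.broadcast(z1, z2).shape)
        return out if out.shape else 0.0
    if a is None:
        raise ValidationError(f"deviation {kind} requires a")
    if kind == SA:
        out = a * z1 * z2
    else:
        if b is None:
            raise ValidationError(f"deviation {kind} requires b")
        if kind == DR:
            out = (a + b * z1) * z1 * z2
        else:  # DL
            out = a * z1 * z2 * (1.0 - b * np.asarray(tu_total, dtype=float))
    out = np.asarray(out, dtype=float)
    return out if out.shape else float(out)


def _shares(params: SurfaceParams, c1: np.ndarray, c2: np.ndarray):
    t1 = c1 / params.ec50_1
    t2 = c2 / params.ec50_2
    tu = t1 + t2
    with np.errstate(invalid="ignore", divide="ignore"):
        z1 = np.where(tu > 0, t1 / np.where(tu > 0, tu, 1.0), 0.0)
    z2 = np.where(tu > 0, 1.0 - z1, 0.0)
    return z1, z2, tu


def _G(params: SurfaceParams, c1: np.ndarray, c2: np.ndarray) -> np.ndarray:
    z1, z2, tu = _shares(params, c1, c2)
    return np.asarray(deviation_G(params.a, params.b, z1, z2, tu, params.deviation))


def predict_ca(params: SurfaceParams, c1, c2, n_bisect: int = 90):
    """CA surface prediction; implicit root solved by vectorized bisection."""
    c1a, c2a = np.broadcast_arrays(np.asarray(c1, dtype=float), np.asarray(c2, dtype=float))
    scalar = c1a.ndim == 0
    c1a = np.atleast_1d(c1a).astype(float)
    c2a = np.atleast_1d(c2a).astype(float)
    if np.any(c1a < 0) or np.any(c2a < 0):
        raise ValidationError("concentrations must be non-negative")
    theta = params.theta_max
    y = np.full(c1a.shape, theta, dtype=float)
    mask = (c1a + c2a) > 0
    if mask.any():
        g = _G(params, c1a[mask], c2a[mask])
        target = np.exp(g)
        cc1 = c1a[mask]
        cc2 = c2a[mask]
        eps = 1e-9 * theta
        lo = np.full(cc1.shape, eps)
        hi = np.full(cc1.shape, theta - eps)

        def f(yv):
            ratio = (theta - yv) / yv
            inv1 = params.beta_1
            inv2 = params.beta_2
            ec1 = params.ec50_1 * ratio ** (1.0 / inv1)
            ec2 = params.ec50_2 * ratio ** (1.0 / inv2)
            return cc1 / ec1 + cc2 / ec2 - target

        flo = f(lo)
        fhi = f(hi)
        if not (np.all(np.isfinite(flo)) and np.all(np.isfinite(fhi))):
            raise NumericalError("CA surface evaluation produced non-finite values")
        # The root can fall outside the eps-clamped bracket for extreme trial
        # parameters (near-step marginals); clip to the asymptote there.
        below = flo > 0   # full effect already at y ~ 0
        above = fhi < 0   # no effect even at y ~ theta_max
        solve = ~(below | above)
        for _ in range(n_bisect):
            mid = 0.5 * (lo + hi)
            pos = (f(mid) > 0) & solve
            neg = solve & ~pos
            hi = np.where(pos, mid, hi)
            lo = np.where(neg, mid, lo)
        yy = 0.5 * (lo + hi)
        yy = np.where(below, eps, yy)
        yy = np.where(above, theta - eps, yy)
        y[mask] = yy
    return float(y[0]) if scalar else y


def predict_ia(params: SurfaceParams, c1, c2):
    """IA surface prediction, closed form."""
    c1a, c2a = np.broadcast_arrays(np.asarray(c1, dtype=float), np.asarray(c2, dtype=float))
    scalar = c1a.ndim == 0
    c1a = np.atleast_1d(c1a).astype(float)
    c2a = np.atleast_1d(c2a).astype(float)
    if np.any(c1a < 0) or np.any(c2a < 0):
        raise ValidationError("concentrations must be non-negative")
    q1 = 1.0 / (1.0 + (c1a / params.ec50_1) ** params.beta_1)
    q2 = 1.0 / (1.0 + (c2a / params.ec50_2) ** params.beta_2)
    g = _G(params, c1a, c2a)
    y = params.theta_max * (q1 * q2) ** np.exp(-g)
    return float(y[0]) if scalar else y


def predict_surface(params: SurfaceParams, model_type: str, c1, c2):
    if model_type == CA:
        return predict_ca(params, c1, c2)
    if model_type == IA:
        return predict_ia(params, c1, c2)
    raise ValidationError(f"model_type must be one of {_FRAMEWORKS}")


def to_decreasing(responses, ceiling: Optional[float] = None):
    """Flip an increasing endpoint onto the decreasing effect scale.

    Returns ``(ceiling - responses, ceiling)``; by default the ceiling is the
    maximum observed response, so the most-affected observation maps to 0.
    """
    responses = np.asarray(responses, dtype=float)
    if ceiling is None:
        ceiling = float(responses.max())
    return ceiling - responses, ceiling


@dataclass(frozen=True)
class SurfaceFit:
    model_type: str
    params: SurfaceParams
    ss_res: float
    ss_tot: float
    n: int
    k_params: int
    log_lik: float
    r2: float

    def __post_init__(self) -> None:
        if self.r2 > 1 + 1e-12:
            raise ValidationError("R2 cannot exceed 1")


def _coerce_points(points) -> pd.DataFrame:
    if isinstance(points, pd.DataFrame):
        df = points
        missing = {"c1", "c2", "response"} - set(df.columns)
        if missing:
            raise ValidationError(f"mixture table missing columns {sorted(missing)}")
        return df[["c1", "c2", "response"]].astype(float)
    rows = [(p.c1, p.c2, p.response) for p in points]
    return pd.DataFrame(rows, columns=["c1", "c2", "response"], dtype=float)


def _param_vector(params: SurfaceParams, deviation: str) -> np.ndarray:
    v = [
        params.theta_max,
        math.log(params.ec50_1),
        math.log(params.beta_1),
        math.log(params.ec50_2),
        math.log(params.beta_2),
    ]
    if deviation != NONE:
        v.append(params.a if params.a is not None else 0.0)
    if deviation in (DR, DL):
        v.append(params.b if params.b is not None else 0.0)
    return np.asarray(v, dtype=float)


def _vector_params(v: np.ndarray, deviation: str) -> SurfaceParams:
    a = b = None
    if deviation != NONE:
        a = float(v[5])
    if deviation in (DR, DL):
        b = float(v[6])
    return SurfaceParams(
        theta_max=float(v[0]),
        ec50_1=float(math.exp(v[1])),
        beta_1=float(math.exp(v[2])),
        ec50_2=float(math.exp(v[3])),
        beta_2=float(math.exp(v[4])),
        deviation=deviation,
        a=a,
        b=b,
    )


def _axis_seed(c: np.ndarray, y: np.ndarray, theta0: float) -> float:
    """Rough EC50 seed: dose whose response is nearest to half the plateau."""
    pos = c > 0
    if not pos.any():
        return 1.0
    idx = np.argmin(np.abs(y[pos] - theta0 / 2.0))
    return float(c[pos][idx])


def fit_surface(
    points,
    model_type: str,
    deviation_kind: str = NONE,
    warm_start: Optional[Union[SurfaceFit, SurfaceParams]] = None,
) -> SurfaceFit:
    """Joint least-squares fit of marginals + deviation over pooled axis and
    mixture data (fixed-ray design).

    Deviation fits should be warm-started from their parent fit (done
    automatically by :func:`classify_interaction`); starting at the parent's
    optimum with a = b = 0 guarantees SS never exceeds the parent's.
    """
    if model_type not in _FRAMEWORKS:
        raise ValidationError(f"model_type must be one of {_FRAMEWORKS}")
    if deviation_kind not in _KINDS:
        raise ValidationError(f"deviation_kind must be one of {_KINDS}")
    df = _coerce_points(points)
    c1 = df["c1"].to_numpy()
    c2 = df["c2"].to_numpy()
    y = df["response"].to_numpy()
    n = y.size
    k = 5 + (deviation_kind != NONE) + (deviation_kind in (DR, DL))
    if n <= k:
        raise ValidationError(f"need n > k_params ({k}); got n = {n}")
    interior = (c1 > 0) & (c2 > 0)
    if deviation_kind != NONE and not interior.any():
        raise ValidationError("deviation fits require at least one interior mixture point")

    span = float(np.max(np.abs(y))) or 1.0
    pos = np.concatenate([c1[c1 > 0], c2[c2 > 0]])
    lo_c, hi_c = float(pos.min()), float(pos.max())
    bounds_lo = [1e-8, math.log(lo_c) - 8, math.log(0.05), math.log(lo_c) - 8, math.log(0.05)]
    bounds_hi = [10 * span, math.log(hi_c) + 8, math.log(50.0), math.log(hi_c) + 8, math.log(50.0)]
    if deviation_kind != NONE:
        bounds_lo.append(-100.0)
        bounds_hi.append(100.0)
    if deviation_kind in (DR, DL):
        bounds_lo.append(-100.0)
        bounds_hi.append(100.0)

    def resid(v):
        p = _vector_params(v, deviation_kind)
        return predict_surface(p, model_type, c1, c2) - y

    starts = []
    if warm_start is not None:
        wp = warm_start.params if isinstance(warm_start, SurfaceFit) else warm_start
        v = [
            wp.theta_max,
            math.log(wp.ec50_1), math.log(wp.beta_1),
            math.log(wp.ec50_2), math.log(wp.beta_2),
        ]
        if deviation_kind != NONE:
            v.append(wp.a if wp.a is not None else 0.0)
        if deviation_kind in (DR, DL):
            v.append(wp.b if wp.b is not None else 0.0)
        starts.append(np.asarray(v))
    else:
        controls = y[(c1 == 0) & (c2 == 0)]
        theta0 = float(controls.mean()) if controls.size else float(y.max())
        if theta0 <= 0:
            theta0 = span
        ax1 = c2 == 0
        ax2 = c1 == 0
        e1 = _axis_seed(c1[ax1], y[ax1], theta0)
        e2 = _axis_seed(c2[ax2], y[ax2], theta0)
        for b0 in (2.0, 1.0):
            v = [theta0, math.log(e1), math.log(b0), math.log(e2), math.log(b0)]
            if deviation_kind != NONE:
                v.append(0.0)
            if deviation_kind in (DR, DL):
                v.append(0.0)
            starts.append(np.asarray(v))

    best = None
    failures = []
    for v0 in starts:
        v0 = np.clip(v0, bounds_lo, bounds_hi)
        try:
            sol = least_squares(
                resid, v0, bounds=(bounds_lo, bounds_hi), ftol=1e-12, xtol=1e-12, gtol=1e-12
            )
        except Exception as exc:
            failures.append(f"start {v0}: {exc}")
            continue
        ss = float(np.sum(sol.fun**2))
        if best is None or ss < best[0]:
            best = (ss, sol)
    if best is None:
        raise ConvergenceError("all surface fit starts failed:\n" + "\n".join(failures))
    ss, sol = best

    if warm_start is not None:
        parent_ss = (
            warm_start.ss_res if isinstance(warm_start, SurfaceFit) else None
        )
        if parent_ss is not None and ss > parent_ss * (1 + 1e-9) + 1e-12:
            raise NumericalError(
                f"deviation fit worse than its parent (SS {ss} > {parent_ss})"
            )

    params = _vector_params(sol.x, deviation_kind)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss / ss_tot if ss_tot > 0 else float("nan")
    sigma2 = max(ss / n, 1e-300)
    log_lik = -(n / 2.0) * (math.log(2 * math.pi * sigma2) + 1.0)
    return SurfaceFit(
        model_type=model_type,
        params=params,
        ss_res=ss,
        ss_tot=ss_tot,
        n=n,
        k_params=params.k_params,
        log_lik=log_lik,
        r2=r2,
    )


@dataclass(frozen=True)
class LRTestResult:
    chi2: float
    df: int
    p: float


def lr_test(reduced: SurfaceFit, full: SurfaceFit) -> LRTestResult:
    """Likelihood-ratio test of nested surface fits (profiled Gaussian variance)."""
    if reduced.n != full.n:
        raise ValidationError("nested fits must use the same data (n mismatch)")
    if reduced.k_params >= full.k_params:
        raise ValidationError("reduced model must have fewer parameters than full")
    df = full.k_params - reduced.k_params
    ratio = reduced.ss_res / full.ss_res if full.ss_res > 0 else math.inf
    chi2 = max(0.0, reduced.n * math.log(ratio)) if math.isfinite(ratio) else math.inf
    p = float(stats.chi2.sf(chi2, df))
    return LRTestResult(chi2=float(chi2), df=df, p=p)


def reference_significance(fit: SurfaceFit) -> float:
    """F-test p-value of the fitted reference surface against the grand mean."""
    k = fit.k_params
    n = fit.n
    if n <= k:
        raise ValidationError("too few points for the regression F-test")
    num = (fit.ss_tot - fit.ss_res) / (k - 1)
    den = fit.ss_res / (n - k)
    if den <= 0:
        return 0.0
    return float(stats.f.sf(num / den, k - 1, n - k))


@dataclass(frozen=True)
class InteractionVerdict:
    framework: str
    pattern: str
    dose_level_dependent: bool
    supporting: dict


def verdict_from_evidence(
    p_ref_vs_a: float,
    p_a_vs_dl: Optional[float],
    a_hat: float,
    framework: str = CA,
    alpha: float = 0.05,
) -> InteractionVerdict:
    """Classification rule applied to the ladder's evidence.

    antagonism iff p(ref vs SA) < alpha and a_hat > 0; synergism iff a_hat < 0;
    dose-level dependence iff p(SA vs DL) < alpha.
    """
    if p_ref_vs_a < alpha:
        pattern = ANTAGONISM if a_hat > 0 else SYNERGISM
    else:
        pattern = NO_INTERACTION
    dl_dep = p_a_vs_dl is not None and p_a_vs_dl < alpha
    return InteractionVerdict(
        framework=framework,
        pattern=pattern,
        dose_level_dependent=bool(dl_dep),
        supporting={
            "p_ref_vs_A": p_ref_vs_a,
            "p_A_vs_DL": p_a_vs_dl,
            "a_hat": a_hat,
        },
    )


@dataclass(frozen=True)
class InteractionAnalysis:
    framework: str
    fit_ref: SurfaceFit
    fit_sa: SurfaceFit
    fit_dl: Optional[SurfaceFit]
    p_reference: float
    ref_vs_sa: LRTestResult
    sa_vs_dl: Optional[LRTestResult]
    verdict: InteractionVerdict

    def to_report(self) -> dict:
        """JSON-serializable block mirroring the published ladder layout."""
        block = {
            "framework": self.framework,
            "n": self.fit_ref.n,
            "fit_ref": {"R2": self.fit_ref.r2, "p": self.p_reference},
            "ref_vs_A": {
                "R2": self.fit_sa.r2,
                "chi2": self.ref_vs_sa.chi2,
                "p": self.ref_vs_sa.p,
                "a_hat": self.fit_sa.params.a,
            },
            "verdict": {
                "pattern": self.verdict.pattern,
                "dose_level_dependent": self.verdict.dose_level_dependent,
            },
        }
        if self.fit_dl is not None and self.sa_vs_dl is not None:
            block["A_vs_DL"] = {
                "R2": self.fit_dl.r2,
                "chi2": self.sa_vs_dl.chi2,
                "p": self.sa_vs_dl.p,
                "b_hat": self.fit_dl.params.b,
            }
        return block


def classify_interaction(
    points,
    framework: str = CA,
    alpha: float = 0.05,
    include_dose_level: bool = True,
) -> InteractionAnalysis:
    """Run the nested ladder reference -> SA -> DL and classify the interaction.

    The SA fit is warm-started from the reference; the reference is then
    re-polished from the SA solution (a dropped) so that nesting
    SS(ref) >= SS(SA) >= SS(DL) holds up to optimizer tolerance.
    """
    fit_ref = fit_surface(points, framework, NONE)
    fit_sa = fit_surface(points, framework, SA, warm_start=fit_ref)
    repolish = SurfaceParams(
        theta_max=fit_sa.params.theta_max,
        ec50_1=fit_sa.params.ec50_1,
        beta_1=fit_sa.params.beta_1,
        ec50_2=fit_sa.params.ec50_2,
        beta_2=fit_sa.params.beta_2,
    )
    fit_ref2 = fit_surface(points, framework, NONE, warm_start=repolish)
    if fit_ref2.ss_res < fit_ref.ss_res:
        fit_ref = fit_ref2
        fit_sa2 = fit_surface(points, framework, SA, warm_start=fit_ref)
        if fit_sa2.ss_res < fit_sa.ss_res:
            fit_sa = fit_sa2

    t_ref_sa = lr_test(fit_ref, fit_sa)
    fit_dl = t_sa_dl = None
    if include_dose_level:
        dl_seed = SurfaceParams(
            theta_max=fit_sa.params.theta_max,
            ec50_1=fit_sa.params.ec50_1,
            beta_1=fit_sa.params.beta_1,
            ec50_2=fit_sa.params.ec50_2,
            beta_2=fit_sa.params.beta_2,
            deviation=DL,
            a=fit_sa.params.a,
            b=0.0,
        )
        fit_dl = fit_surface(points, framework, DL, warm_start=fit_sa_as_dl(fit_sa, dl_seed))
        t_sa_dl = lr_test(fit_sa, fit_dl)

    verdict = verdict_from_evidence(
        t_ref_sa.p,
        t_sa_dl.p if t_sa_dl is not None else None,
        fit_sa.params.a,
        framework=framework,
        alpha=alpha,
    )
    return InteractionAnalysis(
        framework=framework,
        fit_ref=fit_ref,
        fit_sa=fit_sa,
        fit_dl=fit_dl,
        p_reference=reference_significance(fit_ref),
        ref_vs_sa=t_ref_sa,
        sa_vs_dl=t_sa_dl,
        verdict=verdict,
    )


def fit_sa_as_dl(fit_sa: SurfaceFit, dl_seed: SurfaceParams) -> SurfaceFit:
    """Repackage an SA fit as a DL warm start (b = 0 leaves residuals unchanged)."""
    return SurfaceFit(
        model_type=fit_sa.model_type,
        params=dl_seed,
        ss_res=fit_sa.ss_res,
        ss_tot=fit_sa.ss_tot,
        n=fit_sa.n,
        k_params=dl_seed.k_params,
        log_lik=fit_sa.log_lik,
        r2=fit_sa.r2,
    )
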