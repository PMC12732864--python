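"""General modifier (Botts-Morales) inhibition kinetics.

The general modifier scheme couples a Michaelis-Menten enzyme E (substrate
S, Michaelis constant Km) to a modifier I (dissociation constant Ki from
free enzyme).  The ternary complex ESI forms with affinity scaled by alpha
(Ki from ES is alpha*Ki; equivalently Km from EI is alpha*Km) and turns over
at a fraction beta of the uninhibited rate:

    alpha > 1, 0 < beta < 1  ->  hyperbolic mixed-type (partial) inhibition
    alpha -> inf, beta = 0   ->  classical competitive inhibition
    alpha = 1, beta = 1      ->  silent modifier (no effect)

Under rapid equilibrium the non-depleted velocity ratio is

    vi/v0 = (1+sigma) * (1 + beta*I/(alpha*Ki))
            / [ 1 + I/Ki + sigma*(1 + I/(alpha*Ki)) ],    sigma = S/Km,

with I the FREE modifier concentration.  When the inhibitor is tight
binding (It comparable to Et) free and total inhibitor differ; the free
concentration solves a quadratic mass balance and the closed form below
(:func:`velocity_with_depletion`) is exact under the same rapid-equilibrium
assumptions.  A numeric equilibrium solver (:func:`equilibrium_oracle`)
serves as the independent reference for both closed forms.

Units are fixed throughout: substrate in uM, inhibitor / enzyme / Ki in nM,
velocities in the units of ``v0_scale`` (signal/s).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from lmfit import Parameters, minimize
from scipy import stats


@dataclass(frozen=True)
class ModifierParams:
    """Parameters of the general modifier rate law.

    Km in uM, Ki in nM, alpha dimensionless (>0), beta in [0,1],
    ``v0_scale`` the uninhibited velocity at the working substrate
    concentration (signal/s), Et total enzyme in nM (only needed for
    depletion-aware calculations).
    """

    Km: float
    Ki: float
    alpha: float
    beta: float
    v0_scale: float = 1.0
    Et: float | None = None

    def __post_init__(self) -> None:
        if self.Km <= 0 or self.Ki <= 0 or self.alpha <= 0 or self.v0_scale <= 0:
            raise ValueError("Km, Ki, alpha and v0_scale must be positive")
        if not 0 <= self.beta <= 1:
            raise ValueError(f"beta must lie in [0,1], got {self.beta}")
        if self.Et is not None and self.Et <= 0:
            raise ValueError("Et must be positive when given")


@dataclass(frozen=True)
class RatePoint:
    """One initial-rate measurement: S (uM), total inhibitor It (nM), velocity v."""

    S: float
    It: float
    v: float

    def __post_init__(self) -> None:
        if self.S <= 0:
            raise ValueError("substrate concentration must be positive")
        if self.It < 0 or self.v < 0:
            raise ValueError("It and v must be nonnegative")


# ---------------------------------------------------------------------------
# Velocity models
# ---------------------------------------------------------------------------

def equilibrium_oracle(
    S: float, It: float, Et: float, params: ModifierParams
) -> dict[str, float]:
    """Numerically solve the rapid-equilibrium species balance of the scheme.

    Substrate is treated as un-depleted (S in uM >> Et in nM).  The free
    inhibitor concentration is found by safeguarded bisection on [0, It] of
    the inhibitor mass balance; the returned ``vi`` uses the normalization
    vi = v0_scale * (ES + beta*ESI) / (Et*sigma/(1+sigma)), so vi equals
    ``v0_scale`` exactly at It = 0.

    Returns a dict with free species concentrations (nM) and ``vi``.
    """
    if Et <= 0:
        raise ValueError("Et must be positive")
    if It < 0:
        raise ValueError("It must be nonnegative")
    sigma = S / params.Km
    aKi = params.alpha * params.Ki

    def free_enzyme(I: float) -> float:
        return Et / (1.0 + sigma + I / params.Ki + sigma * I / aKi)

    def balance(I: float) -> float:
        E = free_enzyme(I)
        return I + E * (I / params.Ki + sigma * I / aKi) - It

    lo, hi = 0.0, It
    # balance(0) = -It <= 0 and balance(It) >= 0; residual is monotone in I.
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if balance(mid) > 0.0:
            hi = mid
        else:
            lo = mid
    I_free = 0.5 * (lo + hi)
    resid = abs(balance(I_free))
    # tolerance scales with the largest concentration in the balance: the
    # balance itself is evaluated in floating point with terms of size ~It
    assert resid < 1e-10 * max(Et, It, 1.0), "bisection failed to close the mass balance"
    E = free_enzyme(I_free)
    ES = E * sigma
    EI = E * I_free / params.Ki
    ESI = E * sigma * I_free / aKi
    vi = params.v0_scale * (ES + params.beta * ESI) / (Et * sigma / (1.0 + sigma))
    return {"E": E, "ES": ES, "EI": EI, "ESI": ESI, "I_free": I_free, "vi": vi}


def velocity_no_depletion(S: float, I: float, params: ModifierParams) -> float:
    """vi/v0 of the general modifier law with free inhibitor I (It >> Et).

    Returns the dimensionless ratio
    (1+sigma)(1 + beta*I/(alpha*Ki)) / [1 + I/Ki + sigma(1 + I/(alpha*Ki))].
    """
    if S <= 0:
        raise ValueError("substrate concentration must be positive")
    if I < 0:
        raise ValueError("inhibitor concentration must be nonnegative")
    sigma = S / params.Km
    aKi = params.alpha * params.Ki
    num = (1.0 + sigma) * (1.0 + params.beta * I / aKi)
    den = 1.0 + I / params.Ki + sigma * (1.0 + I / aKi)
    return num / den


def velocity_with_depletion(
    S: float, It: float, Et: float, params: ModifierParams
) -> float:
    """Depletion-aware (tight-binding) velocity, in units of ``v0_scale``.

    Free inhibitor I solves the quadratic mass balance

        x^2 + x*[(1+sigma) + c*(Et - It)] - It*c*(1+sigma) = 0,
        x = I*c,  c = (alpha + sigma) / (alpha*Ki),

    and the velocity is the non-depleted law evaluated at that free I:
    vi = v0 * (1+sigma)(1 + beta*I/(alpha*Ki)) / ((1+sigma) + x).

    This closed form is exact under rapid equilibrium with un-depleted
    substrate and agrees with :func:`equilibrium_oracle` to relative 1e-6.
    """
    if Et <= 0:
        raise ValueError("Et must be positive")
    if It < 0:
        raise ValueError("It must be nonnegative")
    sigma = S / params.Km
    aKi = params.alpha * params.Ki
    c = (params.alpha + sigma) / aKi
    b = (1.0 + sigma) + c * (Et - It)
    x = 0.5 * (-b + math.sqrt(b * b + 4.0 * It * c * (1.0 + sigma)))
    I_free = x / c
    num = (1.0 + sigma) * (1.0 + params.beta * I_free / aKi)
    return params.v0_scale * num / ((1.0 + sigma) + x)


# ---------------------------------------------------------------------------
# Specific velocity plot (alpha, beta, Ki from primary/secondary lines)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineFit:
    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float
    intercept_stderr: float


@dataclass(frozen=True)
class SpecificVelocityAnalysis:
    """Primary and secondary specific-velocity-plot fits and the estimates.

    Primary stage: per inhibitor concentration It, v0/vi is linear in
    x = sigma/(1+sigma); a0 and a1 are the fitted values at x = 0 and x = 1.
    Secondary stage: 1/(a1 - 1) and 1/(a0 - 1) are linear in 1/It; their
    slopes and intercepts give

        beta  = c1 / (1 + c1)          (c1: intercept of the a1 line)
        aKi   = s1 * (1 - beta)        (s1: slope of the a1 line)
        alpha = beta + beta / c2       (c2: intercept of the a0 line)
        Ki    = aKi / alpha.
    """

    primary: dict[float, LineFit]  # It -> line of v0/vi vs sigma/(1+sigma)
    a1_values: dict[float, float]
    a0_values: dict[float, float]
    secondary_a1: LineFit  # 1/(a1-1) vs 1/It
    secondary_a0: LineFit  # 1/(a0-1) vs 1/It
    alpha_hat: float
    beta_hat: float
    Ki_hat: float
    alpha_stderr: float
    beta_stderr: float
    Ki_stderr: float
    excluded_It: tuple[float, ...] = ()


def _linfit(x: np.ndarray, y: np.ndarray) -> LineFit:
    if len(x) == 2:
        # exact line through two points; stderr undefined
        slope = (y[1] - y[0]) / (x[1] - x[0])
        return LineFit(float(slope), float(y[0] - slope * x[0]), 1.0, math.nan, math.nan)
    res = stats.linregress(x, y)
    return LineFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_stderr=float(res.stderr),
        intercept_stderr=float(res.intercept_stderr),
    )


def specific_velocity_analysis(
    points: Sequence[RatePoint],
    Km: float,
    Et: float | None = None,
) -> SpecificVelocityAnalysis:
    """Estimate alpha, beta and Ki from initial rates via the specific velocity plot.

    Requires an uninhibited series (It = 0) defining v0 at every substrate
    concentration, and at least 3 inhibitor concentrations with at least 3
    distinct S each.  Primary lines are meaningful only when free ~ total
    inhibitor; when ``Et`` is given, It/Et < 20 triggers a warning.
    Inhibitor concentrations showing no inhibition (fitted a0 <= 1 or
    a1 <= 1) are excluded with a warning.
    """
    if Km <= 0:
        raise ValueError("Km must be positive")
    by_It: dict[float, list[RatePoint]] = {}
    for p in points:
        by_It.setdefault(p.It, []).append(p)
    if 0.0 not in by_It:
        raise ValueError("an uninhibited (It = 0) series is required to define v0")
    # average duplicate v0 measurements per substrate concentration
    acc: dict[float, list[float]] = {}
    for p in by_It[0.0]:
        acc.setdefault(p.S, []).append(p.v)
    v0_by_S = {S: float(np.mean(vs)) for S, vs in acc.items()}

    primary: dict[float, LineFit] = {}
    a1_values: dict[float, float] = {}
    a0_values: dict[float, float] = {}
    excluded: list[float] = []
    for It in sorted(k for k in by_It if k > 0):
        if Et is not None and It / Et < 20:
            warnings.warn(
                f"It={It} nM is less than 20x Et={Et} nM; free inhibitor may be "
                "depleted and the primary line biased",
                stacklevel=2,
            )
        pts = by_It[It]
        S_vals = sorted({p.S for p in pts})
        if len(S_vals) < 3:
            raise ValueError(f"need >= 3 distinct substrate concentrations at It={It}")
        missing = [p.S for p in pts if p.S not in v0_by_S]
        if missing:
            raise ValueError(
                f"no It=0 reference velocity for substrate concentration(s) {missing}"
            )
        x = np.array([p.S / Km / (1.0 + p.S / Km) for p in pts])
        y = np.array([v0_by_S[p.S] / p.v for p in pts])
        line = _linfit(x, y)
        a0 = line.intercept
        a1 = line.intercept + line.slope
        if a0 <= 1.0 or a1 <= 1.0:
            warnings.warn(
                f"It={It} nM shows no inhibition (a0={a0:.4g}, a1={a1:.4g}); excluded",
                stacklevel=2,
            )
            excluded.append(It)
            continue
        primary[It] = line
        a0_values[It] = a0
        a1_values[It] = a1
    if len(primary) < 3:
        raise ValueError(
            f"only {len(primary)} usable inhibitor concentrations (need >= 3)"
        )

    inv_It = np.array([1.0 / It for It in primary])
    y1 = np.array([1.0 / (a1_values[It] - 1.0) for It in primary])
    y0 = np.array([1.0 / (a0_values[It] - 1.0) for It in primary])
    sec1 = _linfit(inv_It, y1)
    sec0 = _linfit(inv_It, y0)
    s1, c1 = sec1.slope, sec1.intercept
    c2 = sec0.intercept
    if c1 <= 0 or c2 <= 0:
        raise ValueError(
            "secondary intercepts are nonpositive; beta ~ 0 (hyperbolic character "
            "absent) and alpha is not identifiable from this design"
        )
    beta = c1 / (1.0 + c1)
    aKi = s1 * (1.0 - beta)
    alpha = beta + beta / c2
    Ki = aKi / alpha

    # first-order error propagation from the secondary-line standard errors
    # (covariance between the two secondary fits is neglected)
    var_c1 = sec1.intercept_stderr**2 if math.isfinite(sec1.intercept_stderr) else math.nan
    var_s1 = sec1.slope_stderr**2 if math.isfinite(sec1.slope_stderr) else math.nan
    var_c2 = sec0.intercept_stderr**2 if math.isfinite(sec0.intercept_stderr) else math.nan
    dbeta_dc1 = 1.0 / (1.0 + c1) ** 2
    beta_se = math.sqrt(var_c1) * dbeta_dc1 if math.isfinite(var_c1) else math.nan
    dalpha_dc1 = dbeta_dc1 * (1.0 + 1.0 / c2)
    dalpha_dc2 = -beta / c2**2
    alpha_se = (
        math.sqrt(dalpha_dc1**2 * var_c1 + dalpha_dc2**2 * var_c2)
        if math.isfinite(var_c1) and math.isfinite(var_c2)
        else math.nan
    )
    # Ki = s1*(1-beta)/alpha
    dKi_ds1 = (1.0 - beta) / alpha
    dKi_dbeta = -s1 / alpha
    dKi_dalpha = -Ki / alpha
    Ki_se = (
        math.sqrt(
            dKi_ds1**2 * var_s1
            + (dKi_dbeta * dbeta_dc1) ** 2 * var_c1
            + dKi_dalpha**2 * alpha_se**2
        )
        if math.isfinite(var_s1) and math.isfinite(var_c1) and math.isfinite(alpha_se)
        else math.nan
    )

    return SpecificVelocityAnalysis(
        primary=primary,
        a1_values=a1_values,
        a0_values=a0_values,
        secondary_a1=sec1,
        secondary_a0=sec0,
        alpha_hat=float(alpha),
        beta_hat=float(beta),
        Ki_hat=float(Ki),
        alpha_stderr=float(alpha_se),
        beta_stderr=float(beta_se),
        Ki_stderr=float(Ki_se),
        excluded_It=tuple(excluded),
    )


# ---------------------------------------------------------------------------
# Depletion-aware Ki fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    """Converged nonlinear fit of the depletion-aware velocity model."""

    params: ModifierParams
    stderr: dict[str, float]
    residuals: np.ndarray = field(repr=False)
    converged: bool = True
    free: tuple[str, ...] = ("Ki", "v0_scale")
    n_points: int = 0


def fit_ki(
    points: Sequence[RatePoint],
    Et: float,
    params_init: ModifierParams,
    free: Iterable[str] = ("Ki", "v0_scale"),
    weights: str = "none",
) -> FitResult:
    """Nonlinear least-squares fit of the tight-binding modifier velocity.

    All points must share one substrate concentration.  By default only Ki
    and v0_scale float while alpha and beta stay fixed (typically at the
    specific-velocity-plot estimates); pass ``free={"Ki","v0_scale","alpha",
    "beta"}`` to float them.  ``weights="inv_v"`` applies 1/v weighting.

    Bounds: Ki > 0, v0_scale > 0, alpha > 0, 0 <= beta <= 1.
    """
    points = list(points)
    if len(points) < 5:
        raise ValueError("need at least 5 rate points")
    S_vals = {p.S for p in points}
    if len(S_vals) != 1:
        raise ValueError(f"fit_ki expects a single substrate concentration, got {sorted(S_vals)}")
    S = S_vals.pop()
    free = set(free)
    unknown = free - {"Ki", "v0_scale", "alpha", "beta"}
    if unknown:
        raise ValueError(f"cannot float parameter(s) {sorted(unknown)}")
    It_max = max(p.It for p in points)
    if It_max < 5 * Et:
        warnings.warn(
            f"inhibitor range tops out at {It_max} nM < 5x Et={Et} nM; "
            "Ki may be poorly identified",
            stacklevel=2,
        )
    if min(p.It for p in points) > 10 * params_init.Ki:
        warnings.warn(
            "all inhibitor concentrations are far above the initial Ki; "
            "Ki is poorly identified by this design",
            stacklevel=2,
        )

    pars = Parameters()
    pars.add("Ki", value=params_init.Ki, min=1e-12, vary="Ki" in free)
    pars.add("v0_scale", value=params_init.v0_scale, min=1e-12, vary="v0_scale" in free)
    pars.add("alpha", value=params_init.alpha, min=1e-12, vary="alpha" in free)
    pars.add("beta", value=params_init.beta, min=0.0, max=1.0, vary="beta" in free)

    It_arr = np.array([p.It for p in points])
    v_arr = np.array([p.v for p in points])
    if weights == "inv_v":
        w = 1.0 / np.maximum(v_arr, 1e-12)
    elif weights == "none":
        w = np.ones_like(v_arr)
    else:
        raise ValueError(f"unknown weighting scheme {weights!r}")

    def resid(p):
        trial = ModifierParams(
            Km=params_init.Km,
            Ki=p["Ki"].value,
            alpha=p["alpha"].value,
            beta=p["beta"].value,
            v0_scale=p["v0_scale"].value,
        )
        model = np.array([velocity_with_depletion(S, It, Et, trial) for It in It_arr])
        return w * (model - v_arr)

    out = minimize(resid, pars, method="leastsq", xtol=1e-10, ftol=1e-10)
    if not out.success:
        raise RuntimeError(f"Ki fit failed to converge: {out.message}")
    fitted = ModifierParams(
        Km=params_init.Km,
        Ki=float(out.params["Ki"].value),
        alpha=float(out.params["alpha"].value),
        beta=float(out.params["beta"].value),
        v0_scale=float(out.params["v0_scale"].value),
        Et=Et,
    )
    stderr = {
        name: (float(out.params[name].stderr) if out.params[name].stderr is not None else math.nan)
        for name in ("Ki", "v0_scale", "alpha", "beta")
        if name in free
    }
    return FitResult(
        params=fitted,
        stderr=stderr,
        residuals=np.asarray(out.residual),
        converged=True,
        free=tuple(sorted(free)),
        n_points=len(points),
    )


# ---------------------------------------------------------------------------
# Derived constants
# ---------------------------------------------------------------------------

def noncompetitive_ki(alpha: float, ki: float) -> float:
    """Noncompetitive inhibition constant alpha*Ki (nM)."""
    if alpha <= 0 or ki <= 0:
        raise ValueError("alpha and Ki must be positive")
    return alpha * ki


@dataclass(frozen=True)
class SPRRates:
    """SPR association (1/(M*s)) and dissociation (1/s) rate constants."""

    ka: float
    kd: float

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.kd <= 0:
            raise ValueError("ka and kd must be positive")


def spr_kd(rates: SPRRates) -> float:
    """Equilibrium dissociation constant K_D = kd/ka, converted to nM."""
    return rates.kd / rates.ka * 1e9


# ---------------------------------------------------------------------------
# Rate-data I/O
# ---------------------------------------------------------------------------

def read_rate_table(path: str | Path) -> list[RatePoint]:
    """Read initial-rate data from TSV with header ``S_uM  I_nM  v``."""
    path = Path(path)
    points = []
    with path.open("r", encoding="utf-8") as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                for col in ("S_uM", "I_nM", "v"):
                    if col not in header:
                        raise ValueError(f"{path}: missing column {col!r}")
                idx = {c: header.index(c) for c in ("S_uM", "I_nM", "v")}
                continue
            try:
                points.append(
                    RatePoint(
                        S=float(fields[idx["S_uM"]]),
                        It=float(fields[idx["I_nM"]]),
                        v=float(fields[idx["v"]]),
                    )
                )
            except (ValueError, IndexError) as err:
                raise ValueError(f"{path}: line {lineno}: {err}") from None
    if header is None:
        raise ValueError(f"{path}: empty rate table")
    return points


def write_rate_table(points: Iterable[RatePoint], path: str | Path) -> int:
    path = Path(path)
    n = 0
    with path.open("w", encoding="utf-8") as fh:
        fh.write("S_uM\tI_nM\tv\n")
        for p in points:
            fh.write(f"{p.S:.10g}\t{p.It:.10g}\t{p.v:.10g}\n")
            n += 1
    return n
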