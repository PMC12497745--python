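"""Structural and statistical model: one-compartment oral kinetics with
allometric weight scaling, a multiplicative drug-interaction factor on
clearance, log-normal between-subject variability and proportional residual
error.

Model summary
-------------
Typical (population) parameters for a subject with weight ``W`` (kg) and
zopiclone flag ``z``::

    CL/F = cl_std * (W/70)**0.75 * (1 + theta_zop * z) * prod(extra factors)
    V/F  = v_std  * (W/70)**1    * prod(extra factors)

Individual clearance carries a log-normal random effect,
``CL_i = CL * exp(eta)`` with ``eta ~ N(0, omega_cl**2)``; volume and the
absorption rate constant carry no between-subject variability in the final
model.  Observations follow a proportional error model,
``Y = C * (1 + eps)`` with ``eps ~ N(0, sigma_prop**2)``.

Concentrations are handled internally in mg/L and exposed in ng/mL
(conversion factor exactly 1000).  All kinetic formulas accept complex
parameter values so that derivatives with respect to the random effect can
be taken by the complex-step method.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .data import CovariateVector, DoseEvent

REFERENCE_WEIGHT = 70.0
MGL_TO_NGML = 1000.0
#: relative ka/ke gap below which the flip-flop limiting form is used
_DEGENERACY_RTOL = 1e-8


class InvalidModelError(ValueError):
    """A parameter set or covariate effect yields a non-positive factor."""


@dataclass(frozen=True)
class PopulationParameters:
    """Fixed effects and variability of the population model.

    Defaults are the published final estimates for clozapine in adult
    schizophrenia patients (70 kg reference): CL/F 29.6 L/h, V/F 308 L,
    ka fixed at 1.3 /h, a -25.4% zopiclone effect on clearance,
    omega_CL 0.348 and proportional residual SD 0.257.
    """

    cl_std: float = 29.6
    v_std: float = 308.0
    ka: float = 1.3
    ka_fixed: bool = True
    theta_zop: float = -0.254
    allo_exp_cl: float = 0.75
    allo_exp_v: float = 1.0
    omega_cl: float = 0.348
    sigma_prop: float = 0.257

    def __post_init__(self) -> None:
        if self.cl_std <= 0 or self.v_std <= 0 or self.ka <= 0:
            raise InvalidModelError(
                f"cl_std, v_std, ka must be > 0 "
                f"(got {self.cl_std}, {self.v_std}, {self.ka})"
            )
        if self.omega_cl < 0:
            raise InvalidModelError(f"omega_cl must be >= 0, got {self.omega_cl}")
        if self.sigma_prop <= 0:
            raise InvalidModelError(f"sigma_prop must be > 0, got {self.sigma_prop}")
        if 1.0 + self.theta_zop <= 0:
            raise InvalidModelError(
                f"zopiclone clearance factor 1 + theta_zop = "
                f"{1.0 + self.theta_zop} is not positive"
            )

    def with_(self, **kw) -> "PopulationParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class CovariateEffect:
    """One multiplicative covariate effect on clearance or volume.

    ``kind="power"`` scales by ``(value / s_m) ** q`` (continuous covariate,
    ``s_m`` the population median); ``kind="linear"`` scales by
    ``1 + q * value`` (categorical / linear-fractional form).
    """

    target: str  # "cl" or "v"
    name: str
    kind: str  # "power" or "linear"
    q: float = 0.0
    s_m: float | None = None

    def __post_init__(self) -> None:
        if self.target not in ("cl", "v"):
            raise InvalidModelError(f"effect target must be 'cl' or 'v', got {self.target!r}")
        if self.kind not in ("power", "linear"):
            raise InvalidModelError(f"effect kind must be 'power' or 'linear', got {self.kind!r}")
        if self.kind == "power" and (self.s_m is None or self.s_m <= 0):
            raise InvalidModelError(
                f"power effect {self.name!r} requires a positive reference s_m"
            )

    @property
    def label(self) -> str:
        return f"{self.name}->{self.target}"

    def factor(self, cov: CovariateVector, q: float | None = None) -> float:
        qq = self.q if q is None else q
        v = cov.value_of(self.name)
        if self.kind == "power":
            return (v / self.s_m) ** qq
        return 1.0 + qq * v


@dataclass(frozen=True)
class TypicalParams:
    """Typical parameters after covariate adjustment (CL L/h, V L, ka /h)."""

    cl: float
    v: float
    ka: float

    def __post_init__(self) -> None:
        if not (self.cl > 0 and self.v > 0 and self.ka > 0):
            raise InvalidModelError(
                f"typical parameters must be positive (cl={self.cl}, v={self.v}, ka={self.ka})"
            )


@dataclass(frozen=True)
class IndividualParams:
    """Realized individual parameters; random effect only on clearance."""

    cl_i: float
    v_i: float
    ka_i: float
    eta_cl: float = 0.0


def typical_params(
    pop: PopulationParameters,
    cov: CovariateVector,
    effects: Sequence[CovariateEffect] = (),
) -> TypicalParams:
    """Typical CL/F and V/F for a subject: allometry, then the zopiclone
    factor on clearance, then any extra multiplicative effects."""
    rw = cov.weight / REFERENCE_WEIGHT
    cl = pop.cl_std * rw**pop.allo_exp_cl
    v = pop.v_std * rw**pop.allo_exp_v

    zop_factor = 1.0 + pop.theta_zop * cov.zop
    if zop_factor <= 0:
        raise InvalidModelError(
            f"zopiclone effect yields non-positive clearance factor {zop_factor}"
        )
    cl *= zop_factor

    for eff in effects:
        f = eff.factor(cov)
        if not np.isfinite(f) or f <= 0:
            raise InvalidModelError(
                f"covariate effect {eff.label} yields non-positive factor {f}"
            )
        if eff.target == "cl":
            cl *= f
        else:
            v *= f
    return TypicalParams(cl=cl, v=v, ka=pop.ka)


def individual_params(tv: TypicalParams, eta_cl: float) -> IndividualParams:
    """Realize individual parameters: ``CL_i = CL * exp(eta)``; V and ka
    carry no random effect."""
    return IndividualParams(cl_i=tv.cl * np.exp(eta_cl), v_i=tv.v, ka_i=tv.ka, eta_cl=eta_cl)


# ---------------------------------------------------------------------------
# concentration kernel
# ---------------------------------------------------------------------------

def _exp_sum(k, tad, tau, n):
    """sum_{j=0}^{n-1} exp(-k*(tad + j*tau)); n may be inf (steady state).

    Complex-safe in ``k``.  Shapes broadcast.
    """
    x = np.exp(-k * tau)
    inf = np.isinf(n)
    # x**n with n possibly inf: finite branch via exp(n*log x) is x**n
    with np.errstate(over="ignore", invalid="ignore"):
        xn = np.where(inf, 0.0, x ** np.where(inf, 1.0, n))
    return np.exp(-k * tad) * (1.0 - xn) / (1.0 - x)


def _exp_sum_t(k, tad, tau, n):
    """sum_{j=0}^{n-1} (tad + j*tau) * exp(-k*(tad + j*tau)); n may be inf.

    Arithmetico-geometric closed form; used only in the ka == ke limit.
    """
    x = np.exp(-k * tau)
    inf = np.isinf(n)
    with np.errstate(over="ignore", invalid="ignore"):
        nn = np.where(inf, 1.0, n)
        xn = np.where(inf, 0.0, x**nn)
        xnm1 = np.where(inf, 0.0, x ** (nn - 1.0))
        geo = (1.0 - xn) / (1.0 - x)
        # sum j*x^j over j=0..n-1
        jsum = np.where(
            inf,
            x / (1.0 - x) ** 2,
            x * (1.0 - nn * xnm1 + (nn - 1.0) * xn) / (1.0 - x) ** 2,
        )
    return np.exp(-k * tad) * (tad * geo + tau * jsum)


def profile_conc(amount, n_doses, tau, tad, cl, v, ka):
    """Concentration (mg/L) of ``n_doses`` doses of ``amount`` mg spaced
    ``tau`` h apart, evaluated ``tad`` h after the last administered dose.

    One-compartment first-order absorption and elimination, superposed via
    the exact geometric-series closed form; ``n_doses=inf`` gives the
    steady-state profile.  ``cl`` may be complex (complex-step derivatives).
    Near the ka == ke degeneracy the analytic flip-flop limit
    ``(D/V) * ka * t * exp(-ka t)`` (summed over doses) is used.
    """
    amount = np.asarray(amount, dtype=float)
    tad = np.asarray(tad, dtype=float)
    ke = np.asarray(cl) / np.asarray(v)
    ka = np.asarray(ka, dtype=float)

    degen = np.abs(ka - np.real(ke)) < _DEGENERACY_RTOL * ka
    # regular branch; where degenerate, shift ke to dodge the 0/0 (result
    # discarded by the final where)
    ke_safe = np.where(degen, ka * 0.5, ke)
    regular = (
        (amount / v)
        * ka
        / (ka - ke_safe)
        * (_exp_sum(ke_safe, tad, tau, n_doses) - _exp_sum(ka, tad, tau, n_doses))
    )
    if np.any(degen):
        limit = (amount / v) * ka * _exp_sum_t(ka, tad, tau, n_doses)
        regular = np.where(degen, limit, regular)
    return regular


def concentration(
    ind: IndividualParams,
    doses: Iterable[DoseEvent],
    t,
) -> np.ndarray | float:
    """Predicted concentration (ng/mL) at time(s) ``t`` for a dosing history.

    Doses with ``interval`` set contribute every ``interval`` hours from
    their start time; all administered doses up to ``t`` are superposed.
    Times before any dose give 0.
    """
    doses = list(doses)
    if not doses:
        raise InvalidModelError("dosing history is empty")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise InvalidModelError("prediction times must be >= 0")
    total = np.zeros_like(t_arr)
    for ev in doses:
        active = t_arr >= ev.time
        if not np.any(active):
            continue
        te = t_arr - ev.time
        if ev.interval is None:
            n = np.ones_like(te)
            tad = te
            tau = 1.0  # irrelevant for n=1
        else:
            n = np.floor(te / ev.interval) + 1.0
            tad = te - (n - 1.0) * ev.interval
            tau = ev.interval
        c = profile_conc(ev.amount, n, tau, tad, ind.cl_i, ind.v_i, ind.ka_i)
        total = total + np.where(active, np.real(c), 0.0)
    out = np.maximum(total, 0.0) * MGL_TO_NGML
    return out if np.ndim(t) else float(out[0])


def steady_state_trough(ind: IndividualParams, dose_mg: float, interval_h: float):
    """Steady-state trough concentration (ng/mL) of ``dose_mg`` every
    ``interval_h`` hours: the infinite-superposition closed form evaluated at
    the end of the dosing interval."""
    if interval_h <= 0:
        raise InvalidModelError(f"interval must be > 0, got {interval_h}")
    if dose_mg < 0:
        raise InvalidModelError(f"dose must be >= 0, got {dose_mg}")
    if dose_mg == 0:
        return 0.0
    c = profile_conc(dose_mg, np.inf, interval_h, interval_h, ind.cl_i, ind.v_i, ind.ka_i)
    return float(np.real(c)) * MGL_TO_NGML


def apply_residual(true_conc, eps):
    """Proportional residual model ``Y = C * (1 + eps)``; the observation
    noise SD scales with the prediction."""
    return np.asarray(true_conc) * (1.0 + np.asarray(eps))
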