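"""Independent oracles used by the test suite.

These deliberately avoid the vectorized likelihood/simulation code paths
they are used to check: quadrature instead of the Laplace approximation,
explicit single-dose superposition instead of the geometric-series closed
form, an ODE integrator instead of the analytic profile, and monotone
inversion instead of Monte Carlo for attainment probabilities.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, minimize_scalar
from scipy.special import roots_hermite
from scipy.stats import norm

import clozapk as cz


def ode_concentration(cl, v, ka, dose_mg, t):
    """Single oral dose concentration (ng/mL) by numerically integrating the
    two-state absorption/elimination ODE system."""
    ke = cl / v

    def rhs(_t, y):
        a_gut, a_central = y
        return [-ka * a_gut, ka * a_gut - ke * a_central]

    sol = solve_ivp(rhs, (0.0, t), [dose_mg, 0.0], rtol=1e-10, atol=1e-12)
    return sol.y[1, -1] / v * 1000.0


def superposition_trough(ind, dose_mg, interval_h, n_doses=50):
    """Steady-state trough by explicit superposition of single doses."""
    doses = [cz.DoseEvent(time=k * interval_h, amount=dose_mg) for k in range(n_doses)]
    return float(cz.concentration(ind, doses, n_doses * interval_h))


def subject_neg_log_joint(subject, pop, eta):
    """Negative log joint density of one subject's data and eta, computed
    through the public single-subject prediction path."""
    tv = cz.typical_params(pop, subject.cov)
    ind = cz.individual_params(tv, eta)
    times = np.array([o.time for o in subject.obs])
    y = np.array([o.conc for o in subject.obs])
    f = np.asarray(cz.concentration(ind, subject.doses, times))
    sd = pop.sigma_prop * f
    nll = 0.5 * np.sum(np.log(2 * np.pi * sd**2) + (y - f) ** 2 / sd**2)
    nlp = 0.5 * math.log(2 * math.pi * pop.omega_cl**2) + eta**2 / (2 * pop.omega_cl**2)
    return float(nll + nlp)


def agq_ofv(dataset, pop, n_nodes=32):
    """-2 log marginal likelihood by adaptive Gauss-Hermite quadrature."""
    nodes, wts = roots_hermite(n_nodes)
    total = 0.0
    for s in dataset.subjects:
        res = minimize_scalar(
            lambda e: subject_neg_log_joint(s, pop, e),
            bounds=(-6.0, 6.0),
            method="bounded",
            options={"xatol": 1e-11},
        )
        mode = res.x
        d = 1e-5
        h0 = subject_neg_log_joint(s, pop, mode)
        hess = (
            subject_neg_log_joint(s, pop, mode + d)
            - 2 * h0
            + subject_neg_log_joint(s, pop, mode - d)
        ) / d**2
        scale = math.sqrt(2.0 / hess)
        integrand = np.array(
            [
                math.exp(-(subject_neg_log_joint(s, pop, mode + scale * t) - h0) + t * t)
                for t in nodes
            ]
        )
        li = scale * float(np.sum(wts * integrand)) * math.exp(-h0)
        total += -2.0 * math.log(li)
    return total


def exact_attainment(pop, weight, zop, dose_per_kg, interval=12.0):
    """Exact PTA and toxicity-exceedance by monotone inversion.

    The steady-state trough is strictly decreasing in eta, so threshold
    crossings are roots in eta and the probabilities are normal CDF values.
    """
    cov = cz.CovariateVector(weight=weight, zop=zop)
    tv = cz.typical_params(pop, cov)
    dose = dose_per_kg * weight / (24.0 / interval)

    def trough(eta):
        return cz.steady_state_trough(cz.individual_params(tv, eta), dose, interval)

    def eta_at(conc):
        return brentq(lambda e: trough(e) - conc, -20.0, 20.0, xtol=1e-12)

    lo, hi = cz.THERAPEUTIC_WINDOW
    w = pop.omega_cl
    pta = norm.cdf(eta_at(lo) / w) - norm.cdf(eta_at(hi) / w)
    p_toxic = norm.cdf(eta_at(cz.TOXICITY_THRESHOLD) / w)
    return float(pta), float(p_toxic)


def fit_result_at(dataset, pop, effects=()):
    """A FitResult frozen at known population parameters (EBEs computed,
    no optimization) — for diagnostics on data simulated from that model."""
    comp = cz.CompiledData(dataset)
    tv = comp.typical(pop, effects)
    _, ebes, _, ok = comp.laplace(tv[0], tv[1], pop.ka, pop.omega_cl, pop.sigma_prop)
    assert np.all(ok)
    ofv = cz.objective(comp, pop, effects)
    return cz.FitResult(
        estimates=pop,
        effects=tuple(effects),
        ofv=ofv,
        se_pct=None,
        ebes=ebes,
        subject_ids=list(comp.ids),
        converged=True,
        n_function_evals=0,
        fixed=("ka",),
        param_names=("cl_std", "v_std", "theta_zop", "omega_cl", "sigma_prop"),
    )
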