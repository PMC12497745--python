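"""Model qualification: goodness-of-fit records, visual predictive check,
nonparametric bootstrap and individual profile curves.

Conditional weighted residuals (CWRES) follow the first-order-conditional
linearization: the subject's prediction is linearized in the random effect
around the empirical-Bayes estimate, the marginal covariance is
``G Omega G' + diag(sigma^2 f^2)`` with the residual variance at the
conditional prediction (interaction), and residuals are decorrelated by the
Cholesky factor.  On data truly generated by the model, CWRES are mean-0,
SD-1 to first order.

The bootstrap resamples subjects with replacement (the subject is the
independent unit), refits every replicate, and summarizes percentile
confidence intervals (2.5th/97.5th, linear a.k.a. type-7 interpolation) and
the relative bias of the bootstrap median,
``bias% = (median - estimate) / estimate * 100``.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular

from .data import Dataset
from .estimate import CompiledData, EstimationError, FitResult, fit as _fit
from .model import PopulationParameters


class DiagnosticError(RuntimeError):
    pass


def _conditional_predictions(comp: CompiledData, fitres: FitResult):
    """(pred, ipred, dfdeta) per observation for a fitted model."""
    tv = comp.typical(fitres.estimates, fitres.effects)
    if tv is None:
        raise DiagnosticError("fitted effects infeasible on this dataset")
    cl_typ, v_typ = tv
    ka = fitres.estimates.ka
    eta = fitres.ebes
    pred = np.real(comp.predict(cl_typ, v_typ, ka))
    # complex step on every subject's eta at once: each observation picks up
    # the derivative with respect to its own subject's random effect
    h = 1e-20
    fc = comp.predict(cl_typ * np.exp(eta + 1j * h), v_typ, ka)
    ipred = np.real(fc)
    dfdeta = np.imag(fc) / h
    return pred, ipred, dfdeta


def gof(dataset: Dataset | CompiledData, fitres: FitResult) -> pd.DataFrame:
    """Goodness-of-fit table: one row per observation with the population
    prediction (PRED, eta=0), individual prediction (IPRED, at the EBE) and
    conditional weighted residual (CWRES)."""
    if not fitres.converged:
        raise EstimationError("goodness of fit requires a converged fit")
    comp = dataset if isinstance(dataset, CompiledData) else CompiledData(dataset)
    pred, ipred, G = _conditional_predictions(comp, fitres)
    omega2 = fitres.estimates.omega_cl**2
    sigma2 = fitres.estimates.sigma_prop**2
    cwres = np.empty(comp.n_obs)
    for si in range(comp.n_subj):
        m = comp.obs_subj == si
        g = G[m]
        f = ipred[m]
        eta_i = fitres.ebes[si]
        V = omega2 * np.outer(g, g) + np.diag(sigma2 * f * f)
        resid = comp.y[m] - (f - g * eta_i)
        try:
            L = cholesky(V, lower=True)
        except np.linalg.LinAlgError as exc:
            raise DiagnosticError(
                f"singular residual covariance for subject {comp.ids[si]}"
            ) from exc
        cwres[m] = solve_triangular(L, resid, lower=True)
    return pd.DataFrame(
        {
            "id": [comp.ids[i] for i in comp.obs_subj],
            "time": comp.obs_times,
            "dv": comp.y,
            "pred": pred,
            "ipred": ipred,
            "cwres": cwres,
        }
    )


@dataclass
class VPCSummary:
    """Binned observed percentiles with simulation confidence bands."""

    table: pd.DataFrame
    n_sim: int
    percentiles: tuple[float, ...]
    flagged_bins: list[int] = field(default_factory=list)


def vpc(
    dataset: Dataset | CompiledData,
    fitres: FitResult,
    n_sim: int = 1000,
    seed: int = 0,
    n_bins: int = 6,
    percentiles: tuple[float, ...] = (5.0, 50.0, 95.0),
) -> VPCSummary:
    """Visual predictive check.

    Simulates ``n_sim`` replicate datasets under the fitted model with the
    original design (same covariates, doses and sampling times), then per
    time bin compares observed percentiles with the simulated 95% confidence
    interval of each percentile.  Bins with fewer than 5 observations are
    flagged, not dropped.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    comp = dataset if isinstance(dataset, CompiledData) else CompiledData(dataset)
    tv = comp.typical(fitres.estimates, fitres.effects)
    if tv is None:
        raise DiagnosticError("fitted effects infeasible on this dataset")
    cl_typ, v_typ = tv
    pop = fitres.estimates
    rng = np.random.default_rng(seed)

    times = comp.obs_times
    uniq = np.unique(times)
    if uniq.size <= n_bins:
        edges = np.concatenate([uniq, [uniq[-1] + 1e-9]])
    else:
        qs = np.linspace(0, 100, n_bins + 1)
        edges = np.percentile(times, qs)
        edges[-1] += 1e-9
        edges = np.unique(edges)
    bin_idx = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, len(edges) - 2)
    n_bins_eff = len(edges) - 1

    def binned_percentiles(values: np.ndarray) -> np.ndarray:
        out = np.full((n_bins_eff, len(percentiles)), np.nan)
        for b in range(n_bins_eff):
            m = bin_idx == b
            if np.any(m):
                out[b] = np.percentile(values[m], percentiles)
        return out

    obs_pct = binned_percentiles(comp.y)
    sims = np.empty((n_sim, n_bins_eff, len(percentiles)))
    for r in range(n_sim):
        eta = rng.normal(0.0, pop.omega_cl, comp.n_subj) if pop.omega_cl > 0 else np.zeros(comp.n_subj)
        f = np.real(comp.predict(cl_typ * np.exp(eta), v_typ, pop.ka))
        eps = rng.normal(0.0, pop.sigma_prop, comp.n_obs)
        y = np.maximum(f * (1.0 + eps), 0.0)
        sims[r] = binned_percentiles(y)

    ci_lo = np.nanpercentile(sims, 2.5, axis=0)
    ci_hi = np.nanpercentile(sims, 97.5, axis=0)
    sim_med = np.nanpercentile(sims, 50.0, axis=0)

    rows = []
    flagged = []
    for b in range(n_bins_eff):
        n_in = int(np.sum(bin_idx == b))
        if 0 < n_in < 5:
            flagged.append(b)
        row = {"bin": b, "t_lo": edges[b], "t_hi": edges[b + 1], "n_obs": n_in}
        for j, p in enumerate(percentiles):
            row[f"obs_p{p:g}"] = obs_pct[b, j]
            row[f"sim_lo_p{p:g}"] = ci_lo[b, j]
            row[f"sim_med_p{p:g}"] = sim_med[b, j]
            row[f"sim_hi_p{p:g}"] = ci_hi[b, j]
        rows.append(row)
    return VPCSummary(pd.DataFrame(rows), n_sim=n_sim, percentiles=percentiles, flagged_bins=flagged)


def bias_pct(estimate: float, median: float) -> float:
    """Relative bias of a bootstrap median: (median - estimate)/estimate * 100."""
    return (median - estimate) / estimate * 100.0


@dataclass
class BootstrapSummary:
    """Per-parameter bootstrap summary (point estimate, median, percentile
    CI, SE% and bias%) plus replicate bookkeeping."""

    table: pd.DataFrame
    n_rep: int
    n_failed: int
    estimates: pd.DataFrame  # raw replicate estimates (converged only)

    @property
    def failure_fraction(self) -> float:
        return self.n_failed / self.n_rep


def bootstrap(
    dataset: Dataset | CompiledData,
    init: PopulationParameters | None = None,
    n_rep: int = 1000,
    seed: int = 0,
    fixed: tuple[str, ...] = ("ka",),
    effects: tuple = (),
    original: FitResult | None = None,
) -> BootstrapSummary:
    """Nonparametric bootstrap of the population fit.

    Resamples subjects with replacement (same n), refits each replicate
    starting from the original estimates, and summarizes percentile CIs,
    SE% and median bias per parameter.  Non-converged replicates are
    excluded from the summaries and counted; more than 10% failures raises a
    warning in the report.
    """
    if n_rep < 200:
        raise ValueError(f"n_rep must be >= 200 for stable percentile CIs, got {n_rep}")
    comp = dataset if isinstance(dataset, CompiledData) else CompiledData(dataset)
    if original is None:
        original = _fit(comp, init=init, fixed=fixed, effects=effects, compute_se=False)
    if not original.converged:
        raise EstimationError("bootstrap requires a converged original fit")

    rng = np.random.default_rng(seed)
    names = original.param_names
    rows = []
    n_failed = 0
    n = comp.n_subj
    for _ in range(n_rep):
        idx = rng.integers(0, n, size=n)
        weights = np.bincount(idx, minlength=n).astype(float)
        try:
            rep = _fit(
                comp,
                init=original.estimates,
                fixed=original.fixed,
                effects=original.effects,
                compute_se=False,
                subject_weights=weights,
                # warm-started replicate refits: percentile summaries do not
                # need the original fit's tight optimizer tolerances
                optimizer_options={"ftol": 1e-8, "gtol": 1e-2, "maxfun": 400},
            )
        except EstimationError:
            rep = None
        if rep is None or not rep.converged:
            n_failed += 1
            continue
        rows.append({nm: rep.estimate_of(nm) for nm in names})
    if not rows:
        raise EstimationError("all bootstrap replicates failed to converge")
    reps = pd.DataFrame(rows)
    if n_failed > 0.10 * n_rep:
        warnings.warn(
            f"bootstrap: {n_failed}/{n_rep} replicates failed to converge",
            RuntimeWarning,
            stacklevel=2,
        )

    out = []
    for nm in names:
        est = original.estimate_of(nm)
        vals = reps[nm].to_numpy()
        med = float(np.percentile(vals, 50.0))
        lo = float(np.percentile(vals, 2.5))
        hi = float(np.percentile(vals, 97.5))
        out.append(
            {
                "parameter": nm,
                "estimate": est,
                "median": med,
                "ci_lo": lo,
                "ci_hi": hi,
                "se_pct": 100.0 * float(np.std(vals, ddof=1)) / abs(est) if est != 0 else math.inf,
                "bias_pct": bias_pct(est, med),
            }
        )
    return BootstrapSummary(pd.DataFrame(out), n_rep=n_rep, n_failed=n_failed, estimates=reps)


def individual_profiles(
    dataset: Dataset | CompiledData,
    fitres: FitResult,
    n_points: int = 100,
) -> pd.DataFrame:
    """Dense per-subject prediction curves (PRED and IPRED) for plotting.

    The time grid for each subject runs from the first dose to the last
    observation time plus one dosing interval.
    """
    if not fitres.converged:
        raise EstimationError("individual profiles require a converged fit")
    ds = dataset if isinstance(dataset, Dataset) else None
    if ds is None:
        raise DiagnosticError("individual_profiles needs the full Dataset")
    from .model import concentration, individual_params, typical_params

    frames = []
    for si, s in enumerate(ds.subjects):
        tv = typical_params(fitres.estimates, s.cov, fitres.effects)
        ind0 = individual_params(tv, 0.0)
        ind_i = individual_params(tv, float(fitres.ebes[si]))
        t_last = max(o.time for o in s.obs)
        intervals = [ev.interval for ev in s.doses if ev.interval is not None]
        pad = intervals[0] if intervals else 0.0
        # observation times are part of the grid so curves can be compared
        # with the data without interpolating across dose-time kinks
        grid = np.union1d(
            np.linspace(0.0, t_last + pad, n_points), [o.time for o in s.obs]
        )
        frames.append(
            pd.DataFrame(
                {
                    "id": s.id,
                    "time": grid,
                    "pred": np.asarray(concentration(ind0, s.doses, grid)),
                    "ipred": np.asarray(concentration(ind_i, s.doses, grid)),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
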