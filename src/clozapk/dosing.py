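"""Monte Carlo dose individualization.

For each (weight, mg/kg/day dose, zopiclone status) scenario, steady-state
trough concentrations are simulated over the population distribution of the
clearance random effect and summarized as the probability of target
attainment (PTA, trough inside the 350-800 ng/mL therapeutic window) and
the probability of exceeding the 1000 ng/mL toxicity threshold.  Daily
doses are split evenly over a q12h regimen by default.  Simulated troughs
are residual-free by default: the questions concern true steady-state
exposure, not assay noise (residual error can be switched on).

``recommend`` turns a PTA grid into a weight-banded dose table: per weight
the dose maximizing PTA (ties to the lower dose, optionally subject to a
toxicity cap) and contiguous weights sharing a dose merged into bands.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import PopulationParameters, typical_params
from .data import CovariateVector

THERAPEUTIC_WINDOW = (350.0, 800.0)
TOXICITY_THRESHOLD = 1000.0

#: simulated weight groups (kg) and daily dose grid (mg/kg/day)
DEFAULT_WEIGHTS = (40.0, 60.0, 80.0, 100.0, 120.0)
DEFAULT_DOSES = tuple(float(d) for d in range(1, 11))


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class Scenario:
    """One simulated dosing scenario."""

    weight: float
    dose_per_kg: float
    interval: float = 12.0
    zop: int = 0
    n_sim: int = 1000
    seed: int = 0
    add_residual: bool = False

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ScenarioError("weight must be > 0")
        if self.dose_per_kg < 0:
            raise ScenarioError("dose_per_kg must be >= 0")
        if self.interval <= 0 or 24.0 % self.interval != 0:
            raise ScenarioError("interval must divide 24 h")
        if self.zop not in (0, 1):
            raise ScenarioError("zop must be 0 or 1")
        if self.n_sim < 1:
            raise ScenarioError("n_sim must be >= 1")

    @property
    def dose_mg(self) -> float:
        """Per-administration dose: daily mg/kg dose split over the day."""
        return self.dose_per_kg * self.weight / (24.0 / self.interval)


@dataclass
class ScenarioResult:
    """Simulated steady-state troughs with attainment fractions."""

    scenario: Scenario
    troughs: np.ndarray
    pta: float
    p_toxic: float
    p_sub: float  # fraction below the window
    p_supra: float  # fraction above the window (incl. toxic)

    @property
    def p_toxic_pct(self) -> float:
        return round(100.0 * self.p_toxic, 1)


def trough_samples(
    pop: PopulationParameters,
    sc: Scenario,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n_sim`` steady-state troughs (ng/mL) for the scenario."""
    rng = np.random.default_rng(sc.seed) if rng is None else rng
    cov = CovariateVector(weight=sc.weight, zop=sc.zop)
    tv = typical_params(pop, cov)
    eta = rng.normal(0.0, pop.omega_cl, sc.n_sim) if pop.omega_cl > 0 else np.zeros(sc.n_sim)
    if sc.dose_mg == 0:
        return np.zeros(sc.n_sim)
    # vectorized closed form: trough is monotone decreasing in eta
    cl_i = tv.cl * np.exp(eta)
    from .model import profile_conc, MGL_TO_NGML

    troughs = (
        np.real(profile_conc(sc.dose_mg, np.inf, sc.interval, sc.interval, cl_i, tv.v, tv.ka))
        * MGL_TO_NGML
    )
    if sc.add_residual:
        eps = rng.normal(0.0, pop.sigma_prop, sc.n_sim)
        troughs = np.maximum(troughs * (1.0 + eps), 0.0)
    return troughs


def simulate_scenario(pop: PopulationParameters, sc: Scenario) -> ScenarioResult:
    """Monte Carlo PTA and toxicity-exceedance for one scenario."""
    t = trough_samples(pop, sc)
    lo, hi = THERAPEUTIC_WINDOW
    return ScenarioResult(
        scenario=sc,
        troughs=t,
        pta=float(np.mean((t >= lo) & (t <= hi))),
        p_toxic=float(np.mean(t > TOXICITY_THRESHOLD)),
        p_sub=float(np.mean(t < lo)),
        p_supra=float(np.mean(t > hi)),
    )


def pta_grid(
    pop: PopulationParameters,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
    doses: Sequence[float] = DEFAULT_DOSES,
    zop: int = 0,
    n_sim: int = 1000,
    seed: int = 0,
    interval: float = 12.0,
    add_residual: bool = False,
) -> pd.DataFrame:
    """Scenario results over a weight x dose grid.

    Sub-seeds are derived deterministically from the master seed per
    (weight, dose) cell and do not depend on the zopiclone flag, so matched
    cells of the two co-medication groups share their random-effect draws.
    """
    if not weights or not doses:
        raise ScenarioError("weight and dose grids must be non-empty")
    rows = []
    for i, w in enumerate(weights):
        for j, d in enumerate(doses):
            sub = int(np.random.SeedSequence([int(seed), i, j]).generate_state(1)[0] % (2**31))
            sc = Scenario(
                weight=float(w), dose_per_kg=float(d), interval=interval, zop=zop,
                n_sim=n_sim, seed=sub, add_residual=add_residual,
            )
            r = simulate_scenario(pop, sc)
            rows.append(
                {
                    "weight": float(w),
                    "dose_per_kg": float(d),
                    "zop": zop,
                    "pta": r.pta,
                    "p_toxic": r.p_toxic,
                    "p_sub": r.p_sub,
                    "p_supra": r.p_supra,
                    "median_trough": float(np.median(r.troughs)),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class RecommendationTable:
    """Weight-banded dose recommendations with safety bounds.

    One row per (zopiclone group, weight band): the recommended mg/kg/day
    dose and the largest toxicity-exceedance percentage across the band's
    simulated weights.  Within each group, bands are disjoint, cover the
    weight range, and doses are non-increasing in weight.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for z, grp in self.table.groupby("zop"):
            g = grp.sort_values("band_lo")
            doses = g["dose_per_kg"].to_numpy()
            if np.any(np.diff(doses) > 0):
                raise ScenarioError(
                    f"recommended doses must be non-increasing in weight (zop={z})"
                )
            lows, highs = g["band_lo"].to_numpy(), g["band_hi"].to_numpy()
            if np.any(lows[1:] != highs[:-1]):
                raise ScenarioError(f"weight bands must tile the range (zop={z})")


def _select_dose(sub: pd.DataFrame, toxicity_cap: float | None) -> float:
    """Dose maximizing PTA (ties to the lower dose), under an optional
    toxicity-probability cap."""
    cand = sub
    if toxicity_cap is not None:
        capped = sub[sub["p_toxic"] <= toxicity_cap]
        if len(capped):
            cand = capped
    cand = cand.sort_values(["pta", "dose_per_kg"], ascending=[False, True])
    best_pta = cand.iloc[0]["pta"]
    ties = cand[cand["pta"] == best_pta]
    return float(ties["dose_per_kg"].min())


def recommend(
    grid_no_zop: pd.DataFrame,
    grid_zop: pd.DataFrame,
    band_edges: dict[int, Sequence[float]] | None = None,
    toxicity_cap: float | None = None,
) -> RecommendationTable:
    """Build the weight-banded recommendation table from two PTA grids.

    Discovery mode (``band_edges=None``): per simulated weight pick the
    PTA-maximizing dose and merge contiguous weights sharing a dose into
    bands.  Reproduction mode: with fixed ``band_edges`` per group (keyed by
    zop flag), each band gets the dose maximizing the band's worst-weight
    PTA.  Either way the reported safety figure is the band's maximum
    toxicity-exceedance probability (percent, 1 decimal).
    """
    rows = []
    for z, grid in ((0, grid_no_zop), (1, grid_zop)):
        if grid is None or not len(grid):
            raise ScenarioError("empty PTA grid")
        weights = sorted(grid["weight"].unique())
        if band_edges is not None:
            edges = list(band_edges[z])
            for lo, hi in zip(edges[:-1], edges[1:]):
                inband = [w for w in weights if lo <= w < hi] or [
                    min(weights, key=lambda w: abs(w - 0.5 * (lo + hi)))
                ]
                sub = grid[grid["weight"].isin(inband)]
                worst = sub.groupby("dose_per_kg")["pta"].min().reset_index()
                worst = worst.merge(
                    sub.groupby("dose_per_kg")["p_toxic"].max().reset_index(),
                    on="dose_per_kg",
                )
                worst = worst.rename(columns={"pta": "pta", "p_toxic": "p_toxic"})
                dose = _select_dose(worst, toxicity_cap)
                ptox = float(sub[sub["dose_per_kg"] == dose]["p_toxic"].max())
                rows.append(
                    {"zop": z, "band_lo": lo, "band_hi": hi,
                     "dose_per_kg": dose, "max_p_toxic_pct": round(100.0 * ptox, 1)}
                )
        else:
            picks = []
            for w in weights:
                sub = grid[grid["weight"] == w]
                dose = _select_dose(sub, toxicity_cap)
                ptox = float(sub[sub["dose_per_kg"] == dose]["p_toxic"].iloc[0])
                picks.append((w, dose, ptox))
            # merge contiguous weights with the same selected dose
            start = 0
            for k in range(1, len(picks) + 1):
                if k == len(picks) or picks[k][1] != picks[start][1]:
                    band_w = picks[start:k]
                    lo = band_w[0][0]
                    hi = picks[k][0] if k < len(picks) else band_w[-1][0]
                    rows.append(
                        {
                            "zop": z,
                            "band_lo": lo,
                            "band_hi": hi,
                            "dose_per_kg": band_w[0][1],
                            "max_p_toxic_pct": round(100.0 * max(p for _, _, p in band_w), 1),
                        }
                    )
                    start = k
    return RecommendationTable(pd.DataFrame(rows))
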