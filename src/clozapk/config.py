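"""Run configuration: a single YAML file, schema-validated (unknown keys
rejected).  Defaults are the published final model and the study's
simulation settings (therapeutic window 350-800 ng/mL, toxicity threshold
1000 ng/mL, 1000 replicates)."""
from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelBlock(_Strict):
    cl_std: float = 29.6
    v_std: float = 308.0
    ka: float = 1.3
    ka_fixed: bool = True
    theta_zop: float = -0.254
    allo_exp_cl: float = 0.75
    allo_exp_v: float = 1.0
    omega_cl: float = 0.348
    sigma_prop: float = 0.257


class EstimationBlock(_Strict):
    fixed: list[str] = Field(default_factory=lambda: ["ka"])
    init_cl_std: float = 20.0
    init_v_std: float = 200.0
    init_theta_zop: float = 0.0
    init_omega_cl: float = 0.3
    init_sigma_prop: float = 0.2
    compute_se: bool = True


class CovariateCandidate(_Strict):
    target: Literal["cl", "v"]
    name: str
    kind: Literal["power", "linear"]
    s_m: float | None = None


class DesignBlock(_Strict):
    n_subjects: int = 81
    weight_mean: float = 70.49
    weight_sd: float = 13.53
    weight_bounds: tuple[float, float] = (38.0, 120.0)
    p_zop: float = 8.0 / 81.0
    dose_per_kg: float = 8.0
    interval: float = 12.0
    n_trough_obs: int = 2
    enriched: bool = False


class EvaluationBlock(_Strict):
    bootstrap_reps: int = 1000
    vpc_reps: int = 1000
    vpc_bins: int = 6


class ScenarioBlock(_Strict):
    weights: list[float] = Field(default_factory=lambda: [40.0, 60.0, 80.0, 100.0, 120.0])
    doses: list[float] = Field(default_factory=lambda: [float(d) for d in range(1, 11)])
    interval: float = 12.0
    n_sim: int = 1000
    band_edges_no_zop: list[float] | None = Field(
        default_factory=lambda: [40.0, 50.0, 67.0, 88.0, 120.0]
    )
    band_edges_zop: list[float] | None = Field(default_factory=lambda: [40.0, 70.0, 120.0])


class RunConfig(_Strict):
    seed: int = 0
    outdir: str = "results"
    dataset: str | None = None
    model: ModelBlock = Field(default_factory=ModelBlock)
    estimation: EstimationBlock = Field(default_factory=EstimationBlock)
    covariate_candidates: list[CovariateCandidate] = Field(
        default_factory=lambda: [CovariateCandidate(target="cl", name="zop", kind="linear")]
    )
    design: DesignBlock = Field(default_factory=DesignBlock)
    evaluation: EvaluationBlock = Field(default_factory=EvaluationBlock)
    scenario: ScenarioBlock = Field(default_factory=ScenarioBlock)


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)
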