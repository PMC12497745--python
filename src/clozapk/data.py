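"""Core data containers for dosing histories, observations and cohorts.

The containers follow the event-record convention of pharmacometrics: a
subject is a dosing history plus a list of timed concentration observations,
with covariates held separately from the events.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence


class ValidationError(ValueError):
    """An object violates one of its structural invariants."""


@dataclass(frozen=True)
class DoseEvent:
    """A single oral dose, or a repeating regimen when ``interval`` is set.

    Parameters
    ----------
    time:
        Hours since the first dose of the record (>= 0).
    amount:
        Dose amount in mg (>= 0).
    interval:
        Dosing interval in hours.  When present the event denotes a regimen
        repeating indefinitely from ``time`` at that interval (the usual
        steady-state maintenance schedule); when ``None`` it is one dose.
    """

    time: float
    amount: float
    interval: float | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError(f"dose time must be >= 0, got {self.time}")
        if self.amount < 0:
            raise ValidationError(f"dose amount must be >= 0, got {self.amount}")
        if self.interval is not None and self.interval <= 0:
            raise ValidationError(f"dosing interval must be > 0, got {self.interval}")


@dataclass(frozen=True)
class Observation:
    """One observed plasma concentration (ng/mL) at ``time`` hours."""

    time: float
    conc: float
    is_trough: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError(f"observation time must be >= 0, got {self.time}")
        if self.conc < 0:
            raise ValidationError(f"concentration must be >= 0, got {self.conc}")


@dataclass(frozen=True)
class CovariateVector:
    """Subject-level covariates entering the structural model.

    ``weight`` (kg) drives the allometric scaling of clearance and volume;
    ``zop`` flags zopiclone co-administration (the drug-drug interaction
    covariate on clearance); ``extras`` carries any additional candidate
    covariates for covariate screening, keyed by name.
    """

    weight: float
    zop: int = 0
    extras: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValidationError(f"weight must be > 0, got {self.weight}")
        if self.zop not in (0, 1):
            raise ValidationError(f"zop flag must be 0 or 1, got {self.zop}")

    def value_of(self, name: str) -> float:
        if name == "weight":
            return self.weight
        if name == "zop":
            return float(self.zop)
        try:
            return float(self.extras[name])
        except KeyError:
            raise KeyError(f"unknown covariate {name!r}") from None


@dataclass
class SubjectRecord:
    """A subject's covariates, dosing history and observations."""

    id: str
    cov: CovariateVector
    doses: list[DoseEvent]
    obs: list[Observation]

    def __post_init__(self) -> None:
        times = [o.time for o in self.obs]
        if times != sorted(times):
            raise ValidationError(f"subject {self.id}: observation times not sorted")


@dataclass
class Dataset:
    """A cohort of subjects plus provenance metadata.

    ``meta`` records how the data came to be (generator seed and settings for
    simulated cohorts, source path for imported ones).
    """

    subjects: list[SubjectRecord]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValidationError("dataset must contain at least one subject")
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValidationError("subject ids must be unique")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_obs(self) -> int:
        return sum(len(s.obs) for s in self.subjects)

    def require_observations(self) -> None:
        missing = [s.id for s in self.subjects if not s.obs]
        if missing:
            raise ValidationError(
                f"subjects without observations cannot be used for estimation: {missing}"
            )


def subset(dataset: Dataset, indices: Sequence[int]) -> Dataset:
    """Build a resampled dataset from subject ``indices`` (with repeats).

    Repeated subjects are re-identified (``<id>#k``) so the result is a valid
    dataset; used by the nonparametric bootstrap.
    """
    counts: dict[int, int] = {}
    subjects = []
    for i in indices:
        k = counts.get(i, 0)
        counts[i] = k + 1
        s = dataset.subjects[i]
        new_id = s.id if k == 0 else f"{s.id}#{k}"
        subjects.append(SubjectRecord(new_id, s.cov, list(s.doses), list(s.obs)))
    return Dataset(subjects, meta={"resampled_from": dataset.meta.get("seed")})
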