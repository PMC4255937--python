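"""Scenario specification: one (disease, drug, endpoint) situation.

A scenario bundles the covariate-distribution sub-model (population), the
IO sub-model (drug-disease dynamics), the execution sub-model (protocol
deviations), the tested dose, and the endpoint definition.  The experiment
grid crosses N scenarios with P experimental designs.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

from .drug_disease import DrugModelSpec
from .exceptions import ConfigurationError
from .execution import DeviationSpec
from .population import PopulationSpec

__all__ = ["ScenarioSpec"]

_ENDPOINT_KINDS = ("change_from_baseline", "final_value", "responder")


@dataclass(frozen=True)
class ScenarioSpec:
    """One drug-disease-endpoint situation.

    ``dose`` is the per-period dose the active arm receives.  ``deviations``,
    when given, overrides the population's default deviation parameters so a
    scenario fully determines trial conduct.  ``drug_b`` configures the second
    treatment of a 2x2 factorial design; when absent, factorial trials use a
    zero-effect copy of the primary drug.
    """

    name: str
    population: PopulationSpec
    drug: DrugModelSpec
    dose: float
    deviations: DeviationSpec | None = None
    drug_b: DrugModelSpec | None = None
    dose_b: float | None = None
    endpoint_kind: str = "change_from_baseline"
    endpoint_threshold: float | None = None
    period_length: float = 1.0

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ConfigurationError(f"dose must be > 0, got {self.dose}")
        if self.endpoint_kind not in _ENDPOINT_KINDS:
            raise ConfigurationError(
                f"endpoint_kind must be one of {_ENDPOINT_KINDS}, got {self.endpoint_kind!r}"
            )
        if self.endpoint_kind == "responder" and self.endpoint_threshold is None:
            raise ConfigurationError("endpoint_kind 'responder' requires endpoint_threshold")
        if self.period_length <= 0:
            raise ConfigurationError(f"period_length must be > 0, got {self.period_length}")
        if self.deviations is not None:
            object.__setattr__(
                self, "population", replace(self.population, deviation_defaults=self.deviations)
            )

    @property
    def effective_drug_b(self) -> DrugModelSpec:
        if self.drug_b is not None:
            return self.drug_b
        return replace(self.drug, emax=0.0)

    @property
    def effective_dose_b(self) -> float:
        return self.dose_b if self.dose_b is not None else self.dose
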