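"""Covariate-distribution sub-model: virtual patient populations.

A virtual population is a set of independent draws from the joint covariate
distribution of a disease population: age, baseline biomarker level (E0,
log-normal so it stays positive), per-period disease-progression rate,
individual drug-sensitivity multiplier (log-normal around 1), a continuous
prognostic biomarker score that shifts progression, and a binary predictive
biomarker that multiplies the maximal drug effect.  Trial cohorts are drawn
from the population uniformly without replacement, optionally restricted by
inclusion/exclusion criteria or enriched on the predictive marker.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import rng_from
from .exceptions import ConfigurationError, RecruitmentError
from .execution import DeviationSpec

__all__ = [
    "PopulationSpec",
    "VirtualPatient",
    "CohortCriteria",
    "generate_population",
    "sample_cohort",
    "population_to_frame",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Joint covariate distribution of a virtual disease population.

    Parameters
    ----------
    n_population : number of virtual patients to generate.
    age_dist : (mean, sd) of age in years (normal, truncated at 0).
    baseline_dist : (log-mean, log-sd) of the baseline biomarker E0
        (log-normal, biomarker units).
    progression_dist : (mean, sd) of the per-period progression rate k_prog
        (normal, biomarker units / period).
    sensitivity_dist : (log-mean, log-sd) of the drug-sensitivity multiplier
        s_i (log-normal, dimensionless).
    prognostic_coeff : additive shift of k_prog per unit of the standard-normal
        prognostic score (biomarker units / period).
    predictive_prevalence : probability of predictive-marker-positive status.
    predictive_effect_ratio : Emax multiplier in marker-positive patients.
    deviation_defaults : protocol-deviation probabilities assigned to every
        generated patient.
    """

    n_population: int
    age_dist: tuple = (30.0, 10.0)
    baseline_dist: tuple = (3.0, 0.3)
    progression_dist: tuple = (0.0, 0.0)
    sensitivity_dist: tuple = (0.0, 0.0)
    prognostic_coeff: float = 0.0
    predictive_prevalence: float = 0.0
    predictive_effect_ratio: float = 1.0
    deviation_defaults: DeviationSpec = field(default_factory=DeviationSpec)

    def __post_init__(self) -> None:
        if self.n_population < 0:
            raise ConfigurationError(f"n_population must be >= 0, got {self.n_population}")
        for name in ("age_dist", "baseline_dist", "progression_dist", "sensitivity_dist"):
            pair = getattr(self, name)
            if len(pair) != 2:
                raise ConfigurationError(f"{name} must be a (location, scale) pair, got {pair!r}")
            if pair[1] < 0:
                raise ConfigurationError(f"{name} scale must be >= 0, got {pair[1]}")
        if not (0.0 <= self.predictive_prevalence <= 1.0):
            raise ConfigurationError(
                f"predictive_prevalence must lie in [0, 1], got {self.predictive_prevalence}"
            )
        if self.predictive_effect_ratio < 0:
            raise ConfigurationError(
                f"predictive_effect_ratio must be >= 0, got {self.predictive_effect_ratio}"
            )


@dataclass(frozen=True)
class VirtualPatient:
    """One simulated subject with individual model parameters.

    ``k_prog`` is the raw progression-rate draw; ``k_prog_adj`` additionally
    carries the prognostic-marker shift
    (k_prog + prognostic_coeff * prognostic_value) and is what the
    drug-disease model uses.
    """

    patient_id: str
    age: float
    e0: float
    k_prog: float
    s_i: float
    prognostic_value: float
    predictive_positive: bool
    k_prog_adj: float = 0.0
    deviation_params: DeviationSpec = field(default_factory=DeviationSpec)


@dataclass(frozen=True)
class CohortCriteria:
    """Inclusion/exclusion rules for cohort sampling."""

    min_age: float | None = None
    max_age: float | None = None
    baseline_min: float | None = None
    baseline_max: float | None = None
    require_predictive_positive: bool = False

    def __post_init__(self) -> None:
        if self.min_age is not None and self.max_age is not None and self.min_age > self.max_age:
            raise ConfigurationError(
                f"min_age ({self.min_age}) must not exceed max_age ({self.max_age})"
            )

    def eligible(self, patient: VirtualPatient) -> bool:
        if self.min_age is not None and patient.age < self.min_age:
            return False
        if self.max_age is not None and patient.age > self.max_age:
            return False
        if self.baseline_min is not None and patient.e0 < self.baseline_min:
            return False
        if self.baseline_max is not None and patient.e0 > self.baseline_max:
            return False
        if self.require_predictive_positive and not patient.predictive_positive:
            return False
        return True


def generate_population(spec: PopulationSpec, seed) -> list[VirtualPatient]:
    """Draw ``spec.n_population`` independent virtual patients.

    Identical (spec, seed) pairs reproduce an identical population.
    """
    rng = rng_from(seed)
    n = spec.n_population
    ages = np.maximum(rng.normal(spec.age_dist[0], spec.age_dist[1], n), 0.0)
    e0 = rng.lognormal(spec.baseline_dist[0], spec.baseline_dist[1], n)
    k_prog = rng.normal(spec.progression_dist[0], spec.progression_dist[1], n)
    s_i = rng.lognormal(spec.sensitivity_dist[0], spec.sensitivity_dist[1], n)
    prognostic = rng.standard_normal(n)
    predictive = rng.random(n) < spec.predictive_prevalence
    dev = spec.deviation_defaults
    width = max(6, len(str(max(n, 1))))
    return [
        VirtualPatient(
            patient_id=f"P{i:0{width}d}",
            age=float(ages[i]),
            e0=float(e0[i]),
            k_prog=float(k_prog[i]),
            s_i=float(s_i[i]),
            prognostic_value=float(prognostic[i]),
            predictive_positive=bool(predictive[i]),
            k_prog_adj=float(k_prog[i] + spec.prognostic_coeff * prognostic[i]),
            deviation_params=dev,
        )
        for i in range(n)
    ]


def sample_cohort(population, n: int, criteria: CohortCriteria | None = None, seed=None):
    """Draw ``n`` distinct eligible patients uniformly without replacement."""
    criteria = criteria or CohortCriteria()
    eligible = [p for p in population if criteria.eligible(p)]
    if len(eligible) < n:
        raise RecruitmentError(
            f"cohort of {n} requested but only {len(eligible)} eligible patients "
            f"in a population of {len(population)}",
            n_eligible=len(eligible),
            n_required=n,
        )
    rng = rng_from(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in idx]


def population_to_frame(population) -> pd.DataFrame:
    """Flat one-row-per-patient table (CSV-exportable)."""
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in population],
            "age": [p.age for p in population],
            "e0": [p.e0 for p in population],
            "k_prog": [p.k_prog for p in population],
            "s_i": [p.s_i for p in population],
            "prognostic_value": [p.prognostic_value for p in population],
            "predictive_positive": [p.predictive_positive for p in population],
        }
    )
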