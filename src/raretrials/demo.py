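"""Packaged demo scenario: a Dornase-alfa-like mucolytic in cystic fibrosis.

The demo emulates a phase-III question for a rare disease: does an inhaled
mucolytic improve mucociliary clearance (the biomarker, in % cleared) in
cystic fibrosis patients?  Seven small-sample designs are compared on a
common virtual population, 50 patients per trial except the N-of-1 series
(8 patients x 3 cycles):

parallel, crossover, N-of-1 series, randomized withdrawal, early escape,
triangular sequential, and randomized play-the-winner.

Parameter choices (documented in the methods note): baseline clearance is
log-normal around ~20%, disease progression is a slow decline of about
-0.1 %/period with patient heterogeneity, the drug adds up to ~8 % clearance
at high dose (EC50 = 1 dose unit, tested dose 2.5), onset is fast
(k_on = 0.6/period) and washout complete in one period; residual visit-to-
visit noise is 4 %.  Mild protocol deviations (5% missed visits, 2%/period
dropout, 1%/period switching, occasional half-dosing) are on by default.
"""
from __future__ import annotations

import math

from .config import dump_config
from .designs import DesignSpec
from .drug_disease import DrugModelSpec
from .engine import ExperimentPlan
from .execution import DeviationSpec
from .population import PopulationSpec
from .scenario import ScenarioSpec

__all__ = ["demo_scenario", "demo_designs", "demo_plan", "make_demo_scenario"]


def demo_scenario(
    emax: float = 8.0,
    residual_sd: float = 4.0,
    progression_mean: float = -0.1,
    deviations: DeviationSpec | None = None,
) -> ScenarioSpec:
    """The Dornase-like mucociliary-clearance scenario."""
    if deviations is None:
        deviations = DeviationSpec(
            missed_visit_prob=0.05,
            dropout_hazard=0.02,
            switch_prob=0.01,
            noncompliance_prob=0.05,
            noncompliance_fraction=0.5,
        )
    population = PopulationSpec(
        n_population=1000,
        age_dist=(18.0, 8.0),
        baseline_dist=(math.log(20.0), 0.3),
        progression_dist=(progression_mean, 0.3),
        sensitivity_dist=(0.0, 0.3),
        prognostic_coeff=0.05,
        predictive_prevalence=0.5,
        predictive_effect_ratio=1.3,
    )
    drug = DrugModelSpec(
        emax=emax,
        ec50=1.0,
        k_on=0.6,
        k_off=1.0,
        residual_sd=residual_sd,
        ae_prob_active=0.05,
        ae_prob_control=0.02,
    )
    return ScenarioSpec(
        name="dornase_cf",
        population=population,
        drug=drug,
        dose=2.5,
        deviations=deviations,
        endpoint_kind="change_from_baseline",
        period_length=1.0,
    )


def demo_designs(n_patients: int = 50) -> tuple:
    """The seven compared designs (N-of-1 runs a smaller series)."""
    common = dict(n_patients=n_patients, n_periods=6, block_size=4, alpha=0.05)
    return (
        DesignSpec(variant="parallel", **common),
        DesignSpec(variant="crossover", washout_periods=1, **common),
        DesignSpec(variant="n_of_1", n_patients=8, n_periods=6, n_cycles=3, washout_periods=1),
        DesignSpec(variant="randomized_withdrawal", run_in_periods=4, responder_threshold=3.0, **common),
        DesignSpec(variant="early_escape", escape_period=3, escape_threshold=0.0, **common),
        DesignSpec(
            variant="sequential_triangular",
            interim_spacing=10,
            theta_ref=1.2,
            sided=1,
            **common,
        ),
        DesignSpec(variant="adaptive_rpw", responder_threshold=3.0, urn_initial=1, urn_add=1, **common),
    )


def demo_plan(n_replicates: int = 1000, root_seed: int = 42) -> ExperimentPlan:
    """The full demo experiment: 1 scenario x 7 designs."""
    return ExperimentPlan(
        scenarios=(demo_scenario(),),
        designs=demo_designs(),
        n_replicates=n_replicates,
        root_seed=root_seed,
        name="dornase_cf_demo",
    )


def make_demo_scenario(path, n_replicates: int = 1000, root_seed: int = 42) -> None:
    """Write the demo experiment config to ``path`` (YAML)."""
    dump_config(demo_plan(n_replicates=n_replicates, root_seed=root_seed), path)
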