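import math

import pytest

from raretrials import (
    DesignSpec,
    DeviationSpec,
    DrugModelSpec,
    PopulationSpec,
    ScenarioSpec,
    demo_scenario,
    generate_population,
)


@pytest.fixture(scope="session")
def cf_scenario():
    """The packaged mucociliary-clearance scenario (real effect, deviations on)."""
    return demo_scenario()


@pytest.fixture(scope="session")
def null_scenario():
    """Stable-disease null: no drug effect, zero mean progression, heterogeneity kept."""
    return demo_scenario(emax=0.0, progression_mean=0.0)


@pytest.fixture(scope="session")
def clean_scenario():
    """Deterministic-friendly scenario: no deviations, no patient heterogeneity."""
    population = PopulationSpec(
        n_population=500,
        baseline_dist=(math.log(20.0), 0.0),
        progression_dist=(0.0, 0.0),
        sensitivity_dist=(0.0, 0.0),
        deviation_defaults=DeviationSpec(),
    )
    drug = DrugModelSpec(emax=8.0, ec50=1.0, k_on=0.6, k_off=1.0, residual_sd=0.0)
    return ScenarioSpec(name="clean", population=population, drug=drug, dose=2.5)


@pytest.fixture(scope="session")
def small_population(cf_scenario):
    return generate_population(cf_scenario.population, seed=12345)


@pytest.fixture()
def parallel_design():
    return DesignSpec(variant="parallel", n_patients=50, n_periods=6)
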