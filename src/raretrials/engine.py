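"""Monte-Carlo experiment runner over the N scenarios x P designs grid.

For each (scenario, design) cell, R independent replicate trials are
simulated and analysed; the cell aggregates into the headline design
performance metrics: power (% significant replicates), coefficient of
variation of the effect estimate (%), mean number of patients under active
treatment, mean trial duration, mean adverse-event count and mean enrolment.

Seeding: one SeedSequence child per cell (keyed on the root seed and the
cell's grid position), one grandchild per replicate, so every cell and every
replicate is individually reproducible and independent of the others.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import analyze_trial
from .designs import DesignSpec
from .designs import run_trial as _run_trial
from .exceptions import ConfigurationError, RecruitmentError
from .population import generate_population, sample_cohort
from .scenario import ScenarioSpec

__all__ = ["ExperimentPlan", "DesignPerformance", "run_cell", "run_experiment", "performance_frame"]

logger = logging.getLogger("raretrials")

_CV_MEAN_FLOOR = 1e-8


@dataclass(frozen=True)
class ExperimentPlan:
    """N scenarios x P designs x R replicates under one root seed."""

    scenarios: tuple
    designs: tuple
    n_replicates: int = 1000
    root_seed: int = 0
    shared_population: bool = True
    name: str = "experiment"

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenarios", tuple(self.scenarios))
        object.__setattr__(self, "designs", tuple(self.designs))
        if len(self.scenarios) < 1:
            raise ConfigurationError("plan needs at least one scenario")
        if len(self.designs) < 1:
            raise ConfigurationError("plan needs at least one design")
        if self.n_replicates < 1:
            raise ConfigurationError(f"n_replicates must be >= 1, got {self.n_replicates}")
        names = [s.name for s in self.scenarios]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"scenario names must be unique, got {names}")


@dataclass
class DesignPerformance:
    """Aggregated Monte-Carlo metrics for one (scenario, design) cell."""

    scenario: str
    design: str
    variant: str
    power_pct: float
    cv_pct: float
    mean_effect: float
    mean_n_active: float
    mean_active_patient_periods: float
    mean_duration: float
    mean_ae: float
    mean_n_enrolled: float
    n_replicates: int
    n_failed: int = 0


def _cell_seed(root_seed: int, i_scenario: int, i_design: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=root_seed, spawn_key=(i_scenario, i_design))


def run_cell(
    scenario: ScenarioSpec,
    design: DesignSpec,
    n_replicates: int,
    seed,
    shared_population: bool = True,
    collect_results: bool = False,
):
    """Simulate and aggregate one (scenario, design) cell.

    Replicates hitting a recruitment failure are recorded as failed and
    excluded from the means; a cell with more than 50% failures raises.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    pop_ss, reps_ss = ss.spawn(2)
    population = (
        generate_population(scenario.population, pop_ss) if shared_population else None
    )
    rep_seeds = reps_ss.spawn(n_replicates)

    results = []
    n_failed = 0
    for r in range(n_replicates):
        cohort_ss, trial_ss, pop_rep_ss = rep_seeds[r].spawn(3)
        try:
            pop = population
            if pop is None:
                pop = generate_population(scenario.population, pop_rep_ss)
            cohort = sample_cohort(pop, design.n_patients, seed=cohort_ss)
            data = _run_trial(design, cohort, scenario, trial_ss)
            results.append(analyze_trial(data, design))
        except RecruitmentError as exc:
            logger.debug("replicate %d failed: %s", r, exc)
            n_failed += 1
    if n_failed > n_replicates / 2:
        raise RecruitmentError(
            f"cell ({scenario.name}, {design.label}): {n_failed}/{n_replicates} replicates "
            "failed recruitment",
            n_eligible=n_replicates - n_failed,
            n_required=n_replicates // 2,
        )

    effects = np.array([t.effect_estimate for t in results], dtype=float)
    finite = effects[np.isfinite(effects)]
    mean_eff = float(finite.mean()) if finite.size else float("nan")
    if finite.size >= 2 and abs(mean_eff) >= _CV_MEAN_FLOOR:
        cv = 100.0 * float(finite.std(ddof=1)) / abs(mean_eff)
    else:
        cv = float("nan")
    n_ok = len(results)
    perf = DesignPerformance(
        scenario=scenario.name,
        design=design.label,
        variant=design.variant,
        power_pct=100.0 * sum(t.significant for t in results) / n_ok if n_ok else float("nan"),
        cv_pct=cv,
        mean_effect=mean_eff,
        mean_n_active=float(np.mean([t.n_active_patients for t in results])) if n_ok else float("nan"),
        mean_active_patient_periods=(
            float(np.mean([t.active_patient_periods for t in results])) if n_ok else float("nan")
        ),
        mean_duration=float(np.mean([t.duration for t in results])) if n_ok else float("nan"),
        mean_ae=float(np.mean([t.ae_count for t in results])) if n_ok else float("nan"),
        mean_n_enrolled=float(np.mean([t.n_enrolled for t in results])) if n_ok else float("nan"),
        n_replicates=n_ok,
        n_failed=n_failed,
    )
    if collect_results:
        return perf, results
    return perf


def run_experiment(plan: ExperimentPlan, collect_results: bool = False):
    """Run every (scenario, design) cell of the plan.

    Returns the list of :class:`DesignPerformance` rows (one per cell), plus
    the per-replicate :class:`TrialResult` lists when ``collect_results``.
    """
    performances = []
    all_results = {}
    for i, scenario in enumerate(plan.scenarios):
        for j, design in enumerate(plan.designs):
            t0 = time.perf_counter()
            out = run_cell(
                scenario,
                design,
                plan.n_replicates,
                _cell_seed(plan.root_seed, i, j),
                shared_population=plan.shared_population,
                collect_results=collect_results,
            )
            if collect_results:
                perf, results = out
                all_results[(scenario.name, design.label)] = results
            else:
                perf = out
            performances.append(perf)
            logger.info(
                "cell (%s, %s): power=%.1f%% in %.2fs",
                scenario.name,
                design.label,
                perf.power_pct,
                time.perf_counter() - t0,
            )
    if collect_results:
        return performances, all_results
    return performances


def performance_frame(performances) -> pd.DataFrame:
    """Performance table, one row per (scenario, design) cell."""
    return pd.DataFrame([vars(p) for p in performances])
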