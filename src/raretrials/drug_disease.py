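"""Input-output (IO) sub-model: drug-disease dynamics and adverse events.

A discrete-time indirect-response Emax model drives a latent treatment
effect A over periods j = 1..T:

    dosed  (D_j > 0):  A_j = A_{j-1} + k_on * (E_target(D_j) - A_{j-1})
    undosed (D_j = 0): A_j = (1 - k_off) * A_{j-1}

with steady-state target

    E_target(D) = s_i * m_i * Emax * D / (EC50 + D)

where s_i is the patient's sensitivity multiplier and m_i the predictive
biomarker multiplier (predictive_effect_ratio if marker-positive, else 1).
The observed biomarker at visit j is

    Y_j = E0 + k_prog_adj * j + A_j + eps_j,   eps_j ~ N(0, residual_sd)

so the baseline visit (j = 0, A_0 = 0) carries no treatment effect.  With a
constant dose A converges geometrically to E_target(D); after stopping, the
effect decays at rate (1 - k_off) per period, so k_off = 1 means complete
washout in one period.  Onset, washout and carryover are exactly the
phenomena crossover, withdrawal and N-of-1 designs exploit.

Adverse events are independent per-period Bernoulli draws at the active or
control probability depending on whether any drug was received that period.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import rng_from
from .exceptions import ConfigurationError, StructuralError

__all__ = [
    "DrugModelSpec",
    "Regimen",
    "Trajectory",
    "simulate_trajectory",
    "extract_endpoint",
    "steady_state_effect",
    "trajectory_to_frame",
]


@dataclass(frozen=True)
class DrugModelSpec:
    """Drug-effect and safety parameters.

    emax : maximal drug effect (biomarker units; positive = benefit).
    ec50 : dose giving half-maximal effect (dose units, > 0).
    k_on : per-period fractional approach to the steady-state effect, (0, 1].
    k_off : per-period fractional washout of the carried-over effect, (0, 1].
    residual_sd : within-patient measurement noise SD (biomarker units).
    ae_prob_active / ae_prob_control : per-period adverse-event probability.
    """

    emax: float
    ec50: float
    k_on: float = 1.0
    k_off: float = 1.0
    residual_sd: float = 0.0
    ae_prob_active: float = 0.0
    ae_prob_control: float = 0.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ConfigurationError(f"ec50 must be > 0, got {self.ec50}")
        for name in ("k_on", "k_off"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigurationError(f"{name} must lie in (0, 1], got {v}")
        if self.residual_sd < 0:
            raise ConfigurationError(f"residual_sd must be >= 0, got {self.residual_sd}")
        for name in ("ae_prob_active", "ae_prob_control"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class Regimen:
    """Planned per-period exposure: a dose per period (0 = placebo/washout)."""

    dose_by_period: tuple
    period_length: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "dose_by_period", tuple(float(d) for d in self.dose_by_period))
        if len(self.dose_by_period) < 1:
            raise ConfigurationError("a regimen needs at least one period")
        if any(d < 0 for d in self.dose_by_period):
            raise ConfigurationError(f"doses must be >= 0, got {self.dose_by_period}")
        if self.period_length <= 0:
            raise ConfigurationError(f"period_length must be > 0, got {self.period_length}")

    @property
    def n_periods(self) -> int:
        return len(self.dose_by_period)


@dataclass
class Trajectory:
    """Biomarker values at visits 0..T, per-period adverse events, observed flags."""

    values_by_visit: np.ndarray
    ae_by_period: np.ndarray
    observed_by_visit: np.ndarray

    def __post_init__(self) -> None:
        if len(self.values_by_visit) != len(self.ae_by_period) + 1:
            raise StructuralError("trajectory needs one visit more than periods")
        if len(self.observed_by_visit) != len(self.values_by_visit):
            raise StructuralError("observed flags must match visit count")

    @property
    def n_periods(self) -> int:
        return len(self.ae_by_period)


def steady_state_effect(patient, drug: DrugModelSpec, dose: float, predictive_effect_ratio: float = 1.0) -> float:
    """Limiting latent effect under constant dosing: s_i * m_i * Emax * D/(EC50 + D)."""
    m = predictive_effect_ratio if patient.predictive_positive else 1.0
    return patient.s_i * m * drug.emax * dose / (drug.ec50 + dose)


def _latent_path(doses: np.ndarray, target_scale: float, drug: DrugModelSpec, a0: float = 0.0) -> np.ndarray:
    """Latent effect A_j for j = 1..T given per-period doses and the patient scale."""
    A = np.empty(doses.size)
    a = a0
    for j, d in enumerate(doses):
        if d > 0:
            target = target_scale * drug.emax * d / (drug.ec50 + d)
            a = a + drug.k_on * (target - a)
        else:
            a = (1.0 - drug.k_off) * a
        A[j] = a
    return A


def simulate_trajectory(
    patient,
    drug: DrugModelSpec,
    regimen: Regimen,
    seed,
    predictive_effect_ratio: float = 1.0,
    drug_b: DrugModelSpec | None = None,
    doses_b=None,
    baseline_noise: bool = True,
) -> Trajectory:
    """Simulate one patient's biomarker trajectory under a regimen.

    ``drug_b``/``doses_b`` optionally add a second, additive treatment
    component (factorial designs).  ``baseline_noise`` controls whether the
    baseline visit carries measurement noise.
    """
    rng = rng_from(seed)
    doses = np.asarray(regimen.dose_by_period, dtype=float)
    T = doses.size
    m = predictive_effect_ratio if patient.predictive_positive else 1.0
    A = _latent_path(doses, patient.s_i * m, drug)
    any_dose = doses > 0
    if drug_b is not None:
        db = np.asarray(doses_b, dtype=float)
        if db.size != T:
            raise StructuralError(f"doses_b length {db.size} does not match regimen length {T}")
        A = A + _latent_path(db, patient.s_i * m, drug_b)
        any_dose = any_dose | (db > 0)

    t = np.arange(T + 1, dtype=float)
    values = patient.e0 + patient.k_prog_adj * t
    values[1:] += A
    if drug.residual_sd > 0:
        noise = rng.normal(0.0, drug.residual_sd, T + 1)
        if not baseline_noise:
            noise[0] = 0.0
        values = values + noise

    ae_p = np.where(any_dose, drug.ae_prob_active, drug.ae_prob_control)
    ae = rng.random(T) < ae_p
    return Trajectory(
        values_by_visit=values,
        ae_by_period=ae,
        observed_by_visit=np.ones(T + 1, dtype=bool),
    )


def extract_endpoint(trajectory: Trajectory, kind: str = "change_from_baseline", threshold: float | None = None):
    """Reduce a trajectory to a scalar (or boolean) endpoint.

    kind is one of ``change_from_baseline``, ``final_value`` or ``responder``.
    The last *observed* visit is used (last-observation-carried-forward);
    with no post-baseline observation the endpoint is missing (NaN / None).
    """
    obs = np.flatnonzero(trajectory.observed_by_visit)
    post = obs[obs > 0]
    if post.size == 0:
        return None if kind == "responder" else float("nan")
    last = int(post[-1])
    change = float(trajectory.values_by_visit[last] - trajectory.values_by_visit[0])
    if kind == "change_from_baseline":
        return change
    if kind == "final_value":
        return float(trajectory.values_by_visit[last])
    if kind == "responder":
        if threshold is None:
            raise ConfigurationError("responder endpoint requires a threshold")
        return bool(change >= threshold)
    raise ConfigurationError(f"unknown endpoint kind {kind!r}")


def trajectory_to_frame(patient_id: str, trajectory: Trajectory, regimen: Regimen) -> pd.DataFrame:
    """Long-format export: one row per visit."""
    T = trajectory.n_periods
    doses = [float("nan")] + list(regimen.dose_by_period)
    ae = [False] + list(trajectory.ae_by_period)
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "visit": np.arange(T + 1),
            "time": np.arange(T + 1) * regimen.period_length,
            "dose": doses,
            "value": trajectory.values_by_visit,
            "observed": trajectory.observed_by_visit,
            "ae": ae,
        }
    )
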