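"""Experimental-design engines: allocation, scheduling and adaptive conduct.

Ten randomized-controlled-trial designs aimed at small samples are
implemented as conduct engines that take a cohort of virtual patients, a
scenario (drug-disease-endpoint situation) and a seed, and return the raw
trial data a design-matched analysis consumes:

- parallel           two-arm parallel groups, permuted-block allocation
- crossover          AB/BA two-period crossover with washout
- factorial_2x2      two treatments in four cells
- randomized_withdrawal  open-label active run-in, responders randomized to
                     continue or withdraw to placebo
- early_escape       placebo non-responders exit at a predefined decision point
- n_of_1             a series of randomized multi-crossover single-patient trials
- sequential_triangular  group-sequential conduct against triangular
                     stopping boundaries
- adaptive_rpw       response-adaptive randomized play-the-winner urn
- placebo_phase      randomized delay before active start; all end on active
- stepped_wedge      clusters cross from control to active at randomized steps

Conduct is intention-to-treat: each record keeps both the assigned exposure
and the exposure actually received after protocol deviations.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import rng_from, seed_sequence
from .analysis import triangular_boundaries, triangular_step
from .drug_disease import Regimen, _latent_path
from .exceptions import ConfigurationError, RecruitmentError, StructuralError
from .execution import apply_deviations

__all__ = [
    "DesignSpec",
    "PatientRecord",
    "TrialData",
    "permuted_block_allocation",
    "RPWUrn",
    "run_trial",
    "trial_to_frame",
    "VARIANTS",
]

VARIANTS = (
    "parallel",
    "crossover",
    "factorial_2x2",
    "randomized_withdrawal",
    "early_escape",
    "n_of_1",
    "sequential_triangular",
    "adaptive_rpw",
    "placebo_phase",
    "stepped_wedge",
)

_TWO_ARM_BLOCK_VARIANTS = {
    "parallel",
    "crossover",
    "randomized_withdrawal",
    "early_escape",
    "sequential_triangular",
}


@dataclass(frozen=True)
class DesignSpec:
    """One experimental-design variant and its parameters.

    Only the parameters a variant uses are consulted; the rest are inert.
    Defaults realize a plausible small-trial configuration: 6 treatment
    periods, blocks of 4, one washout period, a 4-period run-in, interim
    analyses every 10 patients, and an urn starting with one ball per arm
    adding one ball per observed outcome.
    """

    variant: str
    n_patients: int = 50
    n_periods: int = 6
    block_size: int = 4
    washout_periods: int = 1
    run_in_periods: int = 4
    responder_threshold: float = 0.0
    escape_threshold: float = 0.0
    escape_period: int = 3
    interim_schedule: tuple | None = None
    interim_spacing: int = 10
    urn_initial: int = 1
    urn_add: int = 1
    enrol_interval: int = 1
    delay_arms: tuple = (0, 3)
    n_steps: int = 5
    cluster_size: int = 1
    n_cycles: int = 3
    alpha: float = 0.05
    sided: int = 2
    theta_ref: float = 1.2
    name: str | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown design variant {self.variant!r}; choose from {VARIANTS}")
        if self.n_patients < 1:
            raise ConfigurationError(f"n_patients must be >= 1, got {self.n_patients}")
        if self.n_periods < 1:
            raise ConfigurationError(f"n_periods must be >= 1, got {self.n_periods}")
        n_arms = 4 if self.variant == "factorial_2x2" else 2
        if self.variant in _TWO_ARM_BLOCK_VARIANTS or self.variant == "factorial_2x2":
            if self.block_size < n_arms or self.block_size % n_arms != 0:
                raise ConfigurationError(
                    f"block_size must be a positive multiple of {n_arms} for "
                    f"{self.variant}, got {self.block_size}"
                )
        if self.washout_periods < 0:
            raise ConfigurationError(f"washout_periods must be >= 0, got {self.washout_periods}")
        if self.variant == "n_of_1" and self.n_cycles < 2:
            raise ConfigurationError(f"n_cycles must be >= 2 for n_of_1, got {self.n_cycles}")
        if self.variant == "early_escape" and not (1 <= self.escape_period <= self.n_periods):
            raise ConfigurationError(
                f"escape_period must lie in [1, n_periods], got {self.escape_period}"
            )
        if self.interim_schedule is not None:
            sched = tuple(self.interim_schedule)
            if any(b <= a for a, b in zip(sched, sched[1:])):
                raise ConfigurationError(f"interim_schedule must be strictly increasing, got {sched}")
            object.__setattr__(self, "interim_schedule", sched)
        if self.variant == "placebo_phase":
            delays = tuple(int(d) for d in self.delay_arms)
            if len(delays) != 2 or delays[0] == delays[1] or any(d < 0 for d in delays):
                raise ConfigurationError(
                    f"delay_arms must be two distinct non-negative delays, got {self.delay_arms}"
                )
            object.__setattr__(self, "delay_arms", delays)
        if self.variant == "stepped_wedge":
            if self.n_steps < 2:
                raise ConfigurationError(f"n_steps must be >= 2, got {self.n_steps}")
            if self.cluster_size < 1 or self.n_patients % self.cluster_size != 0:
                raise ConfigurationError(
                    f"cluster_size must divide n_patients, got {self.cluster_size} / {self.n_patients}"
                )
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.sided not in (1, 2):
            raise ConfigurationError(f"sided must be 1 or 2, got {self.sided}")
        if self.theta_ref <= 0:
            raise ConfigurationError(f"theta_ref must be > 0, got {self.theta_ref}")
        if self.urn_initial < 1 or self.urn_add < 0:
            raise ConfigurationError("urn_initial must be >= 1 and urn_add >= 0")

    @property
    def label(self) -> str:
        return self.name or self.variant


@dataclass
class PatientRecord:
    """Everything one patient contributed to one trial."""

    patient: object
    arm: str
    enrolled_order: int
    assigned_doses: np.ndarray
    received_doses: np.ndarray
    values: np.ndarray
    observed: np.ndarray
    ae: np.ndarray
    dropout_period: int | None = None
    endpoint: float = float("nan")
    meta: dict = field(default_factory=dict)

    @property
    def any_active(self) -> bool:
        return bool(np.any(self.received_doses > 0))

    @property
    def active_periods(self) -> int:
        return int(np.sum(self.received_doses > 0))


@dataclass
class TrialData:
    """Raw output of one simulated trial, input to :func:`analysis.analyze_trial`."""

    variant: str
    records: list
    period_length: float
    total_periods: int
    stop_reason: str = "completed"
    extras: dict = field(default_factory=dict)

    @property
    def n_enrolled(self) -> int:
        return len(self.records)

    @property
    def duration(self) -> float:
        return self.total_periods * self.period_length


def permuted_block_allocation(n: int, n_arms: int = 2, block_size: int = 4, seed=None) -> np.ndarray:
    """Assignment sequence of ``n`` arm indices in shuffled complete blocks.

    Within every complete block each arm appears ``block_size / n_arms``
    times, so the running imbalance between any two arms never exceeds
    ``block_size / 2``.
    """
    if block_size < n_arms or block_size % n_arms != 0:
        raise ConfigurationError(
            f"block_size must be a positive multiple of n_arms ({n_arms}), got {block_size}"
        )
    rng = rng_from(seed)
    per_arm = block_size // n_arms
    block = np.repeat(np.arange(n_arms), per_arm)
    n_blocks = -(-n // block_size)
    out = np.concatenate([rng.permutation(block) for _ in range(n_blocks)])
    return out[:n]


class RPWUrn:
    """Randomized play-the-winner urn over two arms.

    Starts with ``u`` balls per arm.  Each observed success adds ``beta``
    balls of the same arm; each failure adds ``beta`` balls of the opposite
    arm, so allocation drifts toward the arm that fails less.  With failure
    probabilities (q0, q1) the long-run allocation fraction of arm 0 tends to
    q1 / (q0 + q1).
    """

    def __init__(self, u: int = 1, beta: int = 1):
        if u < 1 or beta < 0:
            raise ConfigurationError("urn needs u >= 1 initial balls and beta >= 0")
        self.balls = [u, u]
        self.beta = beta

    def draw(self, rng) -> int:
        total = self.balls[0] + self.balls[1]
        return int(rng.random() >= self.balls[0] / total)

    def update(self, arm: int, success: bool) -> None:
        target = arm if success else 1 - arm
        self.balls[target] += self.beta


# ---------------------------------------------------------------------------
# per-patient conduct helpers
# ---------------------------------------------------------------------------


def _conduct_full(patient, scenario, planned, alt, dev_rng, out_rng, doses_b_planned=None):
    """Apply deviations to a full-horizon plan, then simulate outcomes from
    the received exposure.  Returns (record fields) before endpoint extraction."""
    T = len(planned)
    reg = Regimen(tuple(planned), scenario.period_length)
    rec = apply_deviations(reg, patient.deviation_params, dev_rng, alternative_doses=alt)
    received = rec.received_doses
    drug = scenario.drug
    m = scenario.population.predictive_effect_ratio if patient.predictive_positive else 1.0
    A = _latent_path(received, patient.s_i * m, drug)
    any_dose = received > 0
    received_b = None
    if doses_b_planned is not None:
        received_b = np.asarray(doses_b_planned, dtype=float).copy()
        if rec.dropout_period is not None:
            received_b[rec.dropout_period - 1 :] = 0.0
        A = A + _latent_path(received_b, patient.s_i * m, scenario.effective_drug_b)
        any_dose = any_dose | (received_b > 0)

    t = np.arange(T + 1, dtype=float)
    values = patient.e0 + patient.k_prog_adj * t
    values[1:] += A
    if drug.residual_sd > 0:
        values = values + out_rng.normal(0.0, drug.residual_sd, T + 1)
    ae_p = np.where(any_dose, drug.ae_prob_active, drug.ae_prob_control)
    ae = out_rng.random(T) < ae_p
    if rec.dropout_period is not None:
        ae[rec.dropout_period - 1 :] = False
    return received, rec.observed, values, ae, rec.dropout_period, A, received_b


def _endpoint(values, observed, scenario, baseline_visit=0, window=None):
    """Change endpoint with last-observation-carried-forward.

    ``window`` restricts the post-baseline visits considered (inclusive
    visit-index range); ``baseline_visit`` anchors the change.  Returns NaN
    when the anchor or every candidate visit is unobserved.
    """
    lo, hi = window if window is not None else (baseline_visit + 1, len(values) - 1)
    if not observed[baseline_visit]:
        return float("nan")
    idx = [j for j in range(hi, lo - 1, -1) if observed[j]]
    if not idx:
        return float("nan")
    last = idx[0]
    if scenario.endpoint_kind == "final_value":
        return float(values[last])
    change = float(values[last] - values[baseline_visit])
    if scenario.endpoint_kind == "responder":
        return float(change >= scenario.endpoint_threshold)
    return change


def _check_cohort(design, cohort, n_required=None):
    need = n_required if n_required is not None else design.n_patients
    if len(cohort) < need:
        raise RecruitmentError(
            f"design {design.variant} needs {need} patients, cohort has {len(cohort)}",
            n_eligible=len(cohort),
            n_required=need,
        )
    return list(cohort)[:need]


# ---------------------------------------------------------------------------
# variant runners
# ---------------------------------------------------------------------------


def _run_parallel(design, cohort, scenario, alloc_rng, dev_rng, out_rng):
    cohort = _check_cohort(design, cohort)
    T = design.n_periods
    active = np.full(T, scenario.dose)
    placebo = np.zeros(T)
    arms = permuted_block_allocation(len(cohort), 2, design.block_size, alloc_rng)
    records = []
    for i, (patient, arm) in enumerate(zip(cohort, arms)):
        planned, alt = (active, placebo) if arm == 0 else (placebo, active)
        received, observed, values, ae, dropout, _, _ = _conduct_full(
            patient, scenario, planned, alt, dev_rng, out_rng
        )
        records.append(
            PatientRecord(
                patient=patient,
                arm="active" if arm == 0 else "control",
                enrolled_order=i,
                assigned_doses=np.array(planned),
                received_doses=received,
                values=values,
                observed=observed,
                ae=ae,
                dropout_period=dropout,
                endpoint=_endpoint(values, observed, scenario),
            )
        )
    return TrialData("parallel", records, scenario.period_length, T)


def _run_crossover(design, cohort, scenario, alloc_rng, dev_rng, out_rng):
    cohort = _check_cohort(design, cohort)
    n, w = design.n_periods, design.washout_periods
    T = 2 * n + w
    dose = scenario.dose
    ab = np.concatenate([np.full(n, dose), np.zeros(w), np.zeros(n)])
    ba = np.concatenate([np.zeros(n), np.zeros(w), np.full(n, dose)])
    arms = permuted_block_allocation(len(cohort), 2, design.block_size, alloc_rng)
    records = []
    for i, (patient, arm) in enumerate(zip(cohort, arms)):
        planned, alt = (ab, ba) if arm == 0 else (ba, ab)
        received, observed, values, ae, dropout, _, _ = _conduct_full(
            patient, scenario, planned, alt, dev_rng, out_rng
        )
        change1 = _endpoint(values, observed, scenario, baseline_visit=0, window=(1, n))
        change2 = _endpoint(values, observed, scenario, baseline_visit=n + w, window=(n + w + 1, T))
        if arm == 0:
            d = change1 - change2
        else:
            d = change2 - change1
        records.append(
            PatientRecord(
                patient=patient,
                arm="AB" if arm == 0 else "BA",
                enrolled_order=i,
                assigned_doses=np.array(planned),
                received_doses=received,
                values=values,
                observed=observed,
                ae=ae,
                dropout_period=dropout,
                endpoint=d,
                meta={"phase_active_change": change1 if arm == 0 else change2,
                      "phase_placebo_change": change2 if arm == 0 else change1},
            )
        )
    return TrialData("crossover", records, scenario.period_length, T)


_FACTORIAL_ARMS = ("placebo", "a_only", "b_only", "ab")


def _run_factorial(design, cohort, scenario, alloc_rng, dev_rng, out_rng):
    cohort = _check_cohort(design, cohort)
    T = design.n_periods
    dose_a, dose_b = scenario.dose, scenario.effective_dose_b
    arms = permuted_block_allocation(len(cohort), 4, design.block_size, alloc_rng)
    records = []
    for i, (patient, arm) in enumerate(zip(cohort, arms)):
        a_on = arm in (1, 3)
        b_on = arm in (2, 3)
        planned_a = np.full(T, dose_a) if a_on else np.zeros(T)
        planned_b = np.full(T, dose_b) if b_on else np.zeros(T)
        received, observed, values, ae, dropout, _, received_b = _conduct_full(
            patient, scenario, planned_a, np.zeros(T), dev_rng, out_rng, doses_b_planned=planned_b
        )
        records.append(
            PatientRecord(
                patient=patient,
                arm=_FACTORIAL_ARMS[arm],
                enrolled_order=i,
                assigned_doses=planned_a,
                received_doses=received,
                values=values,
                observed=observed,
                ae=ae,
                dropout_period=dropout,
                endpoint=_endpoint(values, observed, scenario),
                meta={"a_assigned": a_on, "b_assigned": b_on, "received_b": received_b},
            )
        )
    return TrialData("factorial_2x2", records, scenario.period_length, T)


def _segment(patient, scenario, planned, alt, a0, t0, dev_rng, out_rng):
    """Deviations + outcomes for a continuation segment starting at visit t0
    with latent effect a0.  Returns received, observed (length len+1, first
    entry refers to visit t0 and is informational only), values for visits
    t0+1..t0+len, ae, dropout, a_end."""
    reg = Regimen(tuple(planned), scenario.period_length)
    rec = apply_deviations(reg, patient.deviation_params, dev_rng, alternative_doses=alt)
    received = rec.received_doses
    drug = scenario.drug
    m = scenario.population.predictive_effect_ratio if patient.predictive_positive else 1.0
    A = _latent_path(received, patient.s_i * m, drug, a0=a0)
    L = received.size
    t = np.arange(t0 + 1, t0 + L + 1, dtype=float)
    values = patient.e0 + patient.k_prog_adj * t + A
    if drug.residual_sd > 0:
        values = values + out_rng.normal(0.0, drug.residual_sd, L)
    ae_p = np.where(received > 0, drug.ae_prob_active, drug.ae_prob_control)
    ae = out_rng.random(L) < ae_p
    if rec.dropout_period is not None:
        ae[rec.dropout_period - 1 :] = False
    a_end = A[-1] if L else a0
    return received, rec.observed[1:], values, ae, rec.dropout_period, a_end


def _run_withdrawal(design, cohort, scenario, alloc_rng, dev_rng, out_rng):
    cohort = _check_cohort(design, cohort)
    r, n = design.run_in_periods, design.n_periods
    T = r + n
    dose = scenario.dose
    runin = np.full(r, dose)

    # open-label run-in for everyone
    stage = []
    for i, patient in enumerate(cohort):
        received, observed, values, ae, dropout, A, _ = _conduct_full(
            patient, scenario, runin, np.zeros(r), dev_rng, out_rng
        )
        anchor = next((j for j in range(r, 0, -1) if observed[j]), None)
        responder = (
            dropout is None
            and anchor is not None
            and values[anchor] - values[0] >= design.responder_threshold
        )
        stage.append((patient, received, observed, values, ae, dropout, A[-1] if r else 0.0, anchor, responder))

    responders = [i for i, s in enumerate(stage) if s[8]]
    if len(responders) < 2:
        raise RecruitmentError(
            f"randomized_withdrawal needs >= 2 run-in responders, got {len(responders)}",
            n_eligible=len(responders),
            n_required=2,
        )
    arms = permuted_block_allocation(len(responders), 2, design.block_size, alloc_rng)
    arm_of = dict(zip(responders, arms))

    active_cont = np.full(n, dose)
    placebo_cont = np.zeros(n)
    records = []
    for i, (patient, received, observed, values, ae, dropout, a_end, anchor, responder) in enumerate(stage):
        if not responder:
            rec_doses = np.concatenate([received, np.zeros(n)])
            obs = np.concatenate([observed, np.zeros(n, dtype=bool)])
            vals = np.concatenate([values, np.full(n, np.nan)])
            aes = np.concatenate([ae, np.zeros(n, dtype=bool)])
            records.append(
                PatientRecord(
                    patient=patient,
                    arm="runin_only",
                    enrolled_order=i,
                    assigned_doses=np.concatenate([runin, np.zeros(n)]),
                    received_doses=rec_doses,
                    values=vals,
                    observed=obs,
                    ae=aes,
                    dropout_period=dropout,
                    endpoint=float("nan"),
                    meta={"responder": False},
                )
            )
            continue
        arm = arm_of[i]
        planned, alt = (active_cont, placebo_cont) if arm == 0 else (placebo_cont, active_cont)
        rec2, obs2, vals2, ae2, drop2, _ = _segment(patient, scenario, planned, alt, a_end, r, dev_rng, out_rng)
        all_vals = np.concatenate([values, vals2])
        all_obs = np.concatenate([observed, obs2])
        # change from the randomization anchor to the last observed withdrawal-phase visit
        post = [j for j in range(T, r, -1) if all_obs[j]]
        endpoint = float(all_vals[post[0]] - values[anchor]) if post else float("nan")
        records.append(
            PatientRecord(
                patient=patient,
                arm="active" if arm == 0 else "control",
                enrolled_order=i,
                assigned_doses=np.concatenate([runin, planned]),
                received_doses=np.concatenate([received, rec2]),
                values=all_vals,
                observed=all_obs,
                ae=np.concatenate([ae, ae2]),
                dropout_period=dropout or (r + drop2 if drop2 else None),
                endpoint=endpoint,
                meta={"responder": True},
            )
        )
    return TrialData("randomized_withdrawal", records, scenario.period_length, T)


def _run_early_escape(design, cohort, scenario, alloc_rng, dev_rng, out_rng):
    data = _run_parallel(design, cohort, scenario, alloc_rng, dev_rng, out_rng)
    data.variant = "early_escape"
    esc = design.escape_period
    for rec in data.records:
        # the escape rule is applied to non-responders of either arm: the same
        # selection then acts on both arms, keeping the comparison unbiased,
        # while under a real effect it is almost only placebo patients who leave
        # decision value at the escape visit (carry the last prior observation forward)
        anchor = next((j for j in range(esc, 0, -1) if rec.observed[j]), None)
        if anchor is None or not rec.observed[0]:
            continue
        change = rec.values[anchor] - rec.values[0]
        if change < design.escape_threshold and esc < design.n_periods:
            rec.observed[esc + 1 :] = False
            rec.received_doses[esc:] = 0.0
            rec.ae[esc:] = False
            rec.meta["escaped"] = True
            rec.endpoint = _endpoint(rec.values, rec.observed, scenario)
    return data


def _run_n_of_1(design, cohort, scenario, alloc_rng, dev_rng, out_rng):
    cohort = _check_cohort(design, cohort)
    w, C = design.washout_periods, design.n_cycles
    dose = scenario.dose
    records = []
    for i, patient in enumerate(cohort):
        doses = []
        slots = []  # (cycle, treatment, visit index of period end)
        for c in range(C):
            order = ["active", "placebo"] if alloc_rng.random() < 0.5 else ["placebo", "active"]
            for k, treat in enumerate(order):
                doses.append(dose if treat == "active" else 0.0)
                slots.append((c, treat, len(doses)))
                last = c == C - 1 and k == 1
                if w and not last:
                    doses.extend([0.0] * w)
        planned = np.array(doses)
        # alternative exposure = complement at treatment periods, washout unchanged
        alt = planned.copy()
        for c, treat, j in slots:
            alt[j - 1] = 0.0 if planned[j - 1] > 0 else dose
        received, observed, values, ae, dropout, _, _ = _conduct_full(
            patient, scenario, planned, alt, dev_rng, out_rng
        )
        diffs = []
        for c in range(C):
            pair = [s for s in slots if s[0] == c]
            changes = {}
            for _, treat, j in pair:
                if observed[j] and observed[j - 1]:
                    changes[treat] = values[j] - values[j - 1]
            if "active" in changes and "placebo" in changes:
                diffs.append(changes["active"] - changes["placebo"])
        endpoint = float(np.mean(diffs)) if diffs else float("nan")
        records.append(
            PatientRecord(
                patient=patient,
                arm="series",
                enrolled_order=i,
                assigned_doses=planned,
                received_doses=received,
                values=values,
                observed=observed,
                ae=ae,
                dropout_period=dropout,
                endpoint=endpoint,
                meta={"cycle_diffs": diffs, "n_cycles_used": len(diffs)},
            )
        )
    total = len(records[0].assigned_doses) if records else 0
    return TrialData("n_of_1", records, scenario.period_length, total)


def _interims(design) -> tuple:
    if design.interim_schedule is not None:
        sched = [s for s in design.interim_schedule if s <= design.n_patients]
    else:
        sched = list(range(design.interim_spacing, design.n_patients + 1, design.interim_spacing))
    if not sched or sched[-1] != design.n_patients:
        sched.append(design.n_patients)
    return tuple(sched)


def _score_statistics(endpoints_a, endpoints_b):
    """Whitehead efficient score Z and information V for a two-sample
    comparison of means with the standardized effect theta = (mu_a - mu_b)/sigma:
    V = n_a n_b / N and Z = V * (xbar_a - xbar_b) / s_pooled."""
    na, nb = len(endpoints_a), len(endpoints_b)
    if na < 2 or nb < 2:
        return None
    a = np.asarray(endpoints_a)
    b = np.asarray(endpoints_b)
    s2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if s2 <= 0:
        return None
    V = na * nb / (na + nb)
    Z = V * (a.mean() - b.mean()) / np.sqrt(s2)
    return Z, V


def _run_sequential(design, cohort, scenario, alloc_rng, dev_rng, out_rng):
    cohort = _check_cohort(design, cohort)
    T = design.n_periods
    active = np.full(T, scenario.dose)
    placebo = np.zeros(T)
    arms = permuted_block_allocation(len(cohort), 2, design.block_size, alloc_rng)
    a_bound, c_slope = triangular_boundaries(design.alpha, design.theta_ref)
    sched = _interims(design)

    records = []
    interim_log = []
    stop_reason = "completed"
    enrolled = 0
    for group_idx, upto in enumerate(sched):
        for i in range(enrolled, upto):
            patient, arm = cohort[i], arms[i]
            planned, alt = (active, placebo) if arm == 0 else (placebo, active)
            received, observed, values, ae, dropout, _, _ = _conduct_full(
                patient, scenario, planned, alt, dev_rng, out_rng
            )
            records.append(
                PatientRecord(
                    patient=patient,
                    arm="active" if arm == 0 else "control",
                    enrolled_order=i,
                    assigned_doses=np.array(planned),
                    received_doses=received,
                    values=values,
                    observed=observed,
                    ae=ae,
                    dropout_period=dropout,
                    endpoint=_endpoint(values, observed, scenario),
                )
            )
        enrolled = upto
        ea = [r.endpoint for r in records if r.arm == "active" and np.isfinite(r.endpoint)]
        eb = [r.endpoint for r in records if r.arm == "control" and np.isfinite(r.endpoint)]
        zv = _score_statistics(ea, eb)
        if zv is None:
            interim_log.append({"n": enrolled, "Z": None, "V": None, "decision": "continue"})
            continue
        Z, V = zv
        decision = triangular_step(Z, V, a_bound, c_slope)
        interim_log.append({"n": enrolled, "Z": Z, "V": V, "decision": decision})
        if decision == "stop_efficacy":
            stop_reason = "efficacy_stop"
            break
        if decision == "stop_futility":
            stop_reason = "futility_stop"
            break
    groups_used = len(interim_log) if interim_log else 1
    return TrialData(
        "sequential_triangular",
        records,
        scenario.period_length,
        groups_used * T,
        stop_reason=stop_reason,
        extras={"interims": interim_log, "a": a_bound, "c": c_slope, "schedule": sched},
    )


def _run_rpw(design, cohort, scenario, alloc_rng, dev_rng, out_rng):
    """Play-the-winner conduct with staggered enrolment: patients enter
    ``enrol_interval`` periods apart and the urn is updated with every
    outcome available at each allocation time."""
    cohort = _check_cohort(design, cohort)
    T = design.n_periods
    stagger = design.enrol_interval
    active = np.full(T, scenario.dose)
    placebo = np.zeros(T)
    urn = RPWUrn(design.urn_initial, design.urn_add)
    pending = []  # (available_time, arm, success)
    records = []
    for i, patient in enumerate(cohort):
        now = i * stagger
        still = []
        for avail, arm, success in pending:
            if avail <= now:
                urn.update(arm, success)
            else:
                still.append((avail, arm, success))
        pending = still
        arm = urn.draw(alloc_rng)
        planned, alt = (active, placebo) if arm == 0 else (placebo, active)
        received, observed, values, ae, dropout, _, _ = _conduct_full(
            patient, scenario, planned, alt, dev_rng, out_rng
        )
        endpoint = _endpoint(values, observed, scenario)
        records.append(
            PatientRecord(
                patient=patient,
                arm="active" if arm == 0 else "control",
                enrolled_order=i,
                assigned_doses=np.array(planned),
                received_doses=received,
                values=values,
                observed=observed,
                ae=ae,
                dropout_period=dropout,
                endpoint=endpoint,
                meta={"enrol_time": now},
            )
        )
        post = [j for j in range(T, 0, -1) if observed[j]]
        if post:
            change = values[post[0]] - values[0]
            pending.append((now + T, arm, bool(change >= design.responder_threshold)))
    total = (len(cohort) - 1) * stagger + T
    return TrialData(
        "adaptive_rpw",
        records,
        scenario.period_length,
        total,
        extras={"urn_final": tuple(urn.balls)},
    )


def _run_placebo_phase(design, cohort, scenario, alloc_rng, dev_rng, out_rng):
    cohort = _check_cohort(design, cohort)
    delays = design.delay_arms
    d_max = max(delays)
    T = d_max + design.n_periods
    dose = scenario.dose
    arms = permuted_block_allocation(len(cohort), 2, design.block_size, alloc_rng)
    records = []
    for i, (patient, arm) in enumerate(zip(cohort, arms)):
        d = delays[arm]
        planned = np.concatenate([np.zeros(d), np.full(T - d, dose)])
        d_alt = delays[1 - arm]
        alt = np.concatenate([np.zeros(d_alt), np.full(T - d_alt, dose)])
        received, observed, values, ae, dropout, _, _ = _conduct_full(
            patient, scenario, planned, alt, dev_rng, out_rng
        )
        window_endpoint = (
            _endpoint(values, observed, scenario, baseline_visit=0, window=(1, d_max))
            if d_max >= 1
            else float("nan")
        )
        records.append(
            PatientRecord(
                patient=patient,
                arm=f"delay_{d}",
                enrolled_order=i,
                assigned_doses=planned,
                received_doses=received,
                values=values,
                observed=observed,
                ae=ae,
                dropout_period=dropout,
                endpoint=window_endpoint,
                meta={"delay": d, "full_change": _endpoint(values, observed, scenario)},
            )
        )
    return TrialData("placebo_phase", records, scenario.period_length, T)


def _run_stepped_wedge(design, cohort, scenario, alloc_rng, dev_rng, out_rng):
    cohort = _check_cohort(design, cohort)
    S = design.n_steps
    T = S + 1
    dose = scenario.dose
    n_clusters = len(cohort) // design.cluster_size
    steps_of_cluster = permuted_block_allocation(n_clusters, S, S, alloc_rng) + 1
    records = []
    for i, patient in enumerate(cohort):
        s = int(steps_of_cluster[i // design.cluster_size])
        planned = np.concatenate([np.zeros(s), np.full(T - s, dose)])
        alt = np.zeros(T)
        received, observed, values, ae, dropout, _, _ = _conduct_full(
            patient, scenario, planned, alt, dev_rng, out_rng
        )
        records.append(
            PatientRecord(
                patient=patient,
                arm=f"step_{s}",
                enrolled_order=i,
                assigned_doses=planned,
                received_doses=received,
                values=values,
                observed=observed,
                ae=ae,
                dropout_period=dropout,
                endpoint=_endpoint(values, observed, scenario),
                meta={"step": s, "cluster": i // design.cluster_size},
            )
        )
    return TrialData("stepped_wedge", records, scenario.period_length, T)


_RUNNERS = {
    "parallel": _run_parallel,
    "crossover": _run_crossover,
    "factorial_2x2": _run_factorial,
    "randomized_withdrawal": _run_withdrawal,
    "early_escape": _run_early_escape,
    "n_of_1": _run_n_of_1,
    "sequential_triangular": _run_sequential,
    "adaptive_rpw": _run_rpw,
    "placebo_phase": _run_placebo_phase,
    "stepped_wedge": _run_stepped_wedge,
}


def run_trial(design: DesignSpec, cohort, scenario, seed) -> TrialData:
    """Conduct one simulated trial of ``design`` on ``cohort`` under ``scenario``.

    Three independent random streams are spawned from ``seed``: treatment
    allocation, protocol deviations, and outcomes, so e.g. changing deviation
    probabilities never perturbs the allocation sequence.
    """
    ss = seed_sequence(seed)
    alloc_ss, dev_ss, out_ss = ss.spawn(3)
    return _RUNNERS[design.variant](
        design, cohort, scenario, rng_from(alloc_ss), rng_from(dev_ss), rng_from(out_ss)
    )


def trial_to_frame(data: TrialData, trial_id: str = "trial") -> pd.DataFrame:
    """Long-format export: one row per patient-period."""
    rows = []
    for rec in data.records:
        T = len(rec.received_doses)
        for j in range(T):
            rows.append(
                {
                    "trial_id": trial_id,
                    "patient_id": rec.patient.patient_id,
                    "arm": rec.arm,
                    "period": j + 1,
                    "assigned": rec.assigned_doses[j],
                    "received": rec.received_doses[j],
                    "value": rec.values[j + 1],
                    "observed": bool(rec.observed[j + 1]),
                    "ae": bool(rec.ae[j]),
                }
            )
    return pd.DataFrame(rows)
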