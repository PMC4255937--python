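"""Execution sub-model: probabilistic protocol deviations.

Planned exposure is perturbed by four per-patient deviation processes —
missed visits, definitive dropout, treatment switching, and partial
compliance — after which outcomes are re-simulated from the exposure the
patient actually received.  Analyses remain intention-to-treat: the assigned
arm, not the received one, enters the statistical comparison.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import rng_from
from .exceptions import ConfigurationError, StructuralError

__all__ = ["DeviationSpec", "ExecutedRecord", "apply_deviations"]


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ConfigurationError(f"{name} must lie in [0, 1], got {p!r}")


@dataclass(frozen=True)
class DeviationSpec:
    """Per-patient protocol-deviation probabilities.

    Parameters
    ----------
    missed_visit_prob : per-visit probability of a missed (unobserved) visit;
        the baseline visit is never missed.
    dropout_hazard : per-period probability of definitive, absorbing dropout.
        After dropout no drug is received and no visit is observed.
    switch_prob : per-period probability of switching to the alternative
        treatment; a second switch switches back.
    noncompliance_prob : per-period probability of partial compliance.
    noncompliance_fraction : dose multiplier in [0, 1] applied in a
        partially-compliant period.
    """

    missed_visit_prob: float = 0.0
    dropout_hazard: float = 0.0
    switch_prob: float = 0.0
    noncompliance_prob: float = 0.0
    noncompliance_fraction: float = 1.0

    def __post_init__(self) -> None:
        _check_prob("missed_visit_prob", self.missed_visit_prob)
        _check_prob("dropout_hazard", self.dropout_hazard)
        _check_prob("switch_prob", self.switch_prob)
        _check_prob("noncompliance_prob", self.noncompliance_prob)
        _check_prob("noncompliance_fraction", self.noncompliance_fraction)


@dataclass
class ExecutedRecord:
    """Exposure actually received, and which visits were observed.

    ``received_doses`` has one entry per period; ``observed`` has one entry
    per visit (baseline + one per period).  ``dropout_period`` is the 1-based
    period at which the patient definitively left, or None for a completer.
    """

    received_doses: np.ndarray
    observed: np.ndarray
    dropout_period: int | None = None
    switch_periods: list = field(default_factory=list)
    noncompliant_periods: list = field(default_factory=list)

    @property
    def completed(self) -> bool:
        return self.dropout_period is None


def apply_deviations(regimen, dev: DeviationSpec, seed, alternative_doses=None) -> ExecutedRecord:
    """Overlay protocol deviations on a planned regimen.

    Parameters
    ----------
    regimen : Regimen
        The planned per-period doses.
    dev : DeviationSpec
    seed : int | SeedSequence | Generator
        Deviation stream; independent of the outcome-noise stream by
        construction (the caller passes separate streams).
    alternative_doses : array-like, optional
        Dose sequence of the alternative treatment a switching patient
        receives; defaults to all-zero (switch to no treatment).

    Returns
    -------
    ExecutedRecord
        Received doses, per-visit observed flags, dropout period and the
        periods at which switches / partial compliance occurred.
    """
    rng = rng_from(seed)
    planned = np.asarray(regimen.dose_by_period, dtype=float)
    T = planned.size
    if alternative_doses is None:
        alt = np.zeros(T)
    else:
        alt = np.asarray(alternative_doses, dtype=float)
        if alt.size != T:
            raise StructuralError(
                f"alternative_doses length {alt.size} does not match regimen length {T}"
            )

    received = planned.copy()
    observed = np.ones(T + 1, dtype=bool)  # visit 0 = baseline, never missed
    dropout_period: int | None = None
    switches: list[int] = []
    noncompliant: list[int] = []
    switched = False

    for j in range(1, T + 1):
        if dropout_period is None and dev.dropout_hazard > 0 and rng.random() < dev.dropout_hazard:
            dropout_period = j
        if dropout_period is not None:
            received[j - 1 :] = 0.0
            observed[j:] = False
            break
        if dev.switch_prob > 0 and rng.random() < dev.switch_prob:
            switched = not switched
            switches.append(j)
        dose = alt[j - 1] if switched else planned[j - 1]
        if dev.noncompliance_prob > 0 and rng.random() < dev.noncompliance_prob:
            dose *= dev.noncompliance_fraction
            noncompliant.append(j)
        received[j - 1] = dose
        if dev.missed_visit_prob > 0 and rng.random() < dev.missed_visit_prob:
            observed[j] = False

    return ExecutedRecord(
        received_doses=received,
        observed=observed,
        dropout_period=dropout_period,
        switch_periods=switches,
        noncompliant_periods=noncompliant,
    )
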