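"""Multiple-criteria ranking of (scenario, design) performance rows.

Three orderings are offered:

- :func:`rank_by_significance`: descending power, ties broken by higher
  precision (lower CV) and then shorter duration;
- :func:`rank_weighted`: weighted sum of min-max normalized criteria under a
  stakeholder preference profile;
- :func:`pareto_front`: the non-dominated subset under the profile's
  criterion directions.

Whether exposure to active treatment is a benefit (severe disease, active
drug presumed helpful) or a burden (safety risk) is a stakeholder judgement;
the direction of the ``n_active`` criterion is therefore part of the profile
and carries no default weight.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = ["PreferenceProfile", "rank_by_significance", "rank_weighted", "pareto_front"]

logger = logging.getLogger("raretrials")

_CRITERIA = {
    "power": ("power_pct", "max"),
    "precision": ("cv_pct", "min"),  # lower CV = higher precision
    "n_active": ("mean_n_active", None),  # direction from the profile
    "duration": ("mean_duration", "min"),
    "adverse_events": ("mean_ae", "min"),
    "enrolment": ("mean_n_enrolled", "min"),
}


@dataclass(frozen=True)
class PreferenceProfile:
    """Stakeholder weights over the performance criteria (normalized to sum 1)."""

    power: float = 1.0
    precision: float = 0.0
    n_active: float = 0.0
    duration: float = 0.0
    adverse_events: float = 0.0
    enrolment: float = 0.0
    n_active_direction: str = "minimize"

    def __post_init__(self) -> None:
        weights = [self.power, self.precision, self.n_active, self.duration,
                   self.adverse_events, self.enrolment]
        if any(w < 0 for w in weights):
            raise ConfigurationError(f"preference weights must be >= 0, got {weights}")
        if sum(weights) <= 0:
            raise ConfigurationError("at least one preference weight must be positive")
        if self.n_active_direction not in ("minimize", "maximize"):
            raise ConfigurationError(
                f"n_active_direction must be 'minimize' or 'maximize', got {self.n_active_direction!r}"
            )

    def normalized(self) -> dict:
        weights = {
            "power": self.power,
            "precision": self.precision,
            "n_active": self.n_active,
            "duration": self.duration,
            "adverse_events": self.adverse_events,
            "enrolment": self.enrolment,
        }
        total = sum(weights.values())
        return {k: v / total for k, v in weights.items()}

    def direction(self, criterion: str) -> str:
        col, direction = _CRITERIA[criterion]
        if direction is None:
            return "maximize" if self.n_active_direction == "maximize" else "minimize"
        return "maximize" if direction == "max" else "minimize"


def _as_frame(performances) -> pd.DataFrame:
    if isinstance(performances, pd.DataFrame):
        return performances.copy()
    return pd.DataFrame([vars(p) for p in performances])


def rank_by_significance(performances) -> pd.DataFrame:
    """Rank by the share of significant replicates (power), descending.

    Ties break by higher precision (lower CV; missing CV ranks last), then
    by shorter mean duration.  Adds a 1-based ``rank`` column.
    """
    df = _as_frame(performances)
    if df.empty:
        return df.assign(rank=pd.Series(dtype=int))
    cv = df["cv_pct"].fillna(np.inf)
    order = df.assign(_cv=cv).sort_values(
        by=["power_pct", "_cv", "mean_duration"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    order = order.drop(columns="_cv").reset_index(drop=True)
    order["rank"] = np.arange(1, len(order) + 1)
    return order


def _normalize_column(values: np.ndarray, direction: str) -> np.ndarray:
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return np.zeros_like(values)
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        logger.info("criterion column is constant; it contributes 0 after normalization")
        return np.zeros_like(values)
    scaled = (values - lo) / (hi - lo)
    scaled = np.where(np.isfinite(scaled), scaled, 0.0)  # missing -> worst-neutral 0
    return scaled if direction == "maximize" else 1.0 - scaled


def rank_weighted(performances, profile: PreferenceProfile) -> pd.DataFrame:
    """Weighted-sum MCDA ranking with per-criterion min-max normalization.

    The returned frame carries the total ``score``, one ``score_<criterion>``
    decomposition column per criterion, and a 1-based ``rank``; ties keep the
    input order (stable sort).
    """
    df = _as_frame(performances)
    if df.empty:
        return df.assign(score=pd.Series(dtype=float), rank=pd.Series(dtype=int))
    weights = profile.normalized()
    score = np.zeros(len(df))
    parts = {}
    for criterion, w in weights.items():
        col, _ = _CRITERIA[criterion]
        values = df[col].to_numpy(dtype=float)
        if criterion == "precision":
            # precision = 1/cv; normalizing -cv is equivalent and avoids 1/0
            values = values.copy()
        contrib = w * _normalize_column(values, profile.direction(criterion))
        parts[f"score_{criterion}"] = contrib
        score = score + contrib
    out = df.assign(score=score, **parts)
    out = out.sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def pareto_front(performances, profile: PreferenceProfile | None = None) -> pd.DataFrame:
    """Non-dominated subset under the profile's criterion directions.

    A row is dominated when another row is at least as good on every
    criterion with positive weight and strictly better on one.  Duplicated
    rows are mutually non-dominating and both retained.
    """
    df = _as_frame(performances)
    if df.empty:
        return df
    profile = profile or PreferenceProfile(
        power=1, precision=1, duration=1, adverse_events=1, enrolment=1
    )
    weights = profile.normalized()
    active = [c for c, w in weights.items() if w > 0]
    cols = np.column_stack(
        [
            _signed(df[_CRITERIA[c][0]].to_numpy(dtype=float), profile.direction(c))
            for c in active
        ]
    )
    n = len(df)
    dominated = np.zeros(n, dtype=bool)
    for i in range(n):
        if dominated[i]:
            continue
        for j in range(n):
            if i == j:
                continue
            if np.all(cols[j] >= cols[i]) and np.any(cols[j] > cols[i]):
                dominated[i] = True
                break
    return df[~dominated].reset_index(drop=True)


def _signed(values: np.ndarray, direction: str) -> np.ndarray:
    values = np.where(np.isfinite(values), values, -np.inf if direction == "maximize" else np.inf)
    return values if direction == "maximize" else -values
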