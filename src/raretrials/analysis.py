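"""Design-matched statistical analysis of one simulated trial.

Each design variant gets its simplest valid analysis, intention-to-treat and
complete-case by default:

- parallel-type designs (parallel, play-the-winner, early escape, the
  randomized phase of a withdrawal trial, factorial margins, placebo-phase
  delay groups): Welch two-sample t test on patient endpoints;
- crossover and N-of-1: one-sample t test on within-patient treatment
  differences;
- stepped wedge: ordinary least squares on patient, period and treatment
  indicators, testing the treatment coefficient;
- sequential designs: Whitehead's triangular test on the efficient score
  Z_k and Fisher information V_k accumulated at each interim, with straight-
  line boundaries  Z = a + c V  (efficacy) and  Z = -a + 3 c V  (futility)
  meeting at the apex V = a / c.

The triangular boundary constants use the classic construction for a
one-sided test with size alpha and power 1 - alpha at the reference effect
theta_R (no-overshoot approximation):

    a = 2 * ln(1 / (2 alpha)) / theta_R,      c = theta_R / 4.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import StructuralError

__all__ = [
    "TrialResult",
    "analyze_trial",
    "welch_t",
    "one_sample_t",
    "rank_sum",
    "triangular_boundaries",
    "triangular_step",
]


@dataclass
class TrialResult:
    """Outcome of analysing one simulated trial."""

    variant: str
    effect_estimate: float
    standard_error: float
    p_value: float
    significant: bool
    n_enrolled: int
    n_analyzed: int
    n_active_patients: int
    active_patient_periods: int
    duration: float
    ae_count: int
    stop_reason: str = "completed"
    warnings: list = field(default_factory=list)


def welch_t(a, b, sided: int = 2):
    """Welch two-sample t test: (effect, se, t, df, p).

    effect = mean(a) - mean(b); one-sided tests the benefit direction
    (effect > 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    effect = a.mean() - b.mean()
    va, vb = a.var(ddof=1) if na > 1 else np.nan, b.var(ddof=1) if nb > 1 else np.nan
    se = math.sqrt(va / na + vb / nb) if na > 1 and nb > 1 else float("nan")
    if not np.isfinite(se) or se == 0.0:
        return effect, se, float("nan"), float("nan"), float("nan")
    t = effect / se
    df = (va / na + vb / nb) ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = stats.t.sf(t, df) if sided == 1 else 2.0 * stats.t.sf(abs(t), df)
    return effect, se, t, df, float(p)


def one_sample_t(d, sided: int = 2):
    """One-sample t test against 0: (effect, se, t, df, p)."""
    d = np.asarray(d, dtype=float)
    n = d.size
    effect = d.mean() if n else float("nan")
    if n < 2:
        return effect, float("nan"), float("nan"), float("nan"), float("nan")
    se = d.std(ddof=1) / math.sqrt(n)
    if se == 0.0:
        return effect, se, float("nan"), float("nan"), float("nan")
    t = effect / se
    p = stats.t.sf(t, n - 1) if sided == 1 else 2.0 * stats.t.sf(abs(t), n - 1)
    return effect, se, t, n - 1, float(p)


def rank_sum(a, b, sided: int = 2):
    """Wilcoxon-Mann-Whitney alternative to the Welch comparison."""
    alternative = "greater" if sided == 1 else "two-sided"
    res = stats.mannwhitneyu(a, b, alternative=alternative)
    return float(res.pvalue)


def triangular_boundaries(alpha: float, theta_ref: float):
    """Straight-line triangular-test boundary constants (a, c)."""
    if not (0 < alpha < 0.5):
        raise StructuralError(f"alpha must lie in (0, 0.5), got {alpha}")
    if theta_ref <= 0:
        raise StructuralError(f"theta_ref must be > 0, got {theta_ref}")
    a = 2.0 * math.log(1.0 / (2.0 * alpha)) / theta_ref
    c = theta_ref / 4.0
    return a, c


def triangular_step(Z: float, V: float, a: float, c: float) -> str:
    """Triangular-test decision at one interim.

    Stop for efficacy when Z >= a + cV (boundary inclusive), for futility
    when Z <= -a + 3cV, otherwise continue.  At V = 0 the continuation
    region is the open interval (-a, a).
    """
    if V < 0:
        raise StructuralError(f"information V must be >= 0, got {V}")
    if a <= 0 or c <= 0:
        raise StructuralError(f"boundary constants must be positive, got a={a}, c={c}")
    if Z >= a + c * V:
        return "stop_efficacy"
    if Z <= -a + 3.0 * c * V:
        return "stop_futility"
    return "continue"


# ---------------------------------------------------------------------------
# trial-level dispatch
# ---------------------------------------------------------------------------


def _finite(values):
    return [v for v in values if v is not None and np.isfinite(v)]


def _accounting(data):
    n_active = sum(1 for r in data.records if r.any_active)
    periods = sum(r.active_periods for r in data.records)
    ae = int(sum(int(np.sum(r.ae)) for r in data.records))
    return n_active, periods, ae


def _result(data, design, effect, se, p, n_analyzed, warnings, significant=None):
    n_active, periods, ae = _accounting(data)
    if significant is None:
        significant = bool(np.isfinite(p) and p < design.alpha)
    return TrialResult(
        variant=data.variant,
        effect_estimate=float(effect) if effect is not None else float("nan"),
        standard_error=float(se) if se is not None else float("nan"),
        p_value=float(p) if p is not None else float("nan"),
        significant=significant,
        n_enrolled=data.n_enrolled,
        n_analyzed=n_analyzed,
        n_active_patients=n_active,
        active_patient_periods=periods,
        duration=data.duration,
        ae_count=ae,
        stop_reason=data.stop_reason,
        warnings=warnings,
    )


def _two_sample(data, design, group_a, group_b, method="t"):
    warnings = []
    a = _finite(group_a)
    b = _finite(group_b)
    n_analyzed = len(a) + len(b)
    if len(a) < 2 or len(b) < 2:
        warnings.append("degenerate: fewer than 2 analyzable endpoints in an arm")
        effect = (np.mean(a) if a else np.nan) - (np.mean(b) if b else np.nan)
        return _result(data, design, effect, np.nan, np.nan, n_analyzed, warnings, significant=False)
    if len(a) < 3 or len(b) < 3:
        warnings.append("underpowered: fewer than 3 analyzable endpoints in an arm")
    effect, se, t, df, p = welch_t(a, b, sided=design.sided)
    if np.var(a) == 0 and np.var(b) == 0:
        warnings.append("degenerate: zero variance in both arms")
        return _result(data, design, effect, se, np.nan, n_analyzed, warnings, significant=False)
    if method == "ranksum":
        p = rank_sum(a, b, sided=design.sided)
    return _result(data, design, effect, se, p, n_analyzed, warnings)


def _one_sample(data, design, diffs):
    warnings = []
    d = _finite(diffs)
    if len(d) < 2:
        warnings.append("degenerate: fewer than 2 analyzable within-patient differences")
        return _result(data, design, np.mean(d) if d else np.nan, np.nan, np.nan, len(d), warnings,
                       significant=False)
    if len(d) < 3:
        warnings.append("underpowered: fewer than 3 analyzable within-patient differences")
    effect, se, t, df, p = one_sample_t(d, sided=design.sided)
    if np.std(d) == 0:
        warnings.append("degenerate: zero variance in within-patient differences")
        return _result(data, design, effect, se, np.nan, len(d), warnings, significant=False)
    return _result(data, design, effect, se, p, len(d), warnings)


def _endpoints(data, arm):
    return [r.endpoint for r in data.records if r.arm == arm]


def _analyze_parallel_like(data, design, method="t"):
    return _two_sample(data, design, _endpoints(data, "active"), _endpoints(data, "control"), method)


def _analyze_factorial(data, design, method="t"):
    a_margin = [r.endpoint for r in data.records if r.meta.get("a_assigned")]
    not_a = [r.endpoint for r in data.records if not r.meta.get("a_assigned")]
    return _two_sample(data, design, a_margin, not_a, method)


def _analyze_placebo_phase(data, design, method="t"):
    delays = sorted(design.delay_arms)
    early = [r.endpoint for r in data.records if r.meta.get("delay") == delays[0]]
    late = [r.endpoint for r in data.records if r.meta.get("delay") == delays[1]]
    return _two_sample(data, design, early, late, method)


def _analyze_sequential(data, design, method="t"):
    warnings = []
    a = _finite(_endpoints(data, "active"))
    b = _finite(_endpoints(data, "control"))
    n_analyzed = len(a) + len(b)
    if len(a) >= 2 and len(b) >= 2:
        effect = np.mean(a) - np.mean(b)
        na, nb = len(a), len(b)
        s2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
        se = math.sqrt(s2 * (1 / na + 1 / nb)) if s2 > 0 else float("nan")
    else:
        effect, se = float("nan"), float("nan")
        warnings.append("degenerate: fewer than 2 analyzable endpoints in an arm")
    significant = data.stop_reason == "efficacy_stop"
    if data.stop_reason == "completed" and data.extras.get("interims"):
        warnings.append("reached maximum sample size without crossing a boundary")
    return _result(data, design, effect, se, np.nan, n_analyzed, warnings, significant=significant)


def _analyze_stepped_wedge(data, design, method="t"):
    import statsmodels.api as sm

    rows_y, rows_treat, rows_period, rows_patient = [], [], [], []
    for pi, rec in enumerate(data.records):
        T = len(rec.received_doses)
        for j in range(1, T + 1):
            if not rec.observed[j]:
                continue
            rows_y.append(rec.values[j])
            rows_treat.append(1.0 if rec.assigned_doses[j - 1] > 0 else 0.0)
            rows_period.append(j)
            rows_patient.append(pi)
    y = np.asarray(rows_y)
    n_obs = y.size
    warnings = []
    if n_obs < 10 or len(set(rows_treat)) < 2:
        warnings.append("degenerate: not enough observations for the stepped-wedge regression")
        return _result(data, design, np.nan, np.nan, np.nan, n_obs, warnings, significant=False)
    periods = sorted(set(rows_period))
    patients = sorted(set(rows_patient))
    X = np.zeros((n_obs, 1 + 1 + (len(periods) - 1) + (len(patients) - 1)))
    X[:, 0] = 1.0
    X[:, 1] = rows_treat
    pcol = {p: 2 + k for k, p in enumerate(periods[1:])}
    icol = {p: 2 + len(periods) - 1 + k for k, p in enumerate(patients[1:])}
    for r in range(n_obs):
        if rows_period[r] in pcol:
            X[r, pcol[rows_period[r]]] = 1.0
        if rows_patient[r] in icol:
            X[r, icol[rows_patient[r]]] = 1.0
    fit = sm.OLS(y, X).fit()
    effect, se = fit.params[1], fit.bse[1]
    if design.sided == 1:
        p = stats.t.sf(fit.tvalues[1], fit.df_resid)
    else:
        p = fit.pvalues[1]
    n_analyzed = len({rows_patient[r] for r in range(n_obs)})
    return _result(data, design, effect, se, p, n_analyzed, warnings)


_ANALYZERS = {
    "parallel": _analyze_parallel_like,
    "adaptive_rpw": _analyze_parallel_like,
    "randomized_withdrawal": _analyze_parallel_like,
    "early_escape": _analyze_parallel_like,
    "crossover": lambda data, design, method="t": _one_sample(data, design, [r.endpoint for r in data.records]),
    "factorial_2x2": _analyze_factorial,
    "n_of_1": lambda data, design, method="t": _one_sample(
        data, design, [r.endpoint for r in data.records]
    ),
    "sequential_triangular": _analyze_sequential,
    "placebo_phase": _analyze_placebo_phase,
    "stepped_wedge": _analyze_stepped_wedge,
}


def analyze_trial(data, design, method: str = "t") -> TrialResult:
    """Analyse one simulated trial with the design-matched test.

    ``method`` switches the two-sample comparison between Welch's t (``"t"``)
    and the rank-sum test (``"ranksum"``); one-sample and regression analyses
    ignore it.
    """
    if data.variant != design.variant:
        raise StructuralError(
            f"trial data from variant {data.variant!r} analysed with design {design.variant!r}"
        )
    return _ANALYZERS[data.variant](data, design, method=method)
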