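import math

import numpy as np
import pytest
from scipy import stats

from raretrials import (
    DesignSpec,
    StructuralError,
    analyze_trial,
    run_cell,
    triangular_boundaries,
    triangular_step,
)
from raretrials.designs import PatientRecord, TrialData


def toy_trial(variant, endpoints_by_arm, period_length=1.0, total_periods=6, extras=None):
    """Minimal TrialData carrying only arms and endpoints."""
    records = []
    i = 0
    for arm, endpoints in endpoints_by_arm.items():
        for e in endpoints:
            records.append(
                PatientRecord(
                    patient=None,
                    arm=arm,
                    enrolled_order=i,
                    assigned_doses=np.array([1.0 if arm == "active" else 0.0] * total_periods),
                    received_doses=np.array([1.0 if arm == "active" else 0.0] * total_periods),
                    values=np.zeros(total_periods + 1),
                    observed=np.ones(total_periods + 1, bool),
                    ae=np.zeros(total_periods, bool),
                    endpoint=float(e),
                )
            )
            i += 1
    return TrialData(variant, records, period_length, total_periods, extras=extras or {})


class TestWelchOracle:
    def test_parallel_toy_matches_hand_computation(self):
        # A = (1,2,3), B = (4,5,6): means 2 and 5, both variances 1
        # t = (2-5)/sqrt(1/3+1/3) = -3*sqrt(3/2); Welch df = (2/3)^2/(2*(1/9)) = 4
        data = toy_trial("parallel", {"active": [1, 2, 3], "control": [4, 5, 6]})
        res = analyze_trial(data, DesignSpec(variant="parallel"))
        t_hand = -3.0 / math.sqrt(2.0 / 3.0)
        p_hand = 2.0 * stats.t.sf(abs(t_hand), 4.0)
        assert res.effect_estimate == pytest.approx(-3.0, rel=1e-12)
        assert res.standard_error == pytest.approx(math.sqrt(2.0 / 3.0), rel=1e-12)
        assert res.p_value == pytest.approx(p_hand, rel=1e-10)
        assert res.significant == (p_hand < 0.05)

    def test_crossover_toy_matches_one_sample_hand_computation(self):
        # within-patient differences (1,2,3,4): mean 2.5, sd = sqrt(5/3), se = sd/2
        diffs = [1.0, 2.0, 3.0, 4.0]
        data = toy_trial("crossover", {"AB": diffs[:2], "BA": diffs[2:]})
        res = analyze_trial(data, DesignSpec(variant="crossover"))
        sd = math.sqrt(5.0 / 3.0)
        t_hand = 2.5 / (sd / 2.0)
        p_hand = 2.0 * stats.t.sf(abs(t_hand), 3)
        assert res.effect_estimate == pytest.approx(2.5, rel=1e-12)
        assert res.p_value == pytest.approx(p_hand, rel=1e-10)

    def test_zero_variance_degenerate_not_significant(self):
        data = toy_trial("parallel", {"active": [2, 2, 2], "control": [2, 2, 2]})
        res = analyze_trial(data, DesignSpec(variant="parallel"))
        assert res.effect_estimate == 0.0
        assert not res.significant
        assert math.isnan(res.p_value)
        assert any("degenerate" in w for w in res.warnings)

    def test_underpowered_arm_warned_but_analyzed(self):
        data = toy_trial("parallel", {"active": [1.0, 2.5], "control": [4, 5, 6]})
        res = analyze_trial(data, DesignSpec(variant="parallel"))
        assert any("underpowered" in w for w in res.warnings)
        assert np.isfinite(res.p_value)

    def test_variant_mismatch_rejected(self):
        data = toy_trial("parallel", {"active": [1, 2, 3], "control": [4, 5, 6]})
        with pytest.raises(StructuralError, match="variant"):
            analyze_trial(data, DesignSpec(variant="crossover"))

    def test_ranksum_option(self):
        data = toy_trial("parallel", {"active": [1, 2, 3, 4], "control": [5, 6, 7, 8]})
        res = analyze_trial(data, DesignSpec(variant="parallel"), method="ranksum")
        p_hand = stats.mannwhitneyu([1, 2, 3, 4], [5, 6, 7, 8], alternative="two-sided").pvalue
        assert res.p_value == pytest.approx(float(p_hand), rel=1e-10)


class TestTriangularTest:
    def test_origin_inside_triangle(self):
        assert triangular_step(0.0, 0.0, 1.0, 1.0) == "continue"
        assert triangular_step(0.999, 0.0, 1.0, 1.0) == "continue"

    def test_efficacy_boundary_inclusive(self):
        a, c = 2.0, 0.3
        V = 4.0
        assert triangular_step(a + c * V, V, a, c) == "stop_efficacy"
        assert triangular_step(a + c * V - 1e-9, V, a, c) == "continue"

    def test_futility_boundary_inclusive(self):
        a, c = 2.0, 0.3
        V = 4.0
        assert triangular_step(-a + 3 * c * V, V, a, c) == "stop_futility"
        assert triangular_step(-a + 3 * c * V + 1e-9, V, a, c) == "continue"

    def test_apex_zero_width_continuation(self):
        # boundaries meet where a + cV = -a + 3cV, i.e. V = a/c
        a, c = 2.0, 0.5
        V = a / c
        for z in (-10.0, 0.0, 2 * a - 1e-9, 2 * a, 2 * a + 1e-9, 10.0):
            assert triangular_step(z, V, a, c) != "continue"

    def test_negative_information_rejected(self):
        with pytest.raises(StructuralError, match="information"):
            triangular_step(0.0, -1.0, 1.0, 1.0)

    def test_boundary_constants_construction(self):
        a, c = triangular_boundaries(0.05, 1.2)
        assert a == pytest.approx(2 * math.log(10.0) / 1.2)
        assert c == pytest.approx(0.3)

    def test_drifted_walk_matches_path_simulation_oracle(self):
        # Brownian-increment score process with drift theta_R, group size dV;
        # oracle below applies the region inequalities directly.
        theta, alpha, dV = 1.0, 0.05, 1.5
        a, c = triangular_boundaries(alpha, theta)

        def walk(rng, use_impl):
            Z, V = 0.0, 0.0
            while True:
                V += dV
                Z += theta * dV + math.sqrt(dV) * rng.standard_normal()
                if use_impl:
                    d = triangular_step(Z, V, a, c)
                    if d != "continue":
                        return d == "stop_efficacy"
                else:
                    if Z >= a + c * V:
                        return True
                    if Z <= -a + 3 * c * V:
                        return False

        n = 2000
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(6)
        impl = sum(walk(rng1, True) for _ in range(n)) / n
        oracle = sum(walk(rng2, False) for _ in range(n)) / n
        se = math.sqrt(oracle * (1 - oracle) / n)
        assert abs(impl - oracle) < 4 * math.sqrt(2) * se


class TestSequentialAnalysis:
    def test_efficacy_stop_is_significant(self):
        data = toy_trial(
            "sequential_triangular",
            {"active": [5, 6, 7], "control": [1, 2, 3]},
            extras={"interims": [{"n": 6}]},
        )
        data.stop_reason = "efficacy_stop"
        res = analyze_trial(data, DesignSpec(variant="sequential_triangular", sided=1))
        assert res.significant
        assert res.stop_reason == "efficacy_stop"
        assert res.effect_estimate == pytest.approx(4.0)

    def test_futility_stop_not_significant(self):
        data = toy_trial("sequential_triangular", {"active": [1, 2, 3], "control": [1.5, 2.5, 3.5]})
        data.stop_reason = "futility_stop"
        res = analyze_trial(data, DesignSpec(variant="sequential_triangular", sided=1))
        assert not res.significant


class TestPValueUniformityUnderNull:
    def test_parallel_and_crossover_null_p_uniform(self, null_scenario):
        for variant in ("parallel", "crossover"):
            design = DesignSpec(variant=variant, n_patients=50)
            _, results = run_cell(
                null_scenario, design, 2000, seed=314, collect_results=True
            )
            p = np.array([r.p_value for r in results])
            p = p[np.isfinite(p)]
            ks = stats.kstest(p, "uniform")
            assert ks.pvalue > 0.01, f"{variant}: KS p={ks.pvalue}"
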