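import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raretrials import (
    ConfigurationError,
    DesignSpec,
    RecruitmentError,
    RPWUrn,
    generate_population,
    permuted_block_allocation,
    run_trial,
    sample_cohort,
    trial_to_frame,
)


def cohort_of(scenario, n, seed=5):
    pop = generate_population(scenario.population, seed=seed)
    return sample_cohort(pop, n, seed=seed + 1)


class TestPermutedBlocks:
    def test_single_complete_block(self):
        arms = permuted_block_allocation(4, 2, 4, seed=1)
        assert sorted(arms) == [0, 0, 1, 1]

    def test_partial_final_block_outcomes(self):
        # 50 = 12 blocks of 4 + partial block of 2 -> 25/25 or 26/24
        counts = set()
        for s in range(50):
            arms = permuted_block_allocation(50, 2, 4, seed=s)
            counts.add(tuple(sorted(np.bincount(arms, minlength=2))))
        assert counts <= {(25, 25), (24, 26)}
        assert len(counts) == 2  # both outcomes occur

    def test_three_arms_complete_blocks(self):
        arms = permuted_block_allocation(6, 3, 3, seed=2)
        assert list(np.bincount(arms, minlength=3)) == [2, 2, 2]

    def test_indivisible_block_size_rejected(self):
        with pytest.raises(ConfigurationError, match="block_size"):
            permuted_block_allocation(10, 3, 4, seed=1)

    @settings(derandomize=True, max_examples=40)
    @given(
        n=st.integers(1, 60),
        n_arms=st.integers(2, 4),
        mult=st.integers(1, 3),
        seed=st.integers(0, 1000),
    )
    def test_running_imbalance_bounded(self, n, n_arms, mult, seed):
        block = n_arms * mult
        arms = permuted_block_allocation(n, n_arms, block, seed=seed)
        assert arms.size == n
        running = np.zeros(n_arms)
        for a in arms:
            running[a] += 1
            assert running.max() - running.min() <= block / 2
        # complete blocks are exactly balanced
        for b in range(n // block):
            chunk = arms[b * block : (b + 1) * block]
            assert list(np.bincount(chunk, minlength=n_arms)) == [mult] * n_arms


class TestStructuralContracts:
    def test_parallel_one_arm_throughout(self, cf_scenario):
        design = DesignSpec(variant="parallel", n_patients=50)
        data = run_trial(design, cohort_of(cf_scenario, 50), cf_scenario, seed=1)
        arms = [r.arm for r in data.records]
        assert sorted(np.unique(arms)) == ["active", "control"]
        counts = (arms.count("active"), arms.count("control"))
        assert counts in {(25, 25), (26, 24), (24, 26)}
        for r in data.records:
            on = r.assigned_doses > 0
            assert on.all() or (~on).all()

    def test_crossover_both_treatments_block_balanced(self, cf_scenario):
        design = DesignSpec(variant="crossover", n_patients=50, n_periods=6, washout_periods=1)
        data = run_trial(design, cohort_of(cf_scenario, 50), cf_scenario, seed=2)
        arms = [r.arm for r in data.records]
        assert arms.count("AB") == 25 and arms.count("BA") == 25  # n even, block-balanced
        for r in data.records:
            phase1 = r.assigned_doses[:6]
            phase2 = r.assigned_doses[7:]
            washout = r.assigned_doses[6:7]
            assert (phase1 > 0).all() != (phase2 > 0).all()  # exactly one active phase
            assert washout == 0.0
        assert data.total_periods == 13

    def test_factorial_four_cells(self, cf_scenario):
        design = DesignSpec(variant="factorial_2x2", n_patients=48, block_size=4)
        data = run_trial(design, cohort_of(cf_scenario, 48), cf_scenario, seed=3)
        from collections import Counter

        counts = Counter(r.arm for r in data.records)
        assert counts == {"placebo": 12, "a_only": 12, "b_only": 12, "ab": 12}

    def test_withdrawal_vacuous_threshold_randomizes_everyone(self, clean_scenario):
        design = DesignSpec(
            variant="randomized_withdrawal", n_patients=50, responder_threshold=-1e9
        )
        data = run_trial(design, cohort_of(clean_scenario, 50), clean_scenario, seed=4)
        arms = [r.arm for r in data.records]
        assert "runin_only" not in arms
        assert arms.count("active") + arms.count("control") == 50
        for r in data.records:  # everyone got the active run-in
            assert (r.received_doses[:4] > 0).all()

    def test_withdrawal_too_few_responders_is_recruitment_failure(self, clean_scenario):
        design = DesignSpec(variant="randomized_withdrawal", n_patients=50, responder_threshold=1e9)
        with pytest.raises(RecruitmentError, match="responders"):
            run_trial(design, cohort_of(clean_scenario, 50), clean_scenario, seed=5)

    def test_early_escape_removes_nonresponders_at_decision_point(self, null_scenario):
        design = DesignSpec(variant="early_escape", escape_period=3, escape_threshold=1e9)
        data = run_trial(design, cohort_of(null_scenario, 50), null_scenario, seed=6)
        escaped = [r for r in data.records if r.meta.get("escaped")]
        assert len(escaped) > 40  # impossible threshold: all non-dropouts escape
        for r in escaped:
            assert not r.observed[4:].any()
            assert (r.received_doses[3:] == 0).all()

    def test_n_of_1_pairs_contain_both_treatments(self, cf_scenario):
        design = DesignSpec(variant="n_of_1", n_patients=8, n_cycles=3, washout_periods=1)
        data = run_trial(design, cohort_of(cf_scenario, 8), cf_scenario, seed=7)
        assert len(data.records) == 8
        for r in data.records:
            active_periods = np.flatnonzero(r.assigned_doses > 0)
            assert active_periods.size == 3  # one active period per cycle
        # 3 cycles of (2 treatment periods + washouts between periods)
        assert data.total_periods == 3 * 2 + 5 * 1

    def test_sequential_never_exceeds_max_sample_size(self, cf_scenario):
        design = DesignSpec(variant="sequential_triangular", n_patients=50, interim_spacing=10, sided=1)
        for seed in range(5):
            data = run_trial(design, cohort_of(cf_scenario, 50), cf_scenario, seed=seed)
            assert data.n_enrolled <= 50
            assert data.n_enrolled in {10, 20, 30, 40, 50}
            assert data.stop_reason in {"completed", "efficacy_stop", "futility_stop"}

    def test_placebo_phase_all_completers_end_on_active(self, clean_scenario):
        design = DesignSpec(variant="placebo_phase", n_patients=50, delay_arms=(0, 3))
        data = run_trial(design, cohort_of(clean_scenario, 50), clean_scenario, seed=8)
        for r in data.records:
            assert r.assigned_doses[-1] > 0
            if r.dropout_period is None:
                assert r.received_doses[-1] > 0

    def test_stepped_wedge_all_cross_to_active(self, clean_scenario):
        design = DesignSpec(variant="stepped_wedge", n_patients=50, n_steps=5)
        data = run_trial(design, cohort_of(clean_scenario, 50), clean_scenario, seed=9)
        steps = {r.meta["step"] for r in data.records}
        assert steps == {1, 2, 3, 4, 5}
        for r in data.records:
            s = r.meta["step"]
            assert (r.assigned_doses[:s] == 0).all()
            assert (r.assigned_doses[s:] > 0).all()
            if r.dropout_period is None:
                assert r.received_doses[-1] > 0

    def test_conservation_enrolled_completed_dropped(self, cf_scenario):
        design = DesignSpec(variant="parallel", n_patients=50)
        data = run_trial(design, cohort_of(cf_scenario, 50), cf_scenario, seed=10)
        completed = sum(r.dropout_period is None for r in data.records)
        dropped = sum(r.dropout_period is not None for r in data.records)
        assert completed + dropped == data.n_enrolled == 50

    def test_cohort_too_small_raises(self, cf_scenario):
        design = DesignSpec(variant="parallel", n_patients=50)
        with pytest.raises(RecruitmentError, match="50"):
            run_trial(design, cohort_of(cf_scenario, 20), cf_scenario, seed=1)

    def test_reproducible_under_seed(self, cf_scenario):
        design = DesignSpec(variant="crossover", n_patients=20, block_size=4)
        cohort = cohort_of(cf_scenario, 20)
        a = run_trial(design, cohort, cf_scenario, seed=11)
        b = run_trial(design, cohort, cf_scenario, seed=11)
        for ra, rb in zip(a.records, b.records):
            assert ra.arm == rb.arm
            assert np.array_equal(ra.values, rb.values)
            assert np.array_equal(ra.observed, rb.observed)

    def test_trial_frame_export(self, cf_scenario):
        design = DesignSpec(variant="parallel", n_patients=10, n_periods=4)
        data = run_trial(design, cohort_of(cf_scenario, 10), cf_scenario, seed=12)
        df = trial_to_frame(data, "t1")
        assert len(df) == 10 * 4
        assert set(df["arm"]) == {"active", "control"}


class TestRPWUrn:
    def test_equal_failure_rates_stay_balanced(self):
        rng = np.random.default_rng(1)
        fractions = []
        for _ in range(40):
            urn = RPWUrn(1, 1)
            n_active = 0
            for _ in range(500):
                arm = urn.draw(rng)
                n_active += arm == 0
                urn.update(arm, rng.random() < 0.5)
            fractions.append(n_active / 500)
        assert abs(np.mean(fractions) - 0.5) < 0.03  # symmetry

    def test_perfect_drug_allocation_grows_with_n(self):
        # active always succeeds, control always fails -> fraction -> 1
        rng = np.random.default_rng(2)

        def fraction(n):
            urn = RPWUrn(1, 1)
            count = 0
            for _ in range(n):
                arm = urn.draw(rng)
                count += arm == 0
                urn.update(arm, arm == 0)
            return count / n

        f_small, f_large = fraction(50), fraction(2000)
        assert f_small > 0.5
        assert f_large > f_small

    def test_urn_validation(self):
        with pytest.raises(ConfigurationError):
            RPWUrn(0, 1)
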