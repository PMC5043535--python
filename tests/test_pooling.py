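import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import strokecap as sc
from strokecap.engine import OccupancyAudit
from tests.conftest import product_poisson_joint, single_class_config, two_stream_config
from strokecap.config import LOSModel


def audit(counts, rep_id=0, ward="acute"):
    return OccupancyAudit(rep_id=rep_id, ward=ward, counts=np.asarray(counts))


class TestJointPMF:
    def test_point_mass(self):
        joint = sc.joint_occupancy_pmf([audit([1])], [audit([2], ward="rehab")])
        assert joint.probabilities == {(1, 2): 1.0}

    def test_marginals_match_single_ward_pmfs(self, default_run):
        _, coll = default_run
        joint = sc.joint_occupancy_pmf(coll["acute"], coll["rehab"])
        for ward in ("acute", "rehab"):
            single = sc.occupancy_pmf(coll[ward]).p
            marg = joint.marginal(ward)
            assert marg[: single.size] == pytest.approx(single, abs=1e-12)

    def test_misaligned_audits_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            sc.joint_occupancy_pmf(
                [audit([1, 2], rep_id=0)], [audit([1], rep_id=0, ward="rehab")]
            )
        with pytest.raises(ValueError):
            sc.joint_occupancy_pmf(
                [audit([1], rep_id=0)], [audit([1], rep_id=1, ward="rehab")]
            )

    def test_independent_streams_product_form(self):
        """In the unconstrained pathway the two wards' occupancies are
        independent Poisson, so the joint PMF factorises."""
        cfg = two_stream_config(1.0, 1.0, 3.0, 3.0)
        spec = sc.RunSpec(warmup=60.0, run_length=1500.0, n_reps=20, base_seed=41)
        coll = sc.run_experiment(cfg, spec)
        joint = sc.joint_occupancy_pmf(coll["acute"], coll["rehab"])
        prod = np.outer(joint.marginal("acute"), joint.marginal("rehab"))
        assert np.abs(joint.p - prod).max() < 0.01


class TestPartialPoolDelay:
    def test_reduces_to_single_ward_formula(self):
        """With all beds dedicated to acute and rehab empty, the feasible-state
        truncation is exactly P(N=c)/P(N<=c)."""
        pmf = sc.poisson_pmf(8.5)
        grid = np.zeros((pmf.p.size, 1))
        grid[:, 0] = pmf.p
        joint = sc.JointOccupancyPMF(grid, 0)
        for c in range(1, 16):
            res = sc.partial_pool_delay(joint, sc.BedPlan(c, 0, 0))
            assert res.p_delay_acute == pytest.approx(
                sc.prob_delay(pmf, c), abs=1e-12
            )

    def test_full_pooling_reduces_to_summed_occupancy(self):
        joint = product_poisson_joint(3.0, 4.0)
        total = 9
        res = sc.partial_pool_delay(joint, sc.BedPlan(0, 0, total))
        summed = sc.poisson_pmf(7.0)
        expected = sc.prob_delay(summed, total)
        assert res.p_delay_acute == pytest.approx(expected, abs=1e-9)
        assert res.p_delay_rehab == pytest.approx(res.p_delay_acute, abs=1e-12)

    def test_degenerate_plan_rejected(self):
        joint = product_poisson_joint(1.0, 1.0)
        with pytest.raises(ValueError):
            sc.partial_pool_delay(joint, sc.BedPlan(0, 0, 0))

    def test_no_feasible_state_rejected(self):
        grid = np.zeros((6, 6))
        grid[5, 5] = 1.0
        joint = sc.JointOccupancyPMF(grid, 1)
        with pytest.raises(ValueError, match="feasible"):
            sc.partial_pool_delay(joint, sc.BedPlan(1, 1, 0))

    def test_exact_small_system(self):
        """Unit loads with plan 1/1/1: hand enumeration of the 8 feasible
        states gives p(delay) = 0.25 for both streams."""
        joint = product_poisson_joint(1.0, 1.0)
        res = sc.partial_pool_delay(joint, sc.BedPlan(1, 1, 1))
        assert res.p_delay_acute == pytest.approx(0.25, abs=1e-9)
        assert res.p_delay_rehab == pytest.approx(0.25, abs=1e-9)

    @given(
        da=st.integers(0, 4), dr=st.integers(0, 4), pool=st.integers(0, 4),
        a=st.floats(0.5, 4.0), r=st.floats(0.5, 4.0),
    )
    @settings(derandomize=True, max_examples=40)
    def test_probabilities_always_valid(self, da, dr, pool, a, r):
        if da + dr + pool == 0:
            return
        joint = product_poisson_joint(a, r)
        res = sc.partial_pool_delay(joint, sc.BedPlan(da, dr, pool))
        assert 0.0 <= res.p_delay_acute <= 1.0
        assert 0.0 <= res.p_delay_rehab <= 1.0


class TestFiniteCapacityOracle:
    def test_zero_arrivals(self):
        cfg = two_stream_config(1.0, 1.0, 2.0, 2.0)
        for c in cfg.classes:
            c.interarrival_mean = 1e12
        res = sc.finite_capacity_oracle(cfg, sc.BedPlan(1, 1, 1), 200.0, seed=1)
        assert res.p_delay_acute == 0.0
        assert res.p_delay_rehab == 0.0

    def test_same_seed_identical(self):
        cfg = two_stream_config(0.8, 0.6, 2.0, 3.0)
        a = sc.finite_capacity_oracle(cfg, sc.BedPlan(2, 1, 1), 2000.0, seed=3)
        b = sc.finite_capacity_oracle(cfg, sc.BedPlan(2, 1, 1), 2000.0, seed=3)
        assert a.p_delay_acute == b.p_delay_acute
        assert a.p_delay_rehab == b.p_delay_rehab

    def test_single_stream_matches_erlang_b(self):
        """A lone Poisson stream with exponential stays and c beds is the
        classical Erlang loss system."""
        cfg = single_class_config(1.0, LOSModel("exponential", {"mean": 3.0}))
        ps = [
            sc.finite_capacity_oracle(
                cfg, sc.BedPlan(4, 0, 0), 4100.0, seed=5, warmup=100.0, rep_id=r
            ).p_delay_acute
            for r in range(12)
        ]
        ps = np.array(ps)
        se = ps.std(ddof=1) / np.sqrt(ps.size)
        assert abs(ps.mean() - sc.erlang_b(3.0, 4)) < 3.5 * se

    def test_sticky_assignment_blocks_at_least_as_often(self):
        cfg = two_stream_config(0.5, 0.5, 2.0, 2.0)
        plan = sc.BedPlan(1, 1, 1)
        repack = sc.finite_capacity_oracle(cfg, plan, 20000.0, seed=7, warmup=100.0)
        sticky = sc.finite_capacity_oracle(
            cfg, plan, 20000.0, seed=7, warmup=100.0, repack=False
        )
        assert (
            sticky.p_delay_acute + sticky.p_delay_rehab
            >= repack.p_delay_acute + repack.p_delay_rehab
        )

    def test_formula_matches_oracle_small_instance(self):
        """The feasible-state truncation agrees with the simulated loss system
        on the exact small instance (exponential stays, unit loads, 1/1/1)."""
        cfg = two_stream_config(0.5, 0.5, 2.0, 2.0)
        plan = sc.BedPlan(1, 1, 1)
        exact = sc.partial_pool_delay(product_poisson_joint(1.0, 1.0), plan)
        ps = np.array(
            [
                [r.p_delay_acute, r.p_delay_rehab]
                for r in (
                    sc.finite_capacity_oracle(
                        cfg, plan, 2100.0, seed=8, warmup=100.0, rep_id=i
                    )
                    for i in range(12)
                )
            ]
        )
        se = ps.std(axis=0, ddof=1) / np.sqrt(ps.shape[0])
        assert abs(ps[:, 0].mean() - exact.p_delay_acute) < 3.5 * se[0]
        assert abs(ps[:, 1].mean() - exact.p_delay_rehab) < 3.5 * se[1]

    def test_pooling_bed_pairs_never_hurts_worst_stream(self):
        """Moving one bed from *each* ward into the pool does not increase the
        worse of the two delay probabilities (checked on exact truncations).
        Moving a single bed can transiently hurt the donating stream, so the
        property is stated for balanced bed pairs."""
        for a, r in [(1.0, 1.0), (2.0, 1.5), (3.0, 3.0)]:
            joint = product_poisson_joint(a, r)
            plans = [sc.BedPlan(3, 3, 0), sc.BedPlan(2, 2, 2), sc.BedPlan(1, 1, 4)]
            worst = [
                max(res.p_delay_acute, res.p_delay_rehab)
                for res in (sc.partial_pool_delay(joint, p) for p in plans)
            ]
            assert all(b <= a_ + 1e-12 for a_, b in zip(worst, worst[1:]))
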