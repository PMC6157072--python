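"""Decoder behaviour: integerization, mate allocation, repair, totality."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import matekit as mk
from matekit.data import RoleLimits
from matekit.encoding import (
    allocate_mates_gendered,
    allocate_mates_generic,
    chromosome_dim,
    decode,
    integerize_contributions,
    repair_selfing,
    validate_constraints,
)
from matekit.synthetic import enumerate_valid_plans, random_tiny_problem

from _checker import check_plan


class TestIntegerize:
    def test_largest_remainder_example(self):
        # shares (1.5, 1.0, 0.5): exhaustive check of all integer vectors
        # summing to 3 confirms (2, 1, 0) is the largest-remainder result
        counts, v = integerize_contributions(np.array([3.0, 2.0, 1.0]), RoleLimits(3, 0, 4), 3)
        assert counts.tolist() == [2, 1, 0] and v == 0

    def test_equal_contributions_forced(self):
        counts, v = integerize_contributions(
            np.array([0.9, 0.5, 0.4, 0.1]), RoleLimits(None, 1, 1), 3
        )
        assert counts.tolist() == [1, 1, 1, 0] and v == 0

    def test_all_nonpositive_uniform_with_index_ties(self):
        counts, v = integerize_contributions(
            np.array([-1.0, -1.0, -1.0, -1.0]), RoleLimits(2, 0, None), 2
        )
        assert counts.tolist() == [1, 1, 0, 0] and v == 0

    def test_sum_always_exact(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 8))
            slots = int(rng.integers(1, 9))
            maxc = int(rng.integers(1, 5))
            lim = RoleLimits(None, 0, maxc)
            counts, _ = integerize_contributions(rng.normal(size=n), lim, slots)
            assert counts.sum() == slots


class TestAllocation:
    def test_identity_permutation(self):
        m = allocate_mates_gendered(np.array([2, 0]), np.array([1, 1]), np.array([0.1, 0.9]))
        assert m.tolist() == [[0, 0], [0, 1]]

    def test_swapped_permutation(self):
        m = allocate_mates_gendered(np.array([2, 0]), np.array([1, 1]), np.array([0.9, 0.1]))
        assert m.tolist() == [[0, 1], [0, 0]]

    def test_generic_single_forced_mating(self):
        m = allocate_mates_generic(np.array([1, 1]), np.array([0.3, 0.8]))
        assert sorted(m.ravel().tolist()) == [0, 1]

    def test_plan_depends_on_keys_only_through_argsort(self, rng):
        genes = rng.normal(size=6)
        m1 = allocate_mates_generic(np.array([2, 2, 1, 1]), genes)
        m2 = allocate_mates_generic(np.array([2, 2, 1, 1]), genes * 100.0 + 5.0)
        assert np.array_equal(m1, m2)


class TestSelfingRepair:
    def test_swap_removes_selfing(self):
        m, v = repair_selfing(np.array([[0, 0], [1, 2]]), False)
        assert v == 0
        assert all(a != b for a, b in m)

    def test_irreparable_selfing_counted(self):
        m, v = repair_selfing(np.array([[0, 0]]), False)
        assert v == 1 and m.tolist() == [[0, 0]]

    def test_allowed_selfing_untouched(self):
        m, v = repair_selfing(np.array([[0, 0], [1, 2]]), True)
        assert v == 0 and m.tolist() == [[0, 0], [1, 2]]


class TestDecode:
    def test_worked_micro_case(self):
        cand = mk.CandidateSet(
            ["M1", "M2", "F1", "F2"], gender=[1, 1, 2, 2], criterion=[1.0, 2.0, 3.0, 4.0]
        )
        cons = mk.MatingConstraints.gendered(
            2, male=RoleLimits(None, 0, 2), female=RoleLimits(None, 0, 2)
        )
        plan = decode(np.array([1.0, 0.2, 0.3, 0.7, 0.6, 0.4]), cand, cons)
        assert plan.n_contrib.tolist() == [2, 0, 1, 1]
        # male M1 in both matings; F2 (higher gene) first by key order
        assert plan.matings.tolist() == [[0, 3], [0, 2]]
        assert plan.violations == 0

    def test_monotone_gene_transform_preserves_plan(self, rng):
        cand = mk.CandidateSet([f"c{i}" for i in range(5)])
        cons = mk.MatingConstraints.generic(3, max_contrib=3)
        z = rng.random(chromosome_dim(cand, cons))
        p1 = decode(z, cand, cons)
        z2 = z.copy()
        z2[:5] = z[:5] * 3.0 + 0.0  # positive affine with zero shift keeps ranks & positivity
        p2 = decode(z2, cand, cons)
        assert np.array_equal(p1.matings, p2.matings)
        assert np.array_equal(p1.n_contrib, p2.n_contrib)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=11, max_size=11),
           st.booleans())
    def test_decoder_totality(self, genes, selfing):
        """Any real chromosome decodes to a plan with exact per-role sums."""
        cand = mk.CandidateSet([f"c{i}" for i in range(5)])
        cons = mk.MatingConstraints.generic(3, max_contrib=2, allow_selfing=selfing)
        plan = decode(np.array(genes[:11]), cand, cons)
        assert plan.n_contrib.sum() == 6
        assert plan.x.sum() == pytest.approx(1.0)
        assert plan.matings.shape == (3, 2)

    def test_violations_zero_iff_plan_checks_out(self, rng):
        """Decoder violation accounting agrees with the independent checker."""
        for k in range(300):
            prob = random_tiny_problem(rng)
            z = rng.normal(size=prob.dim)
            plan = prob.decode(z)
            errs = check_plan(plan, prob.constraints, prob.candidates)
            assert (plan.violations == 0) == (not errs), (errs, plan.violations)

    def test_decoded_plans_within_bruteforce_image(self, rng):
        """Valid decoded plans always appear in the exhaustive enumeration."""
        prob = random_tiny_problem(rng, gendered=False)
        valid = set()
        for p in enumerate_valid_plans(prob):
            valid.add((tuple(p.n_contrib), tuple(sorted(map(tuple, np.sort(p.matings, axis=1))))))
        for _ in range(2000):
            plan = prob.decode(rng.normal(size=prob.dim))
            if plan.violations == 0:
                key = (tuple(plan.n_contrib),
                       tuple(sorted(map(tuple, np.sort(plan.matings, axis=1)))))
                assert key in valid


class TestValidate:
    def test_feasible_pool(self):
        cand = mk.CandidateSet([f"c{i}" for i in range(8)], criterion=np.arange(8.0))
        cons = mk.MatingConstraints.generic(16, max_parents=8, max_contrib=4)
        assert validate_constraints(cons, cand) == []

    def test_indivisible_equal_contributions(self):
        # five matings cannot be split into equal contributions of two
        cand = mk.CandidateSet([f"c{i}" for i in range(6)],
                               gender=[1, 2, 1, 2, 1, 2])
        cons = mk.MatingConstraints.gendered(
            5, male=RoleLimits(None, 2, 2), female=RoleLimits(None, 2, 2)
        )
        assert any("divide" in e for e in validate_constraints(cons, cand))

    def test_gendered_without_females(self):
        cand = mk.CandidateSet(["a", "b"], gender=[1, 1])
        cons = mk.MatingConstraints.gendered(2)
        assert any("female" in e for e in validate_constraints(cons, cand))

    def test_insufficient_capacity(self):
        cand = mk.CandidateSet(["a", "b"])
        cons = mk.MatingConstraints.generic(4, max_contrib=1)
        assert validate_constraints(cons, cand)
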