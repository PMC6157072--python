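"""Bound finding, epsilon-constraint target solves and Pareto sweeps."""

import numpy as np
import pytest

import matekit as mk
from matekit.evolver import DEConfig
from matekit.frontier import FrontierPoint, find_bounds, pareto_filter, solve_target, sweep_frontier
from matekit.objectives import TargetSpec, resolve_coancestry_target
from matekit.synthetic import brute_force_optimum, oracle_bounds, random_tiny_problem


def _cfg(seed=1):
    return DEConfig(pop_size=30, iterations=300, window=60, seed=seed)


def _plain_point(gain, coa, deg=0.0):
    return FrontierPoint(degrees=deg, gain=gain, coancestry=coa, inbreeding=0.0,
                         gain_norm=0.0, coancestry_norm=0.0, plan=None)


class TestBounds:
    def test_unrelated_max_one_contribution_closed_form(self, four_unrelated):
        """4 unrelated parents, one slot each: any plan has coancestry 1/8."""
        cand, C = four_unrelated
        cons = mk.MatingConstraints.generic(2, max_contrib=1, allow_selfing=False)
        prob = mk.MatingProblem(cand, C, cons)
        bounds, _ = find_bounds(prob, _cfg())
        assert bounds.c_min == pytest.approx(0.125, abs=1e-12)
        assert bounds.c_at_gmax == pytest.approx(0.125, abs=1e-12)

    def test_min_coancestry_avoids_sib_concentration(self, sib_structure):
        """With full sibs in the pool, the optimum beats the sibs-only plan."""
        cand, C = sib_structure
        cons = mk.MatingConstraints.generic(2, max_contrib=2, allow_selfing=False)
        prob = mk.MatingProblem(cand, C, cons)
        bounds, _ = find_bounds(prob, _cfg(5))
        sibs_only = np.array([0.5, 0.5, 0.0, 0.0])
        sib_coa = float(sibs_only @ C.values @ sibs_only)
        neg, _ = brute_force_optimum(prob, "min_coancestry")
        assert bounds.c_min == pytest.approx(-neg, abs=1e-9)
        assert bounds.c_min < sib_coa - 1e-9


class TestSolveTarget:
    def test_extreme_degrees_recover_bound_solutions(self, sib_structure):
        cand, C = sib_structure
        cons = mk.MatingConstraints.generic(2, max_contrib=2, allow_selfing=False)
        prob = mk.MatingProblem(cand, C, cons)
        bounds, _ = find_bounds(prob, _cfg(2))
        span = max(bounds.span, 1e-12)
        p0 = solve_target(prob, TargetSpec("degrees", 0.0), _cfg(3), bounds)
        p90 = solve_target(prob, TargetSpec("degrees", 90.0), _cfg(4), bounds)
        assert p0.gain == pytest.approx(bounds.g_max, abs=1e-9)
        assert p90.coancestry <= bounds.c_min + 1e-6 * span

    def test_mid_target_matches_bruteforce(self, rng):
        """At 45 degrees the solve equals the constrained enumeration optimum."""
        prob = random_tiny_problem(rng, gendered=False)
        b = oracle_bounds(prob)
        c45 = resolve_coancestry_target(TargetSpec("degrees", 45.0), b.c_min, b.c_at_gmax)
        best, _ = brute_force_optimum(prob, "target", c45, b.span)
        point = solve_target(prob, TargetSpec("degrees", 45.0), _cfg(6), b)
        achieved, _ = mk.objectives.penalized_objective(
            point.gain, point.coancestry, point.inbreeding, point.plan.violations,
            mode="target", n_matings=prob.constraints.n_matings,
            penalty_weight=prob.penalty_weight,
            target_coancestry=c45, span=b.span,
        )
        assert achieved == pytest.approx(best, abs=1e-9)


class TestSweep:
    def test_two_steps_are_exactly_the_bounds(self, sib_structure):
        cand, C = sib_structure
        cons = mk.MatingConstraints.generic(2, max_contrib=2, allow_selfing=False)
        prob = mk.MatingProblem(cand, C, cons)
        bounds, _ = find_bounds(prob, _cfg(8))
        pts = sweep_frontier(prob, 2, _cfg(8))
        assert len(pts) == 2
        assert pts[0].degrees == 0.0 and pts[1].degrees == 90.0
        assert pts[0].gain == pytest.approx(bounds.g_max, abs=1e-9)
        assert pts[1].coancestry == pytest.approx(bounds.c_min, abs=1e-9)

    def test_coancestry_nonincreasing_in_degrees(self, rng):
        prob = random_tiny_problem(rng, gendered=False)
        pts = sweep_frontier(prob, 5, _cfg(9))
        coas = [p.coancestry for p in pts]
        assert all(a >= b - 1e-9 for a, b in zip(coas, coas[1:]))


class TestParetoFilter:
    def test_dominated_point_removed(self):
        pts = [_plain_point(1.0, 0.2, 0.0), _plain_point(0.9, 0.25, 45.0)]
        kept = pareto_filter(pts)
        assert len(kept) == 1 and kept[0].gain == 1.0

    def test_single_point_unchanged(self):
        pts = [_plain_point(1.0, 0.2)]
        assert pareto_filter(pts) == pts

    def test_duplicates_keep_first_by_degrees(self):
        pts = [_plain_point(1.0, 0.2, 30.0), _plain_point(1.0, 0.2, 60.0)]
        kept = pareto_filter(pts)
        assert len(kept) == 1 and kept[0].degrees == 30.0

    def test_filtered_frontier_monotone(self, rng):
        pts = [_plain_point(g, c) for g, c in rng.random((20, 2))]
        kept = sorted(pareto_filter(pts), key=lambda p: p.coancestry)
        gains = [p.gain for p in kept]
        assert all(b >= a - 1e-12 for a, b in zip(gains, gains[1:]))
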