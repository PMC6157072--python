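"""Objective functions, target-form resolution and penalized scalarization."""

import numpy as np
import pytest

from matekit.objectives import (
    TargetSpec,
    genetic_gain,
    group_coancestry,
    mean_progeny_inbreeding,
    penalized_objective,
    resolve_coancestry_target,
    standardize_criterion,
)


class TestStandardize:
    def test_closed_form(self):
        np.testing.assert_allclose(
            standardize_criterion([1.0, 2.0, 3.0]), [-1.2247, 0.0, 1.2247], atol=1e-4
        )

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize_criterion([5.0, 5.0])

    def test_idempotent(self, rng):
        a = rng.normal(size=20)
        once = standardize_criterion(a)
        np.testing.assert_allclose(standardize_criterion(once), once, atol=1e-12)


class TestGainAndCoancestry:
    def test_single_contributor_gain(self):
        a = standardize_criterion([1.0, 2.0, 3.0])[::-1]
        assert genetic_gain(np.array([1.0, 0, 0]), a) == pytest.approx(1.2247, abs=1e-4)

    def test_uniform_contributions_zero_gain(self, rng):
        a = standardize_criterion(rng.normal(size=8))
        assert genetic_gain(np.full(8, 1 / 8), a) == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_contributors(self):
        a = np.array([1.2247, 0.0, -1.2247])
        assert genetic_gain(np.array([0.5, 0.5, 0.0]), a) == pytest.approx(0.6124, abs=1e-4)

    def test_group_coancestry_two_unrelated(self):
        C = np.eye(2) * 0.5
        assert group_coancestry(np.array([0.5, 0.5]), C) == 0.25

    def test_group_coancestry_n_unrelated_uniform(self):
        n = 10
        C = np.eye(n) * 0.5
        assert group_coancestry(np.full(n, 1 / n), C) == pytest.approx(0.05, abs=1e-15)

    def test_single_lineage(self):
        C = np.eye(2) * 0.5
        assert group_coancestry(np.array([1.0, 0.0]), C) == 0.5

    def test_uniform_equals_matrix_mean(self, rng):
        V = rng.random((5, 5))
        C = (V + V.T) / 2
        x = np.full(5, 0.2)
        assert group_coancestry(x, C) == pytest.approx(C.mean(), abs=1e-12)


class TestProgenyInbreeding:
    C = np.array([[0.5, 0.0, 0.25], [0.0, 0.5, 0.0], [0.25, 0.0, 0.5]])

    def test_unrelated_parents(self):
        assert mean_progeny_inbreeding(np.array([[0, 1]]), self.C) == 0.0

    def test_related_parents(self):
        assert mean_progeny_inbreeding(np.array([[0, 2]]), self.C) == 0.25

    def test_mean_over_matings(self):
        assert mean_progeny_inbreeding(np.array([[0, 1], [0, 2]]), self.C) == 0.125

    def test_selfing_contributes_self_coancestry(self):
        assert mean_progeny_inbreeding(np.array([[1, 1]]), self.C) == 0.5

    def test_varies_with_pairing_while_group_coancestry_fixed(self):
        # same contributions, different mate allocation
        x = np.array([2, 1, 1]) / 4.0
        a = mean_progeny_inbreeding(np.array([[0, 1], [0, 2]]), self.C)
        b = mean_progeny_inbreeding(np.array([[0, 2], [0, 1]]), self.C)
        assert a == b  # permuting mating order changes nothing
        c = mean_progeny_inbreeding(np.array([[0, 0], [1, 2]]), self.C)
        assert c != a
        assert group_coancestry(x, self.C) == group_coancestry(x, self.C)


class TestTargetResolution:
    def test_degree_endpoints(self):
        t90 = resolve_coancestry_target(TargetSpec("degrees", 90.0), 0.1, 0.3)
        t0 = resolve_coancestry_target(TargetSpec("degrees", 0.0), 0.1, 0.3)
        assert t90 == pytest.approx(0.1, abs=1e-12)
        assert t0 == pytest.approx(0.3, abs=1e-12)

    def test_rate_form(self):
        t = resolve_coancestry_target(
            TargetSpec("coancestry_rate", 0.01), 0.0, 1.0, c_current=0.10
        )
        assert t == pytest.approx(0.109, abs=1e-12)

    def test_monotone_in_degrees_and_percent(self):
        degs = [resolve_coancestry_target(TargetSpec("degrees", d), 0.1, 0.4)
                for d in np.linspace(0, 90, 10)]
        assert all(a >= b - 1e-12 for a, b in zip(degs, degs[1:]))
        pcts = [resolve_coancestry_target(TargetSpec("percent_of_min", p), 0.1, 0.4)
                for p in np.linspace(0, 100, 10)]
        assert all(b >= a - 1e-12 for a, b in zip(pcts, pcts[1:]))

    def test_clamped_into_bounds(self):
        t = resolve_coancestry_target(TargetSpec("coancestry_value", 0.99), 0.1, 0.3)
        assert t == 0.3

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            resolve_coancestry_target(TargetSpec("degrees", 45.0), 0.5, 0.1)

    def test_invalid_forms(self):
        with pytest.raises(ValueError):
            TargetSpec("degrees", 120.0)
        with pytest.raises(ValueError):
            TargetSpec("percent_of_min", -5.0)
        with pytest.raises(ValueError):
            TargetSpec("nonsense", 1.0)


class TestPenalizedObjective:
    def test_feasible_max_gain(self):
        s, p = penalized_objective(1.0, 0.2, 0.1, 0.0, mode="max_gain", n_matings=4)
        assert (s, p) == (1.0, 0.0)

    def test_target_at_boundary_no_penalty(self):
        s, p = penalized_objective(
            1.0, 0.25, 0.1, 0.0, mode="target", n_matings=4,
            target_coancestry=0.25, span=0.1,
        )
        assert p == 0.0 and s == 1.0

    def test_residual_selfing_breach(self):
        s, p = penalized_objective(
            0.0, 0.2, 0.1, 1.0, mode="max_gain", n_matings=4, penalty_weight=1000.0
        )
        assert p == 250.0 and s == -250.0

    @pytest.mark.parametrize("mode", ["max_gain", "min_coancestry", "min_inbreeding"])
    def test_scalar_orientation(self, mode):
        better = {"max_gain": (1.5, 0.2, 0.2), "min_coancestry": (1.0, 0.1, 0.2),
                  "min_inbreeding": (1.0, 0.2, 0.1)}[mode]
        worse = (1.0, 0.2, 0.2)
        sb, _ = penalized_objective(*better, 0.0, mode=mode, n_matings=4)
        sw, _ = penalized_objective(*worse, 0.0, mode=mode, n_matings=4)
        assert sb >= sw
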