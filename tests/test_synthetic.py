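"""Synthetic generators, genic variance bookkeeping and the brute-force oracle."""

import numpy as np
import pytest

import matekit as mk
from matekit.synthetic import (
    SyntheticConfig,
    edited_criterion,
    enumerate_valid_plans,
    genic_sd,
    simulate_marker_population,
    simulate_pedigree_population,
    toy_recurrent_selection,
    _mate_progeny,
)


class TestGenicSD:
    def test_single_locus(self):
        assert genic_sd([0.5], [1.0]) == pytest.approx(np.sqrt(0.5))

    def test_fixed_locus_contributes_nothing(self):
        assert genic_sd([0.0, 1.0], [3.0, -2.0]) == 0.0

    def test_two_loci_additive(self):
        assert genic_sd([0.5, 0.5], [1.0, 1.0]) == pytest.approx(1.0)


class TestMarkerPopulation:
    def test_editing_already_optimal_genotype(self):
        G = np.array([[2.0]])
        assert edited_criterion(G, np.array([1.0]), 1)[0] == 2.0

    def test_editing_flips_to_favourable_homozygote(self):
        G = np.array([[0.0]])
        assert edited_criterion(G, np.array([1.0]), 1)[0] == 2.0
        # negative effect: favourable homozygote is dosage 0
        G2 = np.array([[2.0]])
        assert edited_criterion(G2, np.array([-1.0]), 1)[0] == 0.0

    def test_mean_criterion_matches_binomial_expectation(self):
        cfg = SyntheticConfig(n_founders=10000, n_loci=1, freq_range=(0.5, 0.5), seed=3)
        _, G, a, p = simulate_marker_population(cfg, effects=np.array([1.0]))
        # E[criterion] = 2 p alpha = 1; tolerance 3 SE
        se = np.sqrt(2 * 0.5 * 0.5 / 10000)
        assert abs(G.mean() - 1.0) < 3 * se

    def test_edited_criterion_never_below_criterion(self, rng):
        cfg = SyntheticConfig(n_founders=50, n_loci=30, seed=9)
        cand, _, _, _ = simulate_marker_population(cfg)
        assert (cand.criterion_edited >= cand.criterion - 1e-12).all()


class TestPedigreePopulation:
    def test_founders_only_are_unrelated(self):
        cfg = SyntheticConfig(n_founders=5, n_generations=0, seed=1)
        cand, ped = simulate_pedigree_population(cfg)
        C = mk.coancestry_from_pedigree(ped)
        np.testing.assert_allclose(C.values, np.eye(5) * 0.5, atol=1e-12)

    def test_children_reference_earlier_ids_only(self):
        cfg = SyntheticConfig(n_founders=4, n_generations=3, n_per_generation=5, seed=2)
        _, ped = simulate_pedigree_population(cfg)
        seen = set()
        for ident, s, d in ped:
            for p in (s, d):
                assert p == "0" or p in seen
            seen.add(ident)

    def test_founder_variance_near_one(self):
        cfg = SyntheticConfig(n_founders=10000, n_generations=0, seed=5)
        cand, _ = simulate_pedigree_population(cfg)
        assert cand.criterion.var() == pytest.approx(1.0, abs=0.05)


class TestBruteForceOracle:
    def test_plan_counts_match_combinatorics(self, four_unrelated):
        cand2 = mk.CandidateSet(["M1", "M2", "F1", "F2"], gender=[1, 1, 2, 2])
        C2 = mk.CoancestryMatrix(cand2.ids, np.eye(4) * 0.5)
        prob = mk.MatingProblem(cand2, C2, mk.MatingConstraints.gendered(1))
        assert sum(1 for _ in enumerate_valid_plans(prob)) == 4

        cand3 = mk.CandidateSet(list("ABC"))
        C3 = mk.CoancestryMatrix(list("ABC"), np.eye(3) * 0.5)
        prob3 = mk.MatingProblem(
            cand3, C3, mk.MatingConstraints.generic(1, allow_selfing=False)
        )
        assert sum(1 for _ in enumerate_valid_plans(prob3)) == 3

        cand4, C4 = four_unrelated
        prob4 = mk.MatingProblem(
            cand4, C4, mk.MatingConstraints.generic(2, max_contrib=1, allow_selfing=False)
        )
        best, _ = mk.brute_force_optimum(prob4, "min_coancestry")
        assert -best == pytest.approx(0.125, abs=1e-15)

    def test_rejects_large_instances(self):
        ids = [f"c{i}" for i in range(7)]
        cand = mk.CandidateSet(ids)
        C = mk.CoancestryMatrix(ids, np.eye(7) * 0.5)
        prob = mk.MatingProblem(cand, C, mk.MatingConstraints.generic(2))
        with pytest.raises(ValueError, match="too large"):
            list(enumerate_valid_plans(prob))


class TestGameteSampling:
    def test_allele_frequency_conserved_in_expectation(self, rng):
        G = rng.integers(0, 3, size=(6, 50)).astype(float)
        pairs = np.array([[0, 1], [2, 3], [4, 5]])
        parent_freq = G[pairs.ravel()].mean(axis=0) / 2.0
        drifts = []
        for rep in range(50):
            prog = _mate_progeny(G, pairs, 10, np.random.default_rng(rep))
            drifts.append(prog.mean(axis=0) / 2.0 - parent_freq)
        mean_drift = np.mean(drifts, axis=0)
        se = np.sqrt(parent_freq * (1 - parent_freq) / (2 * 30 * 50)).clip(1e-3)
        assert (np.abs(mean_drift) < 3 * se + 1e-9).mean() > 0.95


class TestToyRecurrentSelection:
    def test_zero_cycles_gives_base_stats_only(self):
        cfg = SyntheticConfig(n_loci=50, seed=1)
        traj = toy_recurrent_selection(cfg, "truncation-1", 0)
        assert len(traj.mean) == 1 and len(traj.genic_sd) == 1

    def test_stronger_truncation_burns_diversity_faster(self):
        """Four crosses per parent loses genic SD at least as fast as one."""
        lost1, lost4 = [], []
        for rep in range(6):
            cfg = SyntheticConfig(n_loci=100, seed=200 + rep)
            t1 = toy_recurrent_selection(cfg, "truncation-1", 4, seed=300 + rep)
            t4 = toy_recurrent_selection(cfg, "truncation-4", 4, seed=300 + rep)
            lost1.append(t1.genic_sd[0] - t1.genic_sd[-1])
            lost4.append(t4.genic_sd[0] - t4.genic_sd[-1])
        assert np.mean(lost4) > np.mean(lost1)
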