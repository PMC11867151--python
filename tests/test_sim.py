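"""Tests of the event-driven BiSSE tree simulator and trait machinery."""

from __future__ import annotations

import math

import numpy as np
import pytest

import fossilbisse as fb
from fossilbisse.sim import FOCAL_TRAIT

from oracles import yule_stop_time_sampler


def make_single_branch(length: float) -> fb.CompleteTree:
    return fb.CompleteTree(
        parent=[-1], birth=[0.0], death=[np.nan], stop_time=length,
        traits={FOCAL_TRAIT: [[(0.0, 0)]]},
    )


class TestCompleteTreeSimulation:
    def test_pure_birth_tree_has_no_extinct_lineages(self, rng):
        params = fb.BisseParameters(0.1, 0.1, 0.0, 0.0, 0.0, 0.0)
        tree = fb.simulate_complete_tree(params, 5, rng)
        assert tree.n_extant == 5
        assert tree.n_lineages == 5
        assert all(tree.is_extant(k) for k in range(5))
        assert all(s == 0 for s in tree.tip_states(FOCAL_TRAIT).values())

    def test_stopping_rule_gives_exact_extant_count(self, rng):
        params = fb.SCENARIOS["S1"].parameters()
        tree = fb.simulate_complete_tree(params, 100, rng)
        assert tree.n_extant == 100
        # the present coincides with the last speciation event
        last_birth = max(tree.birth)
        assert tree.stop_time == pytest.approx(last_birth)

    def test_child_inherits_parent_state_at_speciation(self, rng):
        params = fb.SCENARIOS["S2"].parameters()
        tree = fb.simulate_complete_tree(params, 60, rng)
        for k in range(1, tree.n_lineages):
            p = tree.parent[k]
            assert tree.traits[FOCAL_TRAIT][k][0][1] == tree.state_at(
                FOCAL_TRAIT, p, tree.birth[k]
            )
            assert tree.birth[k] >= tree.birth[p]
        for k in range(tree.n_lineages):
            if not tree.is_extant(k):
                assert tree.birth[k] < tree.death[k]

    def test_yule_stop_time_matches_exponential_sum_oracle(self):
        lam, n_stop, reps = 1.0, 6, 800
        rng = np.random.default_rng(3)
        times = [
            fb.simulate_complete_tree(
                fb.BisseParameters(lam, lam, 0, 0, 0, 0), n_stop, rng
            ).stop_time
            for _ in range(reps)
        ]
        oracle = yule_stop_time_sampler(lam, n_stop, np.random.default_rng(4), reps)
        expected = sum(1.0 / (k * lam) for k in range(1, n_stop))
        se = math.sqrt(np.var(times) / reps + np.var(oracle) / reps)
        assert abs(np.mean(times) - np.mean(oracle)) < 3 * se
        assert abs(np.mean(times) - expected) < 3 * math.sqrt(np.var(times) / reps)

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            fb.simulate_complete_tree(fb.SCENARIOS["S1"].parameters(), 1, rng)
        with pytest.raises(ValueError):
            fb.BisseParameters(-0.1, 0.1, 0, 0, 0, 0)
        with pytest.raises(ValueError):
            fb.BisseParameters(math.nan, 0.1, 0, 0, 0, 0)

    def test_subcritical_process_exhausts_rejection_budget(self, rng):
        params = fb.BisseParameters(0.01, 0.01, 0.5, 0.5, 0.0, 0.0)
        with pytest.raises(fb.RejectionBudgetExceeded):
            fb.simulate_complete_tree(params, 50, rng, max_rejections=5)

    def test_seeded_runs_are_bit_reproducible(self):
        params = fb.SCENARIOS["S3"].parameters()
        t1 = fb.simulate_complete_tree(params, 40, np.random.default_rng(9))
        t2 = fb.simulate_complete_tree(params, 40, np.random.default_rng(9))
        assert t1.parent == t2.parent
        assert t1.birth == t2.birth
        assert [d for d in t1.death] == pytest.approx([d for d in t2.death], nan_ok=True)
        assert t1.traits == t2.traits


class TestNeutralTraits:
    def test_zero_rate_trait_never_leaves_root_state(self, rng):
        params = fb.SCENARIOS["S1"].parameters()
        tree = fb.simulate_complete_tree(params, 30, rng)
        name = fb.simulate_neutral_trait(tree, fb.NeutralTraitSpec(0.0, "frozen"), rng)
        assert all(traj == [(tree.birth[k], 0)] for k, traj in enumerate(tree.traits[name]))

    def test_flip_probability_matches_closed_form(self):
        # P(end != start) on one branch = (1 - exp(-2qt)) / 2
        q, t, n = 1.0, 0.7, 10_000
        rng = np.random.default_rng(5)
        spec = fb.NeutralTraitSpec(q, "x")
        flips = 0
        for _ in range(n):
            tree = make_single_branch(t)
            name = fb.simulate_neutral_trait(tree, spec, rng)
            flips += tree.state_at(name, 0, t) != 0
        p = (1 - math.exp(-2 * q * t)) / 2
        se = math.sqrt(p * (1 - p) / n)
        assert abs(flips / n - p) < 3 * se

    def test_nonstandard_rates_accepted(self, rng):
        tree = fb.simulate_complete_tree(fb.SCENARIOS["S1"].parameters(), 10, rng)
        for q in (0.01, 0.1, 1.0, 0.5):
            fb.simulate_neutral_trait(tree, fb.NeutralTraitSpec(q), rng, name=f"q{q}")
            assert f"q{q}" in tree.traits

    def test_trajectories_are_valid_piecewise_constant(self, rng):
        tree = fb.simulate_complete_tree(fb.SCENARIOS["S1"].parameters(), 30, rng)
        fb.simulate_neutral_trait(tree, fb.NeutralTraitSpec(1.0, "fast"), rng)
        for name in tree.traits:
            for k, traj in enumerate(tree.traits[name]):
                times = [t for t, _ in traj]
                states = [s for _, s in traj]
                assert times == sorted(times)
                assert times[0] == tree.birth[k]
                assert all(s in (0, 1) for s in states)
                assert all(a != b for a, b in zip(states, states[1:]))

    def test_neutral_state_distribution_exchangeable_with_symmetric_focal(self):
        # under S1 the focal trait is itself a symmetric q=0.01 trait
        rng = np.random.default_rng(11)
        focal_frac, neutral_frac = [], []
        for _ in range(60):
            tree = fb.simulate_complete_tree(fb.SCENARIOS["S1"].parameters(), 20, rng)
            name = fb.simulate_neutral_trait(tree, fb.NeutralTraitSpec(0.01, "n"), rng)
            tips = tree.extant_lineages()
            focal_frac.append(
                np.mean([tree.state_at(FOCAL_TRAIT, k, tree.stop_time) for k in tips])
            )
            neutral_frac.append(
                np.mean([tree.state_at(name, k, tree.stop_time) for k in tips])
            )
        se = math.sqrt((np.var(focal_frac) + np.var(neutral_frac)) / 60)
        assert abs(np.mean(focal_frac) - np.mean(neutral_frac)) < 3 * se + 1e-12


class TestReplicateFilter:
    def test_accepted_replicate_satisfies_frequency_rule(self, small_replicate):
        ds = small_replicate
        for trait in ds.trait_names:
            assert fb.passes_frequency_rule(ds.views, trait)
        assert ds.extant.is_ultrametric()
        assert len(ds.extant.tips()) == 50

    def test_psi_zero_yields_no_fbd_view(self, rng):
        ds = fb.generate_replicate(fb.SCENARIOS["S1"], 0.0, [], 10, rng)
        assert ds.fbd is None
        assert ds.occurrences == []
        assert ds.views == [ds.extant]

    def test_neutral_acceptance_rate_matches_standalone_oracle(self):
        # probability that a fresh q=0.01 trait passes the 10% rule on a
        # fixed tree, vs rerunning the trait simulator standalone
        rng = np.random.default_rng(21)
        tree = fb.simulate_complete_tree(fb.SCENARIOS["S1"].parameters(), 40, rng)
        extant = fb.prune_to_extant(tree)
        spec = fb.NeutralTraitSpec(0.01, "probe")
        n = 400

        def pass_rate(seed):
            r = np.random.default_rng(seed)
            hits = 0
            for _ in range(n):
                fb.simulate_neutral_trait(tree, spec, r)
                extant.stamp_states(tree, spec.label)
                hits += fb.passes_frequency_rule([extant], spec.label)
            return hits / n

        p1, p2 = pass_rate(1), pass_rate(2)
        pbar = (p1 + p2) / 2
        se = math.sqrt(max(2 * pbar * (1 - pbar) / n, 1e-9))
        assert abs(p1 - p2) < 3 * se + 1e-12
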