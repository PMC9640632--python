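"""Engine checks against closed forms, dense matrix exponentials, and SSA."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.linalg import expm

from metcheck.ctmc_engine import (
    RewardStructure,
    StateSpaceBoundError,
    build_ctmc,
    cumulative_reward,
    embed,
    expected_amount,
    step_bounded_reachability,
    time_bounded_reachability,
    transient_distribution,
)
from metcheck.network_model import apply_update, is_enabled, parse_network
from metcheck.stochastic_sim import estimate_query
from metcheck.ctmc_engine import CumulativeReward

from conftest import random_ctmc


class TestBuild:
    def test_single_reaction_two_states(self, one_reaction):
        model, rates = one_reaction(1.0)
        ctmc = build_ctmc(model, rates)
        assert ctmc.n_states == 2
        assert ctmc.rate_matrix.nnz == 1
        i = ctmc.find_state((1, 0))
        j = ctmc.find_state((0, 1))
        assert ctmc.rate_matrix[i, j] == 1.0

    def test_all_zero_initial_is_single_absorbing_state(self, one_reaction):
        model, rates = one_reaction(1.0)
        model = model.with_initial_amounts({"A": 0})
        ctmc = build_ctmc(model, rates)
        assert ctmc.n_states == 1
        assert ctmc.rate_matrix.nnz == 0

    def test_zero_rate_commands_do_not_expand_space(self, one_reaction):
        model, _ = one_reaction()
        ctmc = build_ctmc(model, {"k": 0.0})
        assert ctmc.n_states == 1

    def test_state_count_matches_bruteforce_closure(
        self, default_model, standin_tables
    ):
        """Independent oracle: plain-python BFS with is_enabled/apply_update."""
        small = default_model.with_caps(
            dict.fromkeys(default_model.species_names, 3)
        ).with_initial_amounts({"IDHmut": 1})
        rates = standin_tables[("IDHmut", "hypoxia")]
        active = [
            c
            for c in small.commands
            if all(rates.get(k, 0.0) > 0 for k in c.rate_keys)
        ]
        seen = {small.initial_state()}
        frontier = [small.initial_state()]
        edges = 0
        while frontier:
            nxt = []
            for state in frontier:
                for cmd in active:
                    if is_enabled(cmd, state, small):
                        edges += 1
                        after = apply_update(cmd, state, small)
                        if after not in seen:
                            seen.add(after)
                            nxt.append(after)
            frontier = nxt
        ctmc = build_ctmc(small, rates)
        assert ctmc.n_states == len(seen)
        assert sum(len(v[0]) for v in ctmc.command_transitions.values()) == edges

    def test_state_space_bound_raises(self, default_model, standin_tables):
        with pytest.raises(StateSpaceBoundError, match="caps"):
            build_ctmc(
                default_model, standin_tables[("IDHwt", "normoxia")], max_states=10
            )

    def test_multi_initial_union(self, one_reaction):
        model, rates = one_reaction(1.0)
        ctmc = build_ctmc(model, rates, initial_states=[(1, 0), (0, 0)])
        assert len(ctmc.initial_indices) == 2
        assert ctmc.n_states == 3  # (1,0), (0,1) and the separate (0,0)


class TestEmbed:
    def test_two_outgoing_rates_become_probabilities(self):
        model = parse_network(
            "species A init=1 max=1\nspecies B init=0 max=1\nspecies C init=0 max=1\n"
            "R1: A -> B @ k1\nR2: A -> C @ k2\n"
        )
        ctmc = build_ctmc(model, {"k1": 1.0, "k2": 3.0})
        dtmc = embed(ctmc)
        i = ctmc.find_state((1, 0, 0))
        row = dtmc.P[i].toarray().ravel()
        assert row[ctmc.find_state((0, 1, 0))] == 0.25
        assert row[ctmc.find_state((0, 0, 1))] == 0.75

    def test_absorbing_state_gets_self_loop(self, one_reaction):
        model, rates = one_reaction(1.0)
        ctmc = build_ctmc(model, rates)
        dtmc = embed(ctmc)
        j = ctmc.find_state((0, 1))
        assert dtmc.P[j, j] == 1.0

    def test_rows_sum_to_one_on_random_chains(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            ctmc, _ = random_ctmc(rng, int(rng.integers(2, 30)))
            dtmc = embed(ctmc)
            rowsum = np.asarray(dtmc.P.sum(axis=1)).ravel()
            assert np.abs(rowsum - 1.0).max() <= 1e-12


class TestTransient:
    def test_t_zero_is_point_mass(self, wt_normoxia_ctmc):
        d = transient_distribution(wt_normoxia_ctmc, 0.0)
        assert d[wt_normoxia_ctmc.initial_index] == 1.0
        assert d.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("k", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("t", [0.1, 1.0, 10.0])
    def test_one_reaction_closed_form(self, one_reaction, k, t):
        model, rates = one_reaction(k)
        ctmc = build_ctmc(model, rates)
        d = transient_distribution(ctmc, t)
        assert d[ctmc.find_state((0, 1))] == pytest.approx(
            1 - np.exp(-k * t), abs=1e-10
        )

    def test_matches_matrix_exponential_on_random_chains(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            n = int(rng.integers(3, 50))
            ctmc, Q = random_ctmc(rng, n)
            gen = Q - np.diag(Q.sum(axis=1))
            for t in (0.2, 1.0, 3.0):
                d = transient_distribution(ctmc, t)
                ref = np.eye(n)[0] @ expm(gen * t)
                assert np.abs(d - ref).max() <= 1e-8

    def test_distribution_normalized_on_grid(self, wt_normoxia_ctmc):
        ts = np.array([0.5, 1.0, 5.0, 10.0, 20.0])
        d = transient_distribution(wt_normoxia_ctmc, ts)
        assert np.abs(d.sum(axis=1) - 1.0).max() <= 1e-9

    def test_negative_time_rejected(self, wt_normoxia_ctmc):
        with pytest.raises(ValueError, match="non-negative"):
            transient_distribution(wt_normoxia_ctmc, -1.0)


class TestExpectedAmount:
    def test_t_zero_returns_initial_amount(self, wt_normoxia_ctmc):
        assert expected_amount(wt_normoxia_ctmc, "Gluc", 0.0) == pytest.approx(5.0)

    def test_one_reaction_closed_form(self, one_reaction):
        model, rates = one_reaction(1.3)
        ctmc = build_ctmc(model, rates)
        for t in (0.1, 1.0, 4.0):
            assert expected_amount(ctmc, "B", t) == pytest.approx(
                1 - np.exp(-1.3 * t), abs=1e-10
            )

    def test_chain_matches_expm_oracle(self, chain3):
        model, rates = chain3(1.0, 0.4)
        ctmc = build_ctmc(model, rates)
        n = ctmc.n_states
        Q = ctmc.rate_matrix.toarray()
        gen = Q - np.diag(Q.sum(axis=1))
        for t in (0.5, 2.0, 8.0):
            dist = np.eye(n)[ctmc.initial_index] @ expm(gen * t)
            ref = dist @ ctmc.states[:, model.species_index("B")]
            assert expected_amount(ctmc, "B", t) == pytest.approx(ref, abs=1e-9)

    def test_unknown_species_raises(self, wt_normoxia_ctmc):
        with pytest.raises(KeyError):
            expected_amount(wt_normoxia_ctmc, "NADH", 1.0)


class TestCumulativeReward:
    def test_zero_horizon_zero_reward(self, one_reaction):
        model, rates = one_reaction(1.0)
        ctmc = build_ctmc(model, rates)
        assert cumulative_reward(ctmc, RewardStructure.count_command("R"), 0.0) == 0.0

    def test_single_shot_counts_to_one(self, one_reaction):
        model, rates = one_reaction(2.0)
        ctmc = build_ctmc(model, rates)
        val = cumulative_reward(ctmc, RewardStructure.count_command("R"), 50.0)
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_ping_pong_long_run_rate(self, ping_pong):
        lam, mu, t = 2.0, 3.0, 200.0
        model, rates = ping_pong(lam, mu)
        ctmc = build_ctmc(model, rates)
        val = cumulative_reward(ctmc, RewardStructure.count_command("F"), t)
        asymptote = lam * mu / (lam + mu) * t
        assert val == pytest.approx(asymptote, rel=0.01)

    def test_ping_pong_matches_ssa(self, ping_pong):
        lam, mu, t = 1.0, 0.5, 5.0
        model, rates = ping_pong(lam, mu)
        ctmc = build_ctmc(model, rates)
        query = CumulativeReward(RewardStructure.count_command("F"), t)
        exact = cumulative_reward(ctmc, query.reward, t)
        est, se = estimate_query(model, rates, query, n_runs=3000, seed=5)
        assert abs(est - exact) <= 3 * se

    def test_state_reward_accrues_amount_time_product(self, one_reaction):
        # E[∫ B du] = ∫ (1 - e^{-ku}) du = t - (1 - e^{-kt})/k
        model, rates = one_reaction(1.0)
        ctmc = build_ctmc(model, rates)
        t = 3.0
        val = cumulative_reward(ctmc, RewardStructure.species_amount("B"), t)
        assert val == pytest.approx(t - (1 - np.exp(-t)), abs=1e-8)

    def test_unknown_command_id_raises(self, one_reaction):
        model, rates = one_reaction(1.0)
        ctmc = build_ctmc(model, rates)
        with pytest.raises(KeyError, match="nope"):
            cumulative_reward(ctmc, RewardStructure.count_command("nope"), 1.0)


class TestReachability:
    def test_initially_labeled_state_gives_one(self, one_reaction):
        model, rates = one_reaction(1.0)
        ctmc = build_ctmc(model, rates)
        for t in (0.0, 1.0, 10.0):
            assert time_bounded_reachability(ctmc, "A_saturated", t) == 1.0

    def test_one_reaction_closed_form(self, one_reaction):
        model, rates = one_reaction(0.7)
        ctmc = build_ctmc(model, rates)
        for t in (0.1, 1.0, 10.0):
            assert time_bounded_reachability(
                ctmc, "B_saturated", t
            ) == pytest.approx(1 - np.exp(-0.7 * t), abs=1e-10)

    def test_monotone_in_time(self, wt_normoxia_ctmc):
        ts = np.linspace(0.0, 20.0, 21)
        p = time_bounded_reachability(wt_normoxia_ctmc, "Lac_saturated", ts)
        assert (np.diff(p) >= -1e-9).all()
        assert ((p >= 0) & (p <= 1)).all()

    def test_matches_ssa_fraction(self, chain3, default_model, standin_tables):
        from metcheck.ctmc_engine import TimeBoundedReachability

        model, rates = chain3(1.0, 0.8)
        ctmc = build_ctmc(model, rates)
        t = 2.0
        exact = time_bounded_reachability(ctmc, "C_saturated", t)
        est, se = estimate_query(
            model, rates, TimeBoundedReachability("C_saturated", t), 4000, seed=13
        )
        assert abs(est - exact) <= 3 * max(se, 1e-12)

    def test_unknown_label_raises(self, wt_normoxia_ctmc):
        with pytest.raises(KeyError, match="unknown label"):
            time_bounded_reachability(wt_normoxia_ctmc, "NADH_saturated", 1.0)

    def test_step_bounded_variant_on_jump_chain(self, chain3):
        # two jumps are needed to reach C regardless of rates
        model, rates = chain3(5.0, 0.1)
        ctmc = build_ctmc(model, rates)
        assert step_bounded_reachability(ctmc, "C_saturated", 0) == 0.0
        assert step_bounded_reachability(ctmc, "C_saturated", 1) == 0.0
        assert step_bounded_reachability(ctmc, "C_saturated", 2) == 1.0
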