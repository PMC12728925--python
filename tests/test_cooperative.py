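"""Population strategies: buffer contracts, auxiliary losses, reductions."""

import numpy as np
import pytest

from molexplore import clm_policy, cooperative, rl_engine
from molexplore.clm_policy import TokenSequence
from molexplore.cooperative import (
    PopulationConfig,
    behavior_embedding,
    dvd_score,
    init_population,
    popnorm_adjust,
    purge_insert,
    shared_bonus,
    specialization_loss,
)
from molexplore.nn import Tensor
from molexplore.rl_engine import RLConfig, Trajectory


def _traj(canonical, reward=0.5):
    return Trajectory(TokenSequence((1, 3, 2)), canonical, canonical, -5.0, -6.0,
                      reward, reward)


SHORT_BUDGET = 192


def _run_rows(base_policy, task, rl_cfg, strategy, n=2, seed=7, **pop_kwargs):
    pc = PopulationConfig(strategy=strategy, **pop_kwargs)
    pop = init_population(n, strategy, base_policy, rl_cfg, pop_cfg=pc, seed=seed)
    res = cooperative.run_cooperative(pop, task, SHORT_BUDGET)
    return [[(r["smiles"], r["reward_shaped"]) for r in rec.rows] for rec in res.records]


class TestInitPopulation:
    def test_zero_noise_copies_exactly(self, base_policy, rl_cfg):
        pop = init_population(3, "noise", base_policy, rl_cfg,
                              pop_cfg=PopulationConfig("noise", noise_sigma=0.0), seed=1)
        for agent in pop.agents:
            for k, t in agent.policy.params.items():
                np.testing.assert_array_equal(t.data, base_policy.params[k].data)

    def test_noise_perturbs_every_agent_differently(self, base_policy, rl_cfg):
        pop = init_population(2, "noise", base_policy, rl_cfg,
                              pop_cfg=PopulationConfig("noise", noise_sigma=0.01), seed=1)
        a, b = pop.agents
        diffs = [
            np.abs(a.policy.params[k].data - b.policy.params[k].data).max()
            for k in a.policy.params
        ]
        assert max(diffs) > 0

    def test_same_seed_identical_population(self, base_policy, rl_cfg):
        p1 = init_population(2, "noise", base_policy, rl_cfg, seed=4)
        p2 = init_population(2, "noise", base_policy, rl_cfg, seed=4)
        for a1, a2 in zip(p1.agents, p2.agents):
            for k in a1.policy.params:
                np.testing.assert_array_equal(
                    a1.policy.params[k].data, a2.policy.params[k].data
                )

    def test_unknown_strategy_lists_valid_names(self, base_policy, rl_cfg):
        with pytest.raises(ValueError, match="independent"):
            init_population(2, "telepathy", base_policy, rl_cfg)

    def test_shared_strategy_uses_one_buffer(self, base_policy, rl_cfg):
        pop = init_population(4, "shared", base_policy, rl_cfg, seed=0)
        assert all(a.buffer is pop.shared_buffer for a in pop.agents)


class TestPurge:
    def test_blocked_when_another_buffer_holds_it(self, base_policy, rl_cfg):
        pop = init_population(2, "purge", base_policy, rl_cfg, seed=0)
        pop.agents[1].buffer.insert(_traj("CCO"))
        assert not purge_insert(pop, 0, _traj("CCO"))
        assert "CCO" not in pop.agents[0].buffer

    def test_novel_molecule_inserted(self, base_policy, rl_cfg):
        pop = init_population(2, "purge", base_policy, rl_cfg, seed=0)
        assert purge_insert(pop, 0, _traj("CCO"))
        assert "CCO" in pop.agents[0].buffer

    def test_disjoint_after_many_random_inserts(self, base_policy, rl_cfg, rng):
        pop = init_population(3, "purge", base_policy, rl_cfg, seed=0)
        mols = [f"{'C' * (i % 7 + 1)}O" for i in range(40)]
        for _ in range(1000):
            purge_insert(pop, int(rng.integers(3)), _traj(mols[rng.integers(len(mols))],
                                                          float(rng.random())))
        sets = [set(a.buffer.entries) for a in pop.agents]
        for i in range(3):
            for j in range(i + 1, 3):
                assert not (sets[i] & sets[j])


class TestSharedBonus:
    def test_bonus_for_absent_zero_for_present(self, base_policy, rl_cfg):
        pop = init_population(2, "shared_bonus", base_policy, rl_cfg,
                              pop_cfg=PopulationConfig("shared_bonus", bonus_b=0.2), seed=0)
        assert shared_bonus(pop, "CCO") == 0.2
        pop.shared_buffer.insert(_traj("CCO"))
        assert shared_bonus(pop, "CCO") == 0.0


class TestPopnorm:
    def test_constant_returns_vanish(self):
        out = popnorm_adjust([np.ones(4)])
        np.testing.assert_array_equal(out[0], np.zeros(4))

    def test_mean_subtraction(self):
        out = popnorm_adjust([np.array([2.0]), np.array([0.0])])
        assert out[0][0] == 1.0 and out[1][0] == -1.0

    def test_adjusted_returns_sum_to_zero(self, rng):
        returns = [rng.random(rng.integers(1, 6)) for _ in range(4)]
        adjusted = popnorm_adjust(returns)
        total = np.concatenate(adjusted)
        # zero-mean, hence zero-sum up to float precision
        assert abs(total.mean()) < 1e-12


class TestSpecializationLoss:
    def _pop(self, base_policy, rl_cfg, n=2, seed=0):
        return init_population(n, "ent_s", base_policy, rl_cfg, seed=seed)

    def _states(self, base_policy, n=6):
        return [s for s, _ in base_policy.sample_batch(n, 3)]

    def test_single_agent_population_is_zero(self, base_policy, rl_cfg):
        pop = init_population(1, "ent_s", base_policy, rl_cfg, seed=0)
        states = self._states(base_policy)
        for kind in cooperative.SPECIALIZATION_KINDS:
            assert specialization_loss(kind, pop, 0, states, np.zeros(len(states))) == 0.0

    def test_identical_agents_give_uniform_confidence(self, base_policy, rl_cfg):
        """Agents with equal parameters give entropy ln N and CE ln N."""
        pop = self._pop(base_policy, rl_cfg)
        states = self._states(base_policy)
        origins = np.array([0, 1] * 3)
        ent = specialization_loss("ent_s", pop, 0, states, origins)
        ce = specialization_loss("ce_s", pop, 0, states, origins)
        assert float(ent.data) == pytest.approx(np.log(2), abs=1e-9)
        assert float(ce.data) == pytest.approx(np.log(2), abs=1e-9)

    def test_one_hot_confidence_makes_ce_vanish(self, tiny_vocab, rl_cfg):
        """When each agent is far more confident on its own states the
        cross-entropy specialization loss approaches zero."""
        pol = clm_policy.Policy(tiny_vocab, clm_policy.PolicyConfig(8, 16, 1, 10), seed=0)
        pop = init_population(2, "ce_s", pol, rl_cfg, seed=0)
        # parameter surgery: bias agent 0 hard toward C, agent 1 toward O
        iC = tiny_vocab.index["C"]
        iO = tiny_vocab.index["O"]
        pop.agents[0].policy.params["out_b"].data[iC] += 50.0
        pop.agents[1].policy.params["out_b"].data[iO] += 50.0
        sC = clm_policy.tokenize("CC", tiny_vocab)
        sO = clm_policy.tokenize("OO", tiny_vocab)
        ce = specialization_loss("ce_s", pop, 0, [sC, sO], np.array([0, 1]))
        assert float(ce.data) < 1e-6

    def test_diff_s_zero_when_no_contrast(self, base_policy, rl_cfg):
        pop = self._pop(base_policy, rl_cfg)
        states = self._states(base_policy)
        assert specialization_loss("diff_s", pop, 0, states, np.zeros(len(states))) == 0.0

    def test_diff_n_value_for_identical_agents(self, base_policy, rl_cfg):
        """Identical agents have zero log-probability margin."""
        pop = self._pop(base_policy, rl_cfg)
        states = self._states(base_policy)
        origins = np.array([0, 0, 0, 1, 1, 1])
        loss = specialization_loss("diff_n", pop, 0, states, origins)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-9)

    def test_losses_are_differentiable(self, base_policy, rl_cfg):
        pop = self._pop(base_policy, rl_cfg)
        states = self._states(base_policy)
        origins = np.array([0, 1] * 3)
        for kind in cooperative.SPECIALIZATION_KINDS:
            loss = specialization_loss(kind, pop, 0, states, origins)
            loss.backward()
            grads = [t.grad for t in pop.agents[0].policy.parameters() if t.grad is not None]
            assert grads, f"{kind} produced no gradient"
            for t in pop.agents[0].policy.parameters():
                t.zero_grad()


class TestDvD:
    def test_embedding_deterministic_with_probe_dimension(self, base_policy):
        probes = [s for s, _ in base_policy.sample_batch(5, 1)]
        e1 = behavior_embedding(base_policy, probes)
        e2 = behavior_embedding(base_policy, probes)
        np.testing.assert_array_equal(e1, e2)
        assert e1.shape == (5,)

    def test_identical_embeddings_hit_floor(self):
        e = np.array([[1.0, 2.0], [1.0, 2.0]])
        assert dvd_score(e, floor=-30.0) == pytest.approx(-30.0)

    def test_two_point_closed_form(self):
        e = np.array([[0.0, 0.0], [3.0, 4.0]])  # distance 5
        h = 2.0
        k = np.exp(-25.0 / (2 * h * h))
        expected = np.log(1 - k * k)  # logdet [[1,k],[k,1]], jitter negligible
        assert dvd_score(e, kernel_bandwidth=h) == pytest.approx(expected, abs=1e-6)

    def test_separation_increases_score(self):
        scores = [
            dvd_score(np.array([[0.0, 0.0], [d, 0.0]]), kernel_bandwidth=1.0)
            for d in (0.5, 1.0, 2.0, 4.0)
        ]
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_permutation_invariance(self, rng):
        e = rng.normal(size=(4, 6))
        perm = rng.permutation(4)
        assert dvd_score(e) == pytest.approx(dvd_score(e[perm]))


class TestReductions:
    def test_independent_n1_equals_single_agent_run(self, base_policy, rl_cfg,
                                                    toy_task_and_split):
        task, _ = toy_task_and_split
        rec = rl_engine.run_single_agent(base_policy, task, SHORT_BUDGET, rl_cfg, seed=42)
        pop = init_population(1, "independent", base_policy, rl_cfg, seed=42)
        res = cooperative.run_cooperative(pop, task, SHORT_BUDGET)
        assert [(r["smiles"], r["reward_shaped"]) for r in rec.rows] == \
               [(r["smiles"], r["reward_shaped"]) for r in res.records[0].rows]

    @pytest.mark.parametrize(
        "strategy,kwargs",
        [
            ("noise", {"noise_sigma": 0.0}),
            ("ent_s", {"aux_weight": 0.0}),
            ("ce_s", {"aux_weight": 0.0}),
            ("diff_s", {"aux_weight": 0.0}),
            ("diff_n", {"aux_weight": 0.0}),
            ("dvd", {"aux_weight": 0.0}),
        ],
    )
    def test_zero_coefficient_reduces_to_independent(self, base_policy, rl_cfg,
                                                     toy_task_and_split, strategy, kwargs):
        task, _ = toy_task_and_split
        ref = _run_rows(base_policy, task, rl_cfg, "independent")
        assert _run_rows(base_policy, task, rl_cfg, strategy, **kwargs) == ref

    def test_rnd_with_zero_scale_reduces_to_independent(self, base_policy,
                                                        toy_task_and_split):
        task, _ = toy_task_and_split
        cfg0 = RLConfig(batch_size=64, replay_k=10, lr=3e-3, rnd_bonus_scale=0.0)
        ref = _run_rows(base_policy, task, cfg0, "independent")
        assert _run_rows(base_policy, task, cfg0, "rnd") == ref

    def test_union_score_dominates_each_agent(self, base_policy, rl_cfg,
                                              toy_task_and_split):
        task, _ = toy_task_and_split
        pop = init_population(2, "independent", base_policy, rl_cfg, seed=11)
        res = cooperative.run_cooperative(pop, task, SHORT_BUDGET)
        union = res.union_trace.per_target_max
        for rec in res.records:
            assert np.all(union >= rec.trace.per_target_max - 1e-15)
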