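"""Reward reshaping, replay, exploration mechanisms and the RL step."""

import numpy as np
import pytest
from scipy import stats

from molexplore import chem_core, clm_policy, rl_engine
from molexplore.benchmark import BudgetLedger, ScoreTrace, TaskSpec
from molexplore.clm_policy import TokenSequence
from molexplore.nn import Tensor
from molexplore.rl_engine import (
    DFMemory,
    ReplayBuffer,
    RLConfig,
    RNDState,
    ShapingConfig,
    Trajectory,
    apply_diversity_filter,
    buffer_sample,
    make_agent,
    reinforce_loss,
    reshape_reward,
    rl_step,
    run_single_agent,
)


def _traj(canonical, reward, lp_agent=-5.0):
    seq = TokenSequence((1, 3, 2))
    return Trajectory(seq, canonical or "bad", canonical, lp_agent, -6.0, reward, reward)


class TestReshapeReward:
    def test_identity_configuration(self):
        cfg = ShapingConfig(sigma=0.0, alpha=1.0)
        for r in (0.0, 0.25, 0.5, 1.0):
            assert reshape_reward(r, -50.0, cfg) == r

    def test_prior_penalty_arithmetic(self):
        cfg = ShapingConfig(sigma=0.001, alpha=1.0)
        assert reshape_reward(0.8, -100.0, cfg) == pytest.approx(0.7)

    def test_clip_at_zero_before_exponent(self):
        cfg = ShapingConfig(sigma=0.01, alpha=2.0)
        assert reshape_reward(0.5, -100.0, cfg) == 0.0

    def test_monotone_in_raw_reward(self):
        cfg = ShapingConfig(sigma=0.002, alpha=3.0)
        rs = np.linspace(0, 1, 50)
        shaped = [reshape_reward(r, -80.0, cfg) for r in rs]
        assert all(b >= a for a, b in zip(shaped, shaped[1:]))
        assert all(s >= 0 for s in shaped)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ShapingConfig(sigma=-0.1)
        with pytest.raises(ValueError):
            ShapingConfig(alpha=0.5)
        with pytest.raises(ValueError):
            reshape_reward(-0.1, 0.0, ShapingConfig())


class TestReinforceLoss:
    def test_zero_rewards_give_zero_loss(self):
        batch = [_traj("CCO", 0.0), _traj("CCN", 0.0)]
        assert reinforce_loss(batch) == 0.0

    def test_single_trajectory_value(self):
        t = _traj("CCO", 1.0, lp_agent=-2.0)
        assert reinforce_loss([t]) == pytest.approx(2.0)

    def test_mean_invariance_under_duplication(self):
        batch = [_traj("CCO", 0.3, -1.0), _traj("CCN", 0.9, -4.0)]
        assert reinforce_loss(batch) == pytest.approx(reinforce_loss(batch * 3))

    def test_nonfinite_log_prob_errors(self):
        t = _traj("CCO", 1.0, lp_agent=float("nan"))
        with pytest.raises(FloatingPointError):
            reinforce_loss([t])

    def test_gradient_direction_increases_rewarded_log_prob(self):
        lp = Tensor(np.array([-2.0, -3.0]), requires_grad=True)
        loss = reinforce_loss([_traj("CCO", 1.0), _traj("CCN", 0.0)], log_probs=lp)
        loss.backward()
        assert lp.grad[0] < 0  # pushing log-prob up lowers the loss
        assert lp.grad[1] == 0.0


class TestReplayBuffer:
    def test_dedup_keeps_max_reward(self):
        buf = ReplayBuffer(capacity=10)
        buf.insert(_traj("CCO", 0.3))
        buf.insert(_traj("CCO", 0.7))
        buf.insert(_traj("CCO", 0.5))
        assert len(buf) == 1
        assert buf.entries["CCO"].reward_raw == 0.7

    def test_eviction_of_minimum(self):
        buf = ReplayBuffer(capacity=2)
        for c, r in (("CCO", 0.9), ("CCN", 0.8), ("CCC", 0.5)):
            buf.insert(_traj(c, r))
        assert set(buf.entries) == {"CCO", "CCN"}

    def test_invalid_molecule_is_noop(self):
        buf = ReplayBuffer()
        buf.insert(_traj(None, 1.0))
        assert len(buf) == 0

    def test_sample_whole_buffer_when_k_large(self, rng):
        buf = ReplayBuffer()
        buf.insert(_traj("CCO", 0.5))
        buf.insert(_traj("CCN", 0.1))
        assert len(buf.sample(10, rng)) == 2

    def test_zero_reward_never_drawn_against_positive(self, rng):
        buf = ReplayBuffer()
        buf.insert(_traj("CCO", 1.0))
        buf.insert(_traj("CCN", 0.0))
        for _ in range(50):
            assert buf.sample(1, rng)[0].canonical == "CCO"

    def test_draw_frequencies_proportional_to_reward(self):
        buf = ReplayBuffer()
        buf.insert(_traj("CCO", 0.75))  # 3:1 odds over CCN
        buf.insert(_traj("CCN", 0.25))
        rng = np.random.default_rng(0)
        hits = sum(buf.sample(1, rng)[0].canonical == "CCO" for _ in range(10000))
        lo, hi = stats.binom.interval(0.99, 10000, 0.75)
        assert lo <= hits <= hi

    def test_empty_buffer_errors(self):
        with pytest.raises(ValueError):
            buffer_sample(ReplayBuffer(), 1, 0)


class TestRND:
    def test_bonus_nonnegative(self, rng):
        rnd = RNDState(seed=0)
        fp = chem_core.ecfp4("CCO")
        assert rnd.bonus(fp) >= 0.0

    def test_training_drives_bonus_down_and_novelty_up(self):
        rnd = RNDState(seed=0, lr=3e-3)
        seen = chem_core.ecfp4("CCO")
        novel = chem_core.ecfp4("c1ccc(CNC)cc1")
        initial = rnd.bonus(seen)
        for _ in range(200):
            rnd.update([seen])
        assert rnd.bonus(seen) < 0.1 * initial
        assert rnd.bonus(novel) > rnd.bonus(seen)


class TestDiversityFilter:
    def test_first_pass_then_zero(self):
        mem = DFMemory()
        assert apply_diversity_filter(mem, "CCO", 0.8) == 0.8
        assert apply_diversity_filter(mem, "CCO", 0.8) == 0.0

    def test_same_molecule_different_spelling(self):
        mem = DFMemory()
        c1 = chem_core.validate_and_canonicalize("CCO")
        c2 = chem_core.validate_and_canonicalize("OCC")
        apply_diversity_filter(mem, c1, 0.8)
        assert apply_diversity_filter(mem, c2, 0.9) == 0.0


@pytest.fixture()
def lev_task(toy_task_and_split):
    task, _ = toy_task_and_split
    return task


class TestRLStep:
    def test_budget_64_is_one_step(self, base_policy, lev_task, rl_cfg):
        agent = make_agent(base_policy, rl_cfg, seed=0)
        ledger = BudgetLedger(64)
        trace = ScoreTrace(lev_task.n_trace)
        trajs = rl_step(agent, lev_task, ledger, trace, rl_cfg)
        assert len(trajs) == 64 and ledger.remaining == 0
        assert rl_step(agent, lev_task, ledger, trace, rl_cfg) == []

    def test_truncates_to_remaining_budget(self, base_policy, lev_task, rl_cfg):
        agent = make_agent(base_policy, rl_cfg, seed=0)
        ledger = BudgetLedger(70)
        trace = ScoreTrace(lev_task.n_trace)
        rl_step(agent, lev_task, ledger, trace, rl_cfg)
        trajs = rl_step(agent, lev_task, ledger, trace, rl_cfg)
        assert len(trajs) == 6 and ledger.consumed == 70

    def test_identity_config_shaped_equals_raw(self, base_policy, lev_task):
        cfg = RLConfig(batch_size=32, replay_k=0,
                       shaping=ShapingConfig(sigma=0.0, alpha=1.0))
        rec = run_single_agent(base_policy, lev_task, 64, cfg, seed=1)
        for row in rec.rows:
            assert row["reward_shaped"] == pytest.approx(row["reward_raw"])

    def test_seeded_run_bit_identical(self, base_policy, lev_task, rl_cfg):
        rec1 = run_single_agent(base_policy, lev_task, 192, rl_cfg, seed=9)
        rec2 = run_single_agent(base_policy, lev_task, 192, rl_cfg, seed=9)
        assert rec1.rows == rec2.rows
        np.testing.assert_array_equal(rec1.trace.per_target_max, rec2.trace.per_target_max)

    def test_budget_consumed_exactly(self, base_policy, lev_task, rl_cfg):
        rec = run_single_agent(base_policy, lev_task, 200, rl_cfg, seed=2)
        assert len(rec.rows) == 200

    def test_df_never_rewards_duplicates(self, base_policy, lev_task):
        cfg = RLConfig(batch_size=32, replay_k=5, use_df=True, lr=3e-3)
        rec = run_single_agent(base_policy, lev_task, 320, cfg, seed=3)
        seen = set()
        for row in rec.rows:
            c = row["canonical"]
            if c is None:
                continue
            if c in seen:
                # a duplicate's training reward is zeroed, so its shaped
                # reward clip(0 + sigma*log_prior)^alpha is exactly 0
                assert row["reward_shaped"] == 0.0
            seen.add(c)
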