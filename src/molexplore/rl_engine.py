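"""REINFORCE-based test-time-training engine for the SMILES policy.

The optimizer is REINFORCE over whole generated sequences, with three
additions used throughout the experiments:

* **Prior-regularized reward reshaping** — the raw oracle reward R(τ) is
  reshaped to ``clip(R + σ · log π_prior(τ), 0)^α``, where π_prior is the
  frozen pretrained model.  The σ term regularizes the agent toward the
  prior; the exponent α steepens the gradients in the reshaped reward
  landscape; clipping keeps the reshaped reward non-negative.
* **Prioritized experience replay** — a bounded buffer of high-reward
  molecules, deduplicated by canonical SMILES, sampled without
  replacement with probability proportional to reward.  Replayed
  trajectories have their log-probability recomputed under the current
  policy before entering the loss.
* **Optional exploration mechanisms** — a diversity filter (DF) that
  zeroes the reward of any repeated canonical SMILES, and a random
  network distillation (RND) bonus for novel fingerprints, both applied
  to the reward *before* reshaping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import benchmark, chem_core, clm_policy, nn
from .benchmark import BudgetLedger, ScoreTrace, TaskSpec
from .clm_policy import Policy, TokenSequence
from .nn import Tensor

__all__ = [
    "ShapingConfig", "RLConfig", "Trajectory", "ReplayBuffer", "RNDState",
    "DFMemory", "AgentState", "RunRecord", "reshape_reward", "reinforce_loss",
    "buffer_insert", "buffer_sample", "rnd_bonus", "rnd_update",
    "apply_diversity_filter", "make_agent", "collect_batch", "update_agent",
    "rl_step", "run_single_agent",
]


# ---------------------------------------------------------------------------
# reward reshaping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShapingConfig:
    """Parameters of the reshaped reward clip(R + σ·log_prior, 0)^α."""

    sigma: float = 0.001
    alpha: float = 3.0
    clip_floor: float = 0.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")


def reshape_reward(reward: float, log_prior: float, cfg: ShapingConfig) -> float:
    """clip(R + σ·log_prior, floor 0)^α; identity at σ=0, α=1.

    Monotonically non-decreasing in R and always non-negative.  Reward
    bonuses may push R above 1, so only non-negativity of R is required.
    """
    if reward < 0:
        raise ValueError("raw reward must be non-negative")
    clipped = max(reward + cfg.sigma * log_prior, cfg.clip_floor)
    return float(clipped ** cfg.alpha)


# ---------------------------------------------------------------------------
# trajectories, replay, exploration state
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """One generated molecule with everything the optimizer needs."""

    seq: TokenSequence
    smiles: str
    canonical: str | None
    log_prob_agent: float
    log_prob_prior: float
    reward_raw: float
    reward_shaped: float


@dataclass
class ReplayBuffer:
    """Bounded, deduplicated store of high-reward molecules.

    One entry per canonical SMILES (the highest-reward sighting is
    kept); when over capacity the lowest-reward entry is evicted.
    """

    capacity: int = 100
    entries: dict[str, Trajectory] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, canonical: str) -> bool:
        return canonical in self.entries

    def insert(self, traj: Trajectory) -> None:
        if traj.canonical is None:
            return
        held = self.entries.get(traj.canonical)
        if held is None or traj.reward_raw > held.reward_raw:
            self.entries[traj.canonical] = traj
        if len(self.entries) > self.capacity:
            worst = min(self.entries, key=lambda c: self.entries[c].reward_raw)
            del self.entries[worst]

    def sample(self, k: int, rng: np.random.Generator) -> list[Trajectory]:
        """k sequential draws without replacement, probability proportional
        to reward at each draw; the whole buffer if k >= size.  All-zero
        rewards fall back to uniform draws."""
        items = list(self.entries.values())
        if k >= len(items):
            return items
        rewards = np.array([t.reward_raw for t in items])
        chosen: list[Trajectory] = []
        alive = list(range(len(items)))
        for _ in range(k):
            w = rewards[alive]
            total = w.sum()
            p = w / total if total > 0 else np.full(len(alive), 1.0 / len(alive))
            pick = int(rng.choice(len(alive), p=p))
            chosen.append(items[alive[pick]])
            alive.pop(pick)
        return chosen


def buffer_insert(buf: ReplayBuffer, traj: Trajectory) -> None:
    buf.insert(traj)


def buffer_sample(buf: ReplayBuffer, k: int, seed: int | np.random.Generator) -> list[Trajectory]:
    if len(buf) == 0:
        raise ValueError("cannot sample from an empty replay buffer")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return buf.sample(k, rng)


class RNDState:
    """Random network distillation: novelty bonus on fingerprints.

    A fixed random target network maps fingerprints to an embedding; a
    predictor network of the same shape is regressed toward it on every
    batch of visited states.  The squared prediction error — large for
    fingerprints unlike anything trained on — is normalized by running
    statistics (count-based Welford over all observed errors) and scaled
    into a reward bonus.  Repeated training on one input drives its
    bonus toward zero while the long-memory normalization keeps the
    scale of early errors.
    """

    N_LAYERS = 2

    def __init__(self, seed: int, embed_dim: int = 32, hidden: int = 64,
                 bonus_scale: float = 0.1, lr: float = 1e-3):
        rng = np.random.default_rng(seed)
        sizes = [chem_core.FP_BITS, hidden, embed_dim]
        self.target = nn.init_mlp_params(rng, sizes)
        self.predictor = nn.init_mlp_params(rng, sizes)
        for t in self.target.values():
            t.requires_grad = False  # immutable after init
        self.opt = nn.Adam(list(self.predictor.values()), lr=lr)
        self.bonus_scale = bonus_scale
        self._count = 0
        self._mean = 0.0
        self._m2 = 0.0

    def errors(self, fps: np.ndarray) -> np.ndarray:
        tgt = nn.mlp_forward_np(self.target, fps, self.N_LAYERS)
        pred = nn.mlp_forward_np(self.predictor, fps, self.N_LAYERS)
        return ((tgt - pred) ** 2).mean(axis=1)

    def bonus(self, fp: chem_core.Fingerprint) -> float:
        err = float(self.errors(fp.bits[None, :].astype(float))[0])
        if self._count < 2:
            return self.bonus_scale * err
        var = self._m2 / (self._count - 1)
        return self.bonus_scale * err / np.sqrt(var + 1e-8)

    def update(self, fps_batch: Sequence[chem_core.Fingerprint]) -> None:
        if not fps_batch:
            return
        fps = np.stack([fp.bits.astype(float) for fp in fps_batch])
        for e in self.errors(fps):  # Welford, before the gradient step
            self._count += 1
            delta = e - self._mean
            self._mean += delta / self._count
            self._m2 += delta * (e - self._mean)
        tgt = nn.mlp_forward_np(self.target, fps, self.N_LAYERS)
        pred = nn.mlp_forward(self.predictor, Tensor(fps), self.N_LAYERS)
        loss = ((pred - Tensor(tgt)) ** 2.0).mean()
        self.opt.zero_grad()
        loss.backward()
        self.opt.step()


def rnd_bonus(rnd: RNDState, fp: chem_core.Fingerprint) -> float:
    return rnd.bonus(fp)


def rnd_update(rnd: RNDState, fps_batch: Sequence[chem_core.Fingerprint]) -> None:
    rnd.update(fps_batch)


@dataclass
class DFMemory:
    """Canonical SMILES already rewarded once (diversity filter)."""

    seen: set[str] = field(default_factory=set)


def apply_diversity_filter(mem: DFMemory, canonical: str, reward: float) -> float:
    """First occurrence keeps its reward and is recorded; repeats get 0."""
    if canonical in mem.seen:
        return 0.0
    mem.seen.add(canonical)
    return reward


# ---------------------------------------------------------------------------
# the REINFORCE loss
# ---------------------------------------------------------------------------


def reinforce_loss(batch: Sequence[Trajectory], log_probs: Tensor | None = None):
    """−(1/|batch|) Σ reward_shaped(τ) · log π_θ(τ).

    With ``log_probs`` (a differentiable tensor recomputed under the
    current policy) the returned Tensor's gradient is the REINFORCE
    estimator; without it the stored agent log-probabilities give the
    scalar value.  All-zero shaped rewards give loss 0 and zero gradient.
    """
    if not batch:
        raise ValueError("empty trajectory batch")
    rewards = np.array([t.reward_shaped for t in batch])
    if log_probs is None:
        lps = np.array([t.log_prob_agent for t in batch])
        if not np.all(np.isfinite(lps)):
            raise FloatingPointError("non-finite log-probability in batch")
        return float(-(rewards * lps).mean())
    if not np.all(np.isfinite(log_probs.data)):
        raise FloatingPointError("non-finite log-probability in batch")
    return -((Tensor(rewards) * log_probs).mean())


# ---------------------------------------------------------------------------
# agents and the optimization step
# ---------------------------------------------------------------------------


@dataclass
class RLConfig:
    batch_size: int = 64
    replay_k: int = 10
    buffer_capacity: int = 100
    lr: float = 1e-3
    shaping: ShapingConfig = field(default_factory=ShapingConfig)
    use_df: bool = False
    use_rnd: bool = False
    rnd_bonus_scale: float = 0.1


@dataclass
class AgentState:
    """One RL agent: trainable policy, frozen prior, buffer, optimizer."""

    policy: Policy
    prior: Policy
    buffer: ReplayBuffer
    opt: nn.Adam
    rng: np.random.Generator
    df: DFMemory = field(default_factory=DFMemory)
    rnd: RNDState | None = None
    agent_id: int = 0


def make_agent(base_policy: Policy, cfg: RLConfig, seed: int, agent_id: int = 0) -> AgentState:
    """Clone the pretrained policy into a fresh trainable agent.

    The prior is the base policy itself, frozen at RL start.
    """
    policy = base_policy.clone()
    rnd = RNDState(seed + 1, bonus_scale=cfg.rnd_bonus_scale) if cfg.use_rnd else None
    return AgentState(
        policy=policy,
        prior=base_policy,
        buffer=ReplayBuffer(capacity=cfg.buffer_capacity),
        opt=nn.Adam(policy.parameters(), lr=cfg.lr),
        rng=np.random.default_rng(seed),
        df=DFMemory(),
        rnd=rnd,
        agent_id=agent_id,
    )


@dataclass
class RunRecord:
    """Full ledger of a run: every sample, the trace and final scores."""

    task_name: str
    rows: list[dict] = field(default_factory=list)
    trace: ScoreTrace | None = None
    iterations: int = 0

    def molecules(self) -> list[str]:
        """Unique valid canonical SMILES in first-seen order."""
        seen: dict[str, None] = {}
        for r in self.rows:
            c = r["canonical"]
            if c is not None and c not in seen:
                seen[c] = None
        return list(seen)

    def summary(self, sediv_seed: int = 0) -> dict:
        mols = self.molecules()
        out = {
            "task": self.task_name,
            "n_sampled": len(self.rows),
            "n_valid": sum(1 for r in self.rows if r["canonical"] is not None),
            "n_unique": len(mols),
            "iterations": self.iterations,
            "per_target_max": [float(x) for x in self.trace.per_target_max],
            "task_score": benchmark.task_score(self.trace),
        }
        out["sediv"] = (
            benchmark.sphere_exclusion_diversity(mols, seed=sediv_seed) if mols else 0.0
        )
        return out


def collect_batch(
    agent: AgentState,
    task: TaskSpec,
    ledger: BudgetLedger,
    trace: ScoreTrace,
    cfg: RLConfig,
    record: RunRecord | None = None,
    bonus_fn: Callable[[str], float] | None = None,
) -> list[Trajectory]:
    """Sample one (budget-truncated) batch, score it against the oracle,
    apply exploration bonuses / the diversity filter, and reshape rewards.

    Charges the budget for every sampled string, valid or not, and folds
    the similarities into the score trace."""
    n = min(cfg.batch_size, ledger.remaining)
    if n == 0:
        return []
    samples = agent.policy.sample_batch(n, agent.rng)
    seqs = [s for s, _ in samples]
    prior_lps = agent.prior.sequence_log_probs_np(seqs)
    trajs: list[Trajectory] = []
    rnd_fps: list[chem_core.Fingerprint] = []
    for (seq, lp_agent), lp_prior in zip(samples, prior_lps):
        smiles = clm_policy.detokenize(seq, agent.policy.vocab)
        sims = benchmark.record_sample(ledger, trace, smiles, task)
        reward_raw = float(sims.max())
        canonical = chem_core.validate_and_canonicalize(smiles)
        r = reward_raw
        if canonical is not None:
            if agent.rnd is not None:
                fp = chem_core.ecfp4(canonical)
                r += agent.rnd.bonus(fp)
                rnd_fps.append(fp)
            if bonus_fn is not None:
                r += bonus_fn(canonical)
            if cfg.use_df:
                r = apply_diversity_filter(agent.df, canonical, r)
        shaped = reshape_reward(r, float(lp_prior), cfg.shaping)
        traj = Trajectory(seq, smiles, canonical, float(lp_agent), float(lp_prior),
                          reward_raw, shaped)
        trajs.append(traj)
        if record is not None:
            record.rows.append({
                "iteration": record.iterations,
                "agent": agent.agent_id,
                "smiles": smiles,
                "canonical": canonical,
                "valid": canonical is not None,
                "reward_raw": reward_raw,
                "reward_shaped": shaped,
                "sims": [float(x) for x in sims],
            })
    if agent.rnd is not None:
        agent.rnd.update(rnd_fps)
    return trajs


def update_agent(
    agent: AgentState,
    onpolicy: Sequence[Trajectory],
    cfg: RLConfig,
    aux_loss_fn: Callable[[Tensor, list[TokenSequence]], Tensor | float] | None = None,
    shaped_override: np.ndarray | None = None,
) -> float:
    """One gradient update: replay draw, log-prob recomputation, REINFORCE.

    ``shaped_override`` replaces the on-policy shaped rewards (used by the
    population-baseline strategy); ``aux_loss_fn`` receives the on-policy
    differentiable log-probs and sequences and returns an already-weighted
    auxiliary loss term.
    """
    if not onpolicy:
        return 0.0
    replayed = agent.buffer.sample(cfg.replay_k, agent.rng) if (
        cfg.replay_k > 0 and len(agent.buffer) > 0
    ) else []
    batch = list(onpolicy) + replayed
    rewards = np.array([t.reward_shaped for t in batch])
    if shaped_override is not None:
        rewards[: len(onpolicy)] = shaped_override
    # off-policy correction by recomputation: all log-probs taken under
    # the *current* policy
    log_probs = agent.policy.sequence_log_probs_graph([t.seq for t in batch])
    loss = -((Tensor(rewards) * log_probs).mean())
    if aux_loss_fn is not None:
        if replayed:  # aux terms act on the on-policy states only
            onpolicy_lp = agent.policy.sequence_log_probs_graph([t.seq for t in onpolicy])
        else:
            onpolicy_lp = log_probs
        aux = aux_loss_fn(onpolicy_lp, [t.seq for t in onpolicy])
        if isinstance(aux, Tensor) or aux != 0.0:
            loss = loss + aux
    agent.opt.zero_grad()
    loss.backward()
    agent.opt.step()
    return float(loss.data)


def rl_step(
    agent: AgentState,
    task: TaskSpec,
    ledger: BudgetLedger,
    trace: ScoreTrace,
    cfg: RLConfig,
    record: RunRecord | None = None,
) -> list[Trajectory]:
    """One full iteration: sample, score, insert into replay, update."""
    trajs = collect_batch(agent, task, ledger, trace, cfg, record)
    for t in trajs:
        agent.buffer.insert(t)
    update_agent(agent, trajs, cfg)
    if record is not None:
        record.iterations += 1
    if trace is not None:
        trace.snapshot()
    return trajs


def run_single_agent(
    base_policy: Policy,
    task: TaskSpec,
    budget: int,
    cfg: RLConfig,
    seed: int,
) -> RunRecord:
    """Optimize one agent against one task until the budget is spent."""
    agent = make_agent(base_policy, cfg, seed)
    ledger = BudgetLedger(budget)
    trace = ScoreTrace(task.n_trace)
    record = RunRecord(task_name=task.name, trace=trace)
    while ledger.remaining > 0:
        rl_step(agent, task, ledger, trace, cfg, record)
    return record
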