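"""Population management and cooperative multi-agent strategies.

A population of N REINFORCE agents attacks one task, each with its own
molecule budget, scheduled round-robin (one batch per agent per cycle)
and scored on the *union* of all agents' molecules.  Strategies modify
how agents interact:

* ``independent`` — no interaction (the scaling baseline).
* ``purge`` — replay buffers kept mutually exclusive: a molecule enters
  agent i's buffer only if no other agent's buffer holds it.
* ``shared`` — one replay buffer for the whole population; expected to
  act as a convergence (negative) control.
* ``shared_bonus`` — shared buffer plus a reward bonus for molecules not
  yet in it.
* ``noise`` — Gaussian parameter noise applied to each agent at
  population init.
* ``rnd`` — one random-network-distillation novelty bonus shared by all
  agents.
* ``ent_s`` / ``ce_s`` — specialization by minimizing the entropy /
  cross-entropy of the per-state agent-confidence distribution (softmax
  over agents of sequence log-probability).
* ``diff_s`` — widen the gap between an agent's uncertainty
  (per-token-averaged NLL) on its own states versus the population's.
* ``diff_n`` — maximize the log-probability margin of an agent's
  on-policy states over the other agents.
* ``dvd`` — diversity via determinant: maximize the log-determinant of
  the RBF-kernel matrix of per-agent behavior embeddings (log-probs on a
  frozen probe set).
* ``popnorm`` — subtract the population-mean return as a cross-agent
  baseline.

With zeroed coefficients (λ = 0, bonus = 0, noise σ = 0) every strategy
reduces bit-identically to ``independent``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from . import benchmark, chem_core, nn, rl_engine
from .benchmark import BudgetLedger, ScoreTrace, TaskSpec
from .clm_policy import Policy, TokenSequence
from .nn import Tensor
from .rl_engine import AgentState, RLConfig, ReplayBuffer, RNDState, RunRecord, Trajectory

STRATEGIES = (
    "independent", "purge", "shared", "shared_bonus", "noise", "rnd",
    "ent_s", "ce_s", "diff_s", "diff_n", "dvd", "popnorm",
)

SPECIALIZATION_KINDS = ("ent_s", "ce_s", "diff_s", "diff_n")


@dataclass
class PopulationConfig:
    strategy: str = "independent"
    noise_sigma: float = 0.01     # parameter-noise scale at init
    bonus_b: float = 0.1          # shared-buffer novelty bonus
    aux_weight: float = 0.1       # λ on auxiliary losses
    probe_size: int = 32          # behavior-embedding probe sequences
    dvd_floor: float = -30.0      # log-det floor keeping losses finite

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; valid: {', '.join(STRATEGIES)}"
            )


@dataclass
class PopulationState:
    agents: list[AgentState]
    cfg: PopulationConfig
    rl_cfg: RLConfig
    shared_buffer: ReplayBuffer | None = None
    probe_set: list[TokenSequence] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.agents)


def init_population(
    n: int,
    strategy: str,
    base: Policy,
    rl_cfg: RLConfig,
    pop_cfg: PopulationConfig | None = None,
    noise_sigma: float | None = None,
    seed: int = 0,
) -> PopulationState:
    """Build N agents from one pretrained policy, wired per strategy.

    Agent i's RNG seed is ``seed + i``; parameter noise (strategy
    ``noise``) and the DvD probe set draw from separate seeded streams so
    that zero-coefficient configurations leave the sampling streams
    untouched.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    pop_cfg = pop_cfg or PopulationConfig(strategy=strategy)
    if pop_cfg.strategy != strategy:
        pop_cfg = PopulationConfig(**{**vars(pop_cfg), "strategy": strategy})
    if noise_sigma is not None:
        pop_cfg = PopulationConfig(**{**vars(pop_cfg), "noise_sigma": noise_sigma})
    agents = [rl_engine.make_agent(base, rl_cfg, seed + i, agent_id=i) for i in range(n)]
    pop = PopulationState(agents=agents, cfg=pop_cfg, rl_cfg=rl_cfg)
    if strategy == "noise":
        for i, agent in enumerate(agents):
            agent.policy.perturb(pop_cfg.noise_sigma, np.random.default_rng([seed + i, 91]))
    if strategy in ("shared", "shared_bonus"):
        pop.shared_buffer = ReplayBuffer(capacity=rl_cfg.buffer_capacity)
        for agent in agents:
            agent.buffer = pop.shared_buffer
    if strategy == "rnd":
        shared_rnd = RNDState(seed + 101, bonus_scale=rl_cfg.rnd_bonus_scale)
        for agent in agents:
            agent.rnd = shared_rnd
    if strategy == "dvd":
        probe_rng = np.random.default_rng([seed, 555])
        pop.probe_set = [s for s, _ in base.sample_batch(pop_cfg.probe_size, probe_rng)]
    return pop


# ---------------------------------------------------------------------------
# strategy primitives
# ---------------------------------------------------------------------------


def purge_insert(pop: PopulationState, agent_i: int, traj: Trajectory) -> bool:
    """Insert into agent i's buffer only if no other buffer holds the
    molecule; returns whether it was inserted."""
    if traj.canonical is None:
        return False
    for j, other in enumerate(pop.agents):
        if j != agent_i and traj.canonical in other.buffer:
            return False
    pop.agents[agent_i].buffer.insert(traj)
    return True


def shared_bonus(pop: PopulationState, canonical: str) -> float:
    """Novelty bonus for molecules absent from the shared buffer."""
    if pop.shared_buffer is None:
        raise ValueError("shared_bonus requires a shared buffer")
    return 0.0 if canonical in pop.shared_buffer else pop.cfg.bonus_b


def popnorm_adjust(returns_by_agent: list[np.ndarray]) -> list[np.ndarray]:
    """Subtract the population-mean return of the iteration from every
    agent's per-state returns; the adjusted returns average to zero."""
    if not returns_by_agent:
        return []
    mean = float(np.concatenate(returns_by_agent).mean())
    return [np.asarray(r, dtype=float) - mean for r in returns_by_agent]


def specialization_loss(
    kind: str,
    pop: PopulationState,
    agent_i: int,
    pop_states: list[TokenSequence],
    origins: np.ndarray,
) -> Tensor | float:
    """Auxiliary specialization loss for agent i (differentiable w.r.t.
    agent i's parameters; other agents enter as constants).

    ``pop_states`` are the on-policy trajectories collected across the
    population this iteration; ``origins[s]`` is the agent that generated
    state s.  Per-state agent confidence is the softmax over agents of
    total sequence log-probability; "policy uncertainty" is the
    per-token-averaged NLL.
    """
    if kind not in SPECIALIZATION_KINDS:
        raise ValueError(f"unknown specialization kind {kind!r}")
    if pop.n == 1 or not pop_states:
        return 0.0
    agent = pop.agents[agent_i]
    own_mask = np.asarray(origins) == agent_i

    if kind in ("ent_s", "ce_s"):
        lp_i = agent.policy.sequence_log_probs_graph(pop_states).reshape(-1, 1)
        cols: list[Tensor] = []
        for j, other in enumerate(pop.agents):
            if j == agent_i:
                cols.append(lp_i)
            else:
                cols.append(Tensor(
                    other.policy.sequence_log_probs_np(pop_states).reshape(-1, 1)
                ))
        logits = nn.concat(cols, axis=1)                     # (S, N)
        log_c = nn.log_softmax(logits, axis=1)
        if kind == "ent_s":
            ent = -(log_c.exp() * log_c).sum(axis=1)
            return ent.mean()
        return -(log_c.select(np.asarray(origins))).mean()   # ce_s

    lengths = np.array([max(s.n_predicted, 1) for s in pop_states], dtype=float)
    lp_i = agent.policy.sequence_log_probs_graph(pop_states)
    nll_i = -(lp_i * Tensor(1.0 / lengths))                  # per-token NLL

    if kind == "diff_s":
        if own_mask.all() or not own_mask.any():
            return 0.0
        own = (nll_i * Tensor(own_mask.astype(float))).sum() * (1.0 / own_mask.sum())
        rest = (nll_i * Tensor((~own_mask).astype(float))).sum() * (1.0 / (~own_mask).sum())
        return own - rest

    # diff_n: maximize the on-policy log-prob margin over the other agents
    if not own_mask.any():
        return 0.0
    own_states = [s for s, m in zip(pop_states, own_mask) if m]
    lp_own = agent.policy.sequence_log_probs_graph(own_states)
    margin = lp_own.mean()
    const = 0.0
    for j, other in enumerate(pop.agents):
        if j != agent_i:
            const += float(other.policy.sequence_log_probs_np(own_states).mean())
    return -(margin - Tensor(const / (pop.n - 1)))


def behavior_embedding(policy: Policy, probe_set: Sequence[TokenSequence]) -> np.ndarray:
    """Sequence log-probabilities over a frozen probe set."""
    return policy.sequence_log_probs_np(list(probe_set))


def _median_bandwidth(embeddings: np.ndarray) -> float:
    dists = [
        float(np.linalg.norm(embeddings[a] - embeddings[b]))
        for a, b in combinations(range(len(embeddings)), 2)
    ]
    med = float(np.median(dists)) if dists else 1.0
    return med if med > 0 else 1.0


def dvd_score(
    embeddings: np.ndarray,
    kernel_bandwidth: float | None = None,
    floor: float = -30.0,
) -> float:
    """Log-determinant (floored) of the RBF kernel matrix of behavior
    embeddings; invariant under agent permutation; at the floor when two
    embeddings coincide."""
    embeddings = np.asarray(embeddings, dtype=float)
    if len(embeddings) < 2:
        raise ValueError("dvd_score needs at least two embeddings")
    h = kernel_bandwidth if kernel_bandwidth is not None else _median_bandwidth(embeddings)
    sq = ((embeddings[:, None, :] - embeddings[None, :, :]) ** 2).sum(axis=2)
    K = np.exp(-sq / (2.0 * h * h))
    sign, ld = np.linalg.slogdet(K)
    if sign <= 0:  # numerically singular: coincident embeddings
        return floor
    return float(max(ld, floor))


def _dvd_loss(pop: PopulationState, agent_i: int) -> Tensor | float:
    """−dvd on the kernel matrix with agent i's embedding differentiable."""
    const_emb = np.stack([
        behavior_embedding(a.policy, pop.probe_set) for a in pop.agents
    ])
    h = _median_bandwidth(const_emb)
    floor = pop.cfg.dvd_floor
    value = dvd_score(const_emb, kernel_bandwidth=h, floor=floor)
    if value <= floor:  # at the floor the score is constant: no gradient
        return -floor
    emb_i = pop.agents[agent_i].policy.sequence_log_probs_graph(list(pop.probe_set))
    rows = [
        emb_i.reshape(1, -1) if j == agent_i else Tensor(const_emb[j].reshape(1, -1))
        for j in range(pop.n)
    ]
    E = nn.concat(rows, axis=0)                              # (N, P)
    s = (E * E).sum(axis=1, keepdims=True)                   # (N, 1)
    sq = s + s.T - 2.0 * (E @ E.T)
    K = sq * (-1.0 / (2.0 * h * h))
    K = K.exp() + Tensor(1e-8 * np.eye(pop.n))
    return -(K.logdet())


# ---------------------------------------------------------------------------
# the cooperative run loop
# ---------------------------------------------------------------------------


@dataclass
class PopulationRunRecord:
    strategy: str
    records: list[RunRecord]
    union_trace: ScoreTrace
    task_name: str

    def union_molecules(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            for m in rec.molecules():
                seen.setdefault(m, None)
        return list(seen)

    def union_summary(self, sediv_seed: int = 0) -> dict:
        mols = self.union_molecules()
        return {
            "task": self.task_name,
            "strategy": self.strategy,
            "n_agents": len(self.records),
            "per_target_max": [float(x) for x in self.union_trace.per_target_max],
            "task_score": benchmark.task_score(self.union_trace),
            "n_unique_union": len(mols),
            "sediv": benchmark.sphere_exclusion_diversity(mols, seed=sediv_seed)
            if mols else 0.0,
        }


def mean_interagent_buffer_tanimoto(pop: PopulationState) -> float:
    """Mean pairwise Tanimoto between the buffer contents of distinct
    agents (a convergence diagnostic; NaN-free: empty pairs contribute 0)."""
    fps = []
    for agent in pop.agents:
        fps.append([chem_core.ecfp4(c) for c in agent.buffer.entries])
    vals = []
    for a, b in combinations(range(pop.n), 2):
        if not fps[a] or not fps[b]:
            continue
        pair = [chem_core.tanimoto(x, y) for x in fps[a] for y in fps[b]]
        vals.append(float(np.mean(pair)))
    return float(np.mean(vals)) if vals else 0.0


def run_cooperative(
    pop: PopulationState,
    task: TaskSpec,
    budget_per_agent: int,
    sediv_seed: int = 0,
) -> PopulationRunRecord:
    """Round-robin population optimization of one task.

    Each cycle every agent with budget left samples one batch (collect
    phase), buffers are filled per strategy, and every agent takes one
    gradient step with its strategy's reward adjustment or auxiliary
    loss (update phase).  The union trace scores the whole population.
    """
    cfg, rl_cfg = pop.cfg, pop.rl_cfg
    strategy = cfg.strategy
    ledgers = [BudgetLedger(budget_per_agent) for _ in pop.agents]
    traces = [ScoreTrace(task.n_trace) for _ in pop.agents]
    union_trace = ScoreTrace(task.n_trace)
    records = [RunRecord(task_name=task.name) for _ in pop.agents]
    for rec, tr in zip(records, traces):
        rec.trace = tr

    bonus_fn = (lambda c: shared_bonus(pop, c)) if strategy == "shared_bonus" else None

    while any(l.remaining > 0 for l in ledgers):
        batches: list[list[Trajectory]] = []
        for i, agent in enumerate(pop.agents):
            row0 = len(records[i].rows)
            trajs = rl_engine.collect_batch(
                agent, task, ledgers[i], traces[i], rl_cfg, records[i], bonus_fn=bonus_fn
            )
            for row in records[i].rows[row0:]:
                union_trace.update(np.asarray(row["sims"]))
            batches.append(trajs)

        for i, trajs in enumerate(batches):
            for t in trajs:
                if strategy == "purge":
                    purge_insert(pop, i, t)
                else:
                    pop.agents[i].buffer.insert(t)

        overrides: list[np.ndarray | None] = [None] * pop.n
        if strategy == "popnorm":
            adjusted = popnorm_adjust(
                [np.array([t.reward_shaped for t in b]) for b in batches if b]
            )
            it = iter(adjusted)
            overrides = [next(it) if b else None for b in batches]

        pop_states: list[TokenSequence] = []
        origins: list[int] = []
        if strategy in SPECIALIZATION_KINDS:
            for i, trajs in enumerate(batches):
                pop_states.extend(t.seq for t in trajs)
                origins.extend([i] * len(trajs))

        for i, agent in enumerate(pop.agents):
            if not batches[i]:
                continue
            aux_fn = None
            if strategy in SPECIALIZATION_KINDS and cfg.aux_weight != 0.0:
                kind, lam = strategy, cfg.aux_weight
                aux_fn = (
                    lambda lp, seqs, _i=i: lam * specialization_loss(
                        kind, pop, _i, pop_states, np.array(origins)
                    )
                )
            elif strategy == "dvd" and cfg.aux_weight != 0.0:
                aux_fn = lambda lp, seqs, _i=i: cfg.aux_weight * _dvd_loss(pop, _i)
            rl_engine.update_agent(
                agent, batches[i], rl_cfg, aux_loss_fn=aux_fn,
                shaped_override=overrides[i],
            )
            records[i].iterations += 1
            traces[i].snapshot()
        union_trace.snapshot()

    return PopulationRunRecord(
        strategy=strategy, records=records, union_trace=union_trace, task_name=task.name
    )
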