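"""Test-time-training scaling protocols and replicate aggregation.

Two scaling axes are compared on a rediscovery task:

* **agent scaling** — N independent RL agents, each with its own molecule
  budget, scored on the union of everything the population generated;
* **budget scaling** — a single agent whose budget grows, optionally with
  an RND exploration bonus or a diversity filter.

Each setting is replicated with deterministically derived seeds
(replicate seed = base_seed + 1000·replicate, agent seed = replicate
seed + agent index), so agent populations are *nested*: the agents of an
N-agent run are the first N agents of a 2N-agent run, which makes the
union score exactly non-decreasing in N within a replicate.  Benchmark
score versus log2(N) is summarized by a least-squares log-linear fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import benchmark, rl_engine
from .benchmark import TaskSpec
from .clm_policy import Policy
from .rl_engine import RLConfig, RunRecord

BUDGET_VARIANTS = ("plain", "rnd", "df")


@dataclass
class ScalingConfig:
    """Grid of scaling settings.

    Defaults are desk-scale (1–8 agents, 1,000-molecule budgets); the
    larger published-style grids (up to 128 agents, 10,000 per agent)
    remain expressible by configuration.
    """

    agent_counts: tuple[int, ...] = (1, 2, 4, 8)
    budget_per_agent: int = 1000
    budgets: tuple[int, ...] = (1000, 2000, 4000)
    replicates: int = 5
    base_seed: int = 0
    strategy: str = "independent"

    def __post_init__(self):
        if any(n < 1 for n in self.agent_counts) or any(b < 1 for b in self.budgets):
            raise ValueError("agent counts and budgets must be positive")


def replicate_seed(base_seed: int, r: int) -> int:
    return base_seed + 1000 * r


def agent_seed(rep_seed: int, i: int) -> int:
    return rep_seed + i


def union_score(records: list[RunRecord]) -> tuple[float, np.ndarray]:
    """Product-of-max score over the union of several runs' molecules."""
    maxes = np.max(np.stack([r.trace.per_target_max for r in records]), axis=0)
    return float(np.prod(maxes)), maxes


def scale_agents_experiment(
    task: TaskSpec,
    base_policy: Policy,
    cfg: ScalingConfig,
    rl_cfg: RLConfig | None = None,
) -> pd.DataFrame:
    """Independent-agent scaling: one row per (N, replicate).

    Within a replicate the maximal population is run once and smaller
    populations are scored as nested prefixes — identical to running
    them separately because agent seeds depend only on the replicate and
    the agent index.
    """
    rl_cfg = rl_cfg or RLConfig()
    n_max = max(cfg.agent_counts)
    rows = []
    for r in range(cfg.replicates):
        rseed = replicate_seed(cfg.base_seed, r)
        records = [
            rl_engine.run_single_agent(
                base_policy, task, cfg.budget_per_agent, rl_cfg, agent_seed(rseed, i)
            )
            for i in range(n_max)
        ]
        for n in cfg.agent_counts:
            score, maxes = union_score(records[:n])
            mols: dict[str, None] = {}
            for rec in records[:n]:
                for m in rec.molecules():
                    mols.setdefault(m, None)
            sediv = (
                benchmark.sphere_exclusion_diversity(list(mols), seed=rseed)
                if mols else 0.0
            )
            rows.append({
                "task": task.name, "setting": n, "replicate": r,
                "score": score, "sediv": sediv,
                **{f"max_t{j}": float(m) for j, m in enumerate(maxes)},
            })
    return pd.DataFrame(rows)


def scale_budget_experiment(
    task: TaskSpec,
    base_policy: Policy,
    cfg: ScalingConfig,
    rl_cfg: RLConfig | None = None,
    variant: str = "plain",
) -> pd.DataFrame:
    """Single-agent budget scaling, optionally with RND or a DF."""
    if variant not in BUDGET_VARIANTS:
        raise ValueError(f"variant must be one of {BUDGET_VARIANTS}")
    rl_cfg = rl_cfg or RLConfig()
    rl_cfg = replace(rl_cfg, use_rnd=variant == "rnd", use_df=variant == "df")
    rows = []
    for budget in cfg.budgets:
        for r in range(cfg.replicates):
            rseed = replicate_seed(cfg.base_seed, r)
            rec = rl_engine.run_single_agent(
                base_policy, task, budget, rl_cfg, agent_seed(rseed, 0)
            )
            summ = rec.summary(sediv_seed=rseed)
            rows.append({
                "task": task.name, "setting": budget, "replicate": r,
                "variant": variant, "score": summ["task_score"],
                "sediv": summ["sediv"],
                **{f"max_t{j}": m for j, m in enumerate(summ["per_target_max"])},
            })
    return pd.DataFrame(rows)


def fit_log_linear(scores: dict[int, float] | pd.Series) -> tuple[float, float, float]:
    """Least-squares fit of score against log2(N): (slope, intercept, R²)."""
    if isinstance(scores, pd.Series):
        scores = scores.to_dict()
    if len(scores) < 3:
        raise ValueError("log-linear fit needs at least 3 distinct settings")
    ns = np.array(sorted(scores))
    ys = np.array([scores[n] for n in ns], dtype=float)
    res = stats.linregress(np.log2(ns), ys)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def aggregate(results: pd.DataFrame, by: tuple[str, ...] = ("task", "setting")) -> pd.DataFrame:
    """Mean and sample standard deviation of score (and SEDiv) per setting.

    Single-replicate settings report a standard deviation of 0.
    """
    cols = [c for c in ("score", "sediv") if c in results.columns]
    agg = results.groupby(list(by))[cols].agg(["mean", "std"])
    agg.columns = [f"{c}_{s}" for c, s in agg.columns]
    for c in cols:
        agg[f"{c}_std"] = agg[f"{c}_std"].fillna(0.0)
    return agg.reset_index()


def compare_strategies(
    scores_by_strategy: dict[str, list[float]], baseline: str = "independent"
) -> pd.DataFrame:
    """One-tailed two-sample t-tests (strategy > baseline) with a
    Bonferroni correction over the tested strategies."""
    if baseline not in scores_by_strategy:
        raise ValueError(f"baseline {baseline!r} missing from scores")
    base = scores_by_strategy[baseline]
    names = [s for s in scores_by_strategy if s != baseline]
    rows = []
    for name in names:
        t, p = stats.ttest_ind(scores_by_strategy[name], base, alternative="greater")
        rows.append({
            "strategy": name,
            "mean": float(np.mean(scores_by_strategy[name])),
            "baseline_mean": float(np.mean(base)),
            "t_stat": float(t),
            "p_value": float(p),
            "p_bonferroni": float(min(p * len(names), 1.0)),
        })
    return pd.DataFrame(rows)


def run_benchmark_suite(
    tasks: list[TaskSpec],
    base_policy: Policy,
    budget: int,
    rl_cfg: RLConfig | None = None,
    base_seed: int = 0,
    replicates: int = 1,
) -> pd.DataFrame:
    """Single-agent baseline over a task suite: one row per
    (task, replicate) plus the benchmark sum is their per-replicate sum."""
    rl_cfg = rl_cfg or RLConfig()
    rows = []
    for r in range(replicates):
        rseed = replicate_seed(base_seed, r)
        for task in tasks:
            rec = rl_engine.run_single_agent(
                base_policy, task, budget, rl_cfg, agent_seed(rseed, 0)
            )
            summ = rec.summary(sediv_seed=rseed)
            rows.append({
                "task": task.name, "replicate": r,
                "score": summ["task_score"], "sediv": summ["sediv"],
            })
    return pd.DataFrame(rows)
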