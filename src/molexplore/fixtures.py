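"""Synthetic pretraining corpora and toy multi-target rediscovery tasks.

Real rediscovery benchmarks pair a drug-like pretraining corpus with
sets of structurally dissimilar co-active drug candidates.  This module
generates seeded stand-ins at desk scale: a grammar-based toy SMILES
corpus (chains, branches and rings over C/N/O, valid by construction)
and tasks whose targets are drawn from the corpus under an explicit
pairwise-dissimilarity cap, then *excluded* from the returned
pretraining split — rediscovery, not recall.

The grammar builds molecules top-down from valid fragments, so no
rejection loop on the chemistry toolkit is needed; validity is still
asserted for every emitted string.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import chem_core
from .benchmark import TaskSpec


@dataclass
class CorpusSpec:
    """Grammar parameters of the toy corpus.

    ``max_heavy_atoms`` bounds molecule size; ``branch_prob`` and
    ``ring_prob`` control how often branches and (aromatic or saturated)
    rings appear.  Emission is deterministic per seed.
    """

    size: int = 1000
    max_heavy_atoms: int = 12
    atoms: tuple[str, ...] = ("C", "N", "O")
    branch_prob: float = 0.3
    ring_prob: float = 0.3
    seed: int = 0


_MAX_ATTEMPT_FACTOR = 100  # attempts per requested molecule before giving up


def _chain(rng: np.random.Generator, spec: CorpusSpec, budget: list[int], depth: int) -> str:
    """A linear heavy-atom chain with optional single branches off carbons."""
    out: list[str] = []
    length = int(rng.integers(1, 5))
    # bias toward carbon, as in drug-like molecules
    weights = np.array([3.0 if a == "C" else 1.0 for a in spec.atoms])
    weights /= weights.sum()
    for _ in range(length):
        if budget[0] <= 0:
            break
        atom = str(rng.choice(list(spec.atoms), p=weights))
        budget[0] -= 1
        out.append(atom)
        if atom == "C" and depth < 2 and budget[0] > 0 and rng.random() < spec.branch_prob:
            sub = _chain(rng, spec, budget, depth + 1)
            if sub:
                out.append(f"({sub})")
    return "".join(out)


def generate_toy_molecule(rng: np.random.Generator, spec: CorpusSpec) -> str:
    """One valid SMILES from the fragment grammar."""
    budget = [int(rng.integers(2, spec.max_heavy_atoms + 1))]
    if budget[0] >= 7 and rng.random() < spec.ring_prob:
        budget[0] -= 6
        sub = _chain(rng, spec, budget, 1) or "C"
        core = "c1ccc({})cc1" if rng.random() < 0.5 else "C1CCC({})CC1"
        return core.format(sub)
    return _chain(rng, spec, budget, 0) or "C"


def generate_toy_corpus(spec: CorpusSpec) -> list[str]:
    """``size`` distinct valid molecules (distinct canonical forms).

    Raises if the grammar cannot produce enough distinct molecules —
    the requested size exceeds the (approximately) enumerable space.
    """
    if spec.size < 1:
        raise ValueError("corpus size must be >= 1")
    rng = np.random.default_rng(spec.seed)
    out: list[str] = []
    seen: set[str] = set()
    for _ in range(_MAX_ATTEMPT_FACTOR * spec.size):
        s = generate_toy_molecule(rng, spec)
        c = chem_core.validate_and_canonicalize(s)
        if c is None:  # grammar guarantees validity; fail loudly if not
            raise AssertionError(f"grammar emitted invalid SMILES: {s!r}")
        if c not in seen:
            seen.add(c)
            out.append(s)
        if len(out) == spec.size:
            return out
    raise ValueError(
        f"could not generate {spec.size} distinct molecules; "
        "the grammar space is too small for this spec"
    )


def generate_toy_task(
    corpus: list[str],
    n_targets: int,
    max_pairwise_sim: float = 0.3,
    oracle_kind: str = "levenshtein",
    seed: int = 0,
    name: str | None = None,
) -> tuple[TaskSpec, list[str]]:
    """A rediscovery task with structurally dissimilar targets.

    Targets are picked greedily from a seeded shuffle of the corpus so
    that every pair has ECFP4 Tanimoto <= ``max_pairwise_sim``, then
    removed from the returned pretraining split.  Raises (suggesting a
    looser cutoff) when the constraint cannot be met.
    """
    if n_targets < 2:
        raise ValueError("rediscovery tasks need at least 2 targets")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    chosen: list[str] = []
    chosen_fps: list[chem_core.Fingerprint] = []
    for idx in order:
        c = chem_core.validate_and_canonicalize(corpus[idx])
        if c is None or c in chosen:
            continue
        fp = chem_core.ecfp4(c)
        if all(chem_core.tanimoto(fp, f) <= max_pairwise_sim for f in chosen_fps):
            chosen.append(c)
            chosen_fps.append(fp)
        if len(chosen) == n_targets:
            break
    if len(chosen) < n_targets:
        raise ValueError(
            f"only found {len(chosen)}/{n_targets} targets with pairwise "
            f"Tanimoto <= {max_pairwise_sim}; try a looser cutoff"
        )
    task = TaskSpec(
        name=name or f"toy-{n_targets}t-s{seed}",
        targets=chosen,
        oracle_kind=oracle_kind,
    )
    target_set = set(task.targets)
    split = [m for m in corpus if chem_core.validate_and_canonicalize(m) not in target_set]
    return task, split


# Desk-scale study conditions: a 600-molecule corpus, a small 1-layer GRU
# and a pretraining protocol that reaches >= ~95% sample validity on the
# toy grammar.  The RL fine-tuning learning rate matches the pretraining
# one.  Paper-style scales (bigger nets, 10k budgets, up to 128 agents)
# remain plain configuration.
DESK_CORPUS_SIZE = 600
DESK_POLICY = dict(embedding_size=32, hidden_size=64, num_layers=1, max_len=60)
DESK_PRETRAIN = dict(epochs=50, batch_size=64, lr=3e-3)
DESK_RL_LR = 3e-3


def pretrained_toy_policy(corpus: list[str], seed: int = 0):
    """Build and pretrain the desk-scale policy on a toy corpus."""
    from . import clm_policy

    vocab = clm_policy.build_vocabulary(corpus)
    policy = clm_policy.Policy(
        vocab, clm_policy.PolicyConfig(**DESK_POLICY), seed=seed
    )
    clm_policy.pretrain(policy, corpus, seed=seed, **DESK_PRETRAIN)
    return policy


SUITE_TARGET_COUNTS = (2, 3, 3, 4)


def toy_benchmark_suite(
    corpus: list[str],
    oracle_kind: str = "levenshtein",
    max_pairwise_sim: float = 0.3,
    seed: int = 0,
) -> tuple[list[TaskSpec], list[str]]:
    """Four toy tasks with 2, 3, 3 and 4 targets and one pretraining split.

    Target sets are disjoint across tasks and all targets are excluded
    from the split.
    """
    tasks: list[TaskSpec] = []
    pool = list(corpus)
    for k, n in enumerate(SUITE_TARGET_COUNTS):
        task, pool = generate_toy_task(
            pool, n, max_pairwise_sim, oracle_kind, seed=seed + k,
            name=f"toy{k}-{n}t",
        )
        tasks.append(task)
    return tasks, pool
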