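"""Shared fixtures: one toy corpus, one pretrained policy, one 2-target task.

The expensive pieces (corpus generation, pretraining) are session-scoped
and deterministic, so every test sees the same study conditions.
"""

import numpy as np
import pytest

from molexplore import clm_policy, fixtures, rl_engine

CORPUS_SEED = 1


@pytest.fixture(scope="session")
def toy_corpus() -> list[str]:
    spec = fixtures.CorpusSpec(size=fixtures.DESK_CORPUS_SIZE, seed=CORPUS_SEED)
    return fixtures.generate_toy_corpus(spec)


@pytest.fixture(scope="session")
def toy_task_and_split(toy_corpus):
    """A 2-target string-similarity task with targets held out of the split."""
    return fixtures.generate_toy_task(toy_corpus, n_targets=2, seed=0)


@pytest.fixture(scope="session")
def base_policy(toy_task_and_split):
    _, split = toy_task_and_split
    return fixtures.pretrained_toy_policy(split, seed=0)


@pytest.fixture(scope="session")
def rl_cfg() -> rl_engine.RLConfig:
    return rl_engine.RLConfig(batch_size=64, replay_k=10, lr=fixtures.DESK_RL_LR)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_vocab():
    return clm_policy.build_vocabulary(["CCO", "CCN", "c1ccccc1", "CC(C)O"])
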