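"""Multi-target rediscovery benchmark: tasks, oracle, metric, diversity.

A task carries a set of structurally dissimilar target molecules that are
all active against one biological target; the generator's goal is to
rediscover *all* of them.  The oracle rewards a molecule with its
similarity to the *nearest* target (string-edit or fingerprint), so the
reward landscape has one mode per target.  Performance is the product
over targets of the run-wide maximum similarity achieved, which is 1 only
when every target is perfectly rediscovered.  Chemical-space coverage is
measured by sphere-exclusion diversity (SEDiv) at a Tanimoto threshold of
0.65 on a sample of 1000 molecules.

The budget counts every sampled string — valid or not, unique or not —
mirroring an oracle-call budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import yaml

from . import chem_core

ORACLE_KINDS = ("levenshtein", "tanimoto", "external")

DEFAULT_SEDIV_THRESHOLD = 0.65
DEFAULT_SEDIV_SAMPLE = 1000
DEFAULT_BUDGET = 10_000


class BudgetExhaustedError(RuntimeError):
    """Raised when a sample is requested past the molecule budget."""


class TaskSchemaError(ValueError):
    """Raised by :func:`load_task` when a task file violates the schema."""


@dataclass
class TaskSpec:
    """A named rediscovery task.

    ``targets`` holds 2–4 canonical SMILES for rediscovery tasks.  With
    ``oracle_kind="external"`` the reward comes from a user-registered
    callback (e.g. a bioactivity model) and ``targets`` may be empty, in
    which case the score trace tracks the maximum reward as a single
    pseudo-target.
    """

    name: str
    targets: list[str]
    oracle_kind: str
    threshold: float | None = None
    external_fn: Callable[[str], float] | None = None
    _target_fps: list[chem_core.Fingerprint] = field(default_factory=list, repr=False)

    def __post_init__(self):
        if self.oracle_kind not in ORACLE_KINDS:
            raise TaskSchemaError(
                f"oracle_kind {self.oracle_kind!r} not one of {ORACLE_KINDS}"
            )
        canon = []
        for t in self.targets:
            c = chem_core.validate_and_canonicalize(t)
            if c is None:
                raise TaskSchemaError(f"invalid target SMILES: {t!r}")
            canon.append(c)
        if len(set(canon)) != len(canon):
            raise TaskSchemaError("targets must be pairwise distinct")
        if self.oracle_kind != "external" and len(canon) < 2:
            raise TaskSchemaError(
                f"rediscovery tasks need >=2 targets, got {len(canon)}"
            )
        self.targets = canon
        if self.oracle_kind == "tanimoto":
            self._target_fps = [chem_core.ecfp4(c) for c in canon]

    @property
    def n_trace(self) -> int:
        """Number of entries the score trace tracks."""
        return len(self.targets) if self.targets else 1


def target_similarities(smiles: str, task: TaskSpec) -> np.ndarray:
    """Similarity of one sampled string to every target (zeros if invalid).

    Similarities are computed on the canonical form of the sample, so two
    SMILES spellings of one molecule always score identically.
    """
    canonical = chem_core.validate_and_canonicalize(smiles)
    if canonical is None:
        return np.zeros(task.n_trace)
    if task.oracle_kind == "levenshtein":
        return np.array(
            [chem_core.levenshtein_similarity(canonical, t) for t in task.targets]
        )
    if task.oracle_kind == "tanimoto":
        fp = chem_core.ecfp4(canonical)
        return np.array([chem_core.tanimoto(fp, tfp) for tfp in task._target_fps])
    if task.external_fn is None:
        raise TaskSchemaError(
            f"task {task.name!r} has oracle_kind 'external' but no registered callback"
        )
    return np.array([float(task.external_fn(canonical))])


def oracle_reward(smiles: str, task: TaskSpec) -> float:
    """Similarity to the nearest target: R(m) = max_t sim(m, m_t).

    Invalid SMILES score 0.
    """
    return float(target_similarities(smiles, task).max())


@dataclass
class BudgetLedger:
    """Counts oracle-visible samples against a fixed molecule budget."""

    budget: int
    consumed: int = 0

    def __post_init__(self):
        if self.budget <= 0:
            raise ValueError("budget must be positive")

    @property
    def remaining(self) -> int:
        return self.budget - self.consumed

    def charge(self, n: int = 1) -> None:
        if self.consumed + n > self.budget:
            raise BudgetExhaustedError(
                f"budget exhausted: {self.consumed}+{n} > {self.budget}"
            )
        self.consumed += n


@dataclass
class ScoreTrace:
    """Running per-target maximum similarity, with per-update snapshots."""

    n_targets: int
    per_target_max: np.ndarray = field(init=False)
    history: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        if self.n_targets < 1:
            raise ValueError("trace needs at least one target entry")
        self.per_target_max = np.zeros(self.n_targets)

    def update(self, sims: np.ndarray) -> None:
        if sims.shape != self.per_target_max.shape:
            raise ValueError("similarity vector has wrong length")
        self.per_target_max = np.maximum(self.per_target_max, sims)

    def snapshot(self) -> None:
        self.history.append(self.per_target_max.copy())


def task_score(trace: ScoreTrace) -> float:
    """Product over targets of the maximum similarity achieved."""
    return float(np.prod(trace.per_target_max))


def benchmark_sum(task_scores: Sequence[float]) -> float:
    """Sum of per-task scores; bounded above by the number of tasks."""
    return float(sum(task_scores))


def record_sample(
    ledger: BudgetLedger, trace: ScoreTrace, smiles: str, task: TaskSpec
) -> np.ndarray:
    """Charge one sample against the budget and fold its per-target
    similarities into the trace.  Returns the similarity vector so the
    caller can reuse it for the reward (one oracle call per sample)."""
    ledger.charge(1)
    sims = target_similarities(smiles, task)
    trace.update(sims)
    return sims


def sphere_exclusion_diversity(
    mols: Sequence[str],
    threshold: float = DEFAULT_SEDIV_THRESHOLD,
    sample_size: int = DEFAULT_SEDIV_SAMPLE,
    seed: int | np.random.Generator = 0,
) -> float:
    """Fraction of a random sample surviving greedy sphere exclusion.

    A uniform sample (without replacement) of up to ``sample_size``
    molecules is scanned in sample order; a molecule founds a new sphere
    iff its Tanimoto similarity to every existing sphere center is
    strictly below ``threshold`` (ties fall inside the sphere).  The
    count of centers is normalized by the number of molecules scanned.
    """
    if len(mols) == 0:
        raise ValueError("SEDiv needs at least one molecule")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mols = list(mols)
    if len(mols) > sample_size:
        idx = rng.choice(len(mols), size=sample_size, replace=False)
        sample = [mols[i] for i in idx]
    else:
        sample = mols
    fps = np.stack([chem_core.ecfp4(m).bits for m in sample])
    popcounts = fps.sum(axis=1)
    center_idx: list[int] = []
    for i in range(len(sample)):
        if not center_idx:
            center_idx.append(i)
            continue
        centers = fps[center_idx]
        inter = (centers & fps[i]).sum(axis=1)
        union = popcounts[center_idx] + popcounts[i] - inter
        sims = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
        if np.all(sims < threshold):
            center_idx.append(i)
    return len(center_idx) / len(sample)


def load_task(path) -> TaskSpec:
    """Load and validate a task YAML file.

    Schema: ``name`` (str), ``oracle`` (levenshtein | tanimoto | external),
    ``targets`` (list of SMILES), optional ``threshold`` (unit interval).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise TaskSchemaError(f"task file {path} is not a mapping")
    for key in ("name", "oracle", "targets"):
        if key not in raw:
            raise TaskSchemaError(f"task file missing required field {key!r}")
    threshold = raw.get("threshold")
    if threshold is not None:
        threshold = float(threshold)
        if not (0.0 <= threshold <= 1.0):
            raise TaskSchemaError("field 'threshold' must lie in [0, 1]")
    targets = raw["targets"]
    if not isinstance(targets, list) or not all(isinstance(t, str) for t in targets):
        raise TaskSchemaError("field 'targets' must be a list of SMILES strings")
    try:
        return TaskSpec(
            name=str(raw["name"]),
            targets=targets,
            oracle_kind=str(raw["oracle"]),
            threshold=threshold,
        )
    except TaskSchemaError as err:
        raise TaskSchemaError(f"{path}: {err}") from err


def save_task(path, task: TaskSpec) -> None:
    data = {"name": task.name, "oracle": task.oracle_kind, "targets": list(task.targets)}
    if task.threshold is not None:
        data["threshold"] = task.threshold
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
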