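# Methods

## Problem

Given a reward oracle over molecules, standard RL fine-tuning of a SMILES
chemical language model (CLM) finds *one* high-reward region and exploits
it.  Multi-target rediscovery asks a harder question: a task carries a set
of 2–4 structurally dissimilar target molecules that are all active
against one biological target, and the goal is to get close to *all* of
them.  The oracle rewards a generated molecule `m` with its similarity to
the nearest target,

    R(m) = max_t sim(m, m_t),

so the reward landscape has one mode per target and a single greedy agent
typically climbs only one of them.  Performance is the product-of-max
metric

    score = prod_t max_i sim(m_i, m_t)

taken over *all* molecules generated in a run (run-wide maxima, since the
quantity of interest is whether each target was ever approached).  The
score of a task suite is the plain sum of task scores, bounded by the
number of tasks.

Similarity is either normalized string-edit similarity on canonical
SMILES, `1 − LD(a,b)/max(|a|,|b|)` with `LD` the Levenshtein distance
(the string-space variant), or Tanimoto similarity on radius-2 2048-bit
hashed circular fingerprints (ECFP4-style).  The string-edit
normalization is the standard one guaranteeing values in [0, 1]; it is
computed character-wise on canonical SMILES so the oracle is independent
of the generator's tokenization.  Invalid SMILES score 0, and the
molecule budget counts *every* sampled string — valid or not, unique or
not — mirroring an oracle-call budget.

Chemical-space coverage is measured by sphere-exclusion diversity
(SEDiv): draw up to 1000 unique valid molecules uniformly without
replacement (seeded), scan them greedily, let a molecule found a new
sphere iff its Tanimoto to every existing center is strictly below 0.65
(ties fall inside), and report centers divided by the number scanned.

## Model and optimizer

The policy is an autoregressive GRU over SMILES tokens (regex
tokenization: bracket atoms, Cl/Br and `%nn` ring labels are single
tokens).  Next-token probabilities are a softmax over the vocabulary with
the padding and begin-of-sequence symbols masked out, so the distribution
properly normalizes over emittable tokens.  Pretraining minimizes the
mean per-sequence negative log-likelihood with Adam.

Test-time training then fine-tunes a clone of the pretrained policy per
task with REINFORCE over whole sequences, using the shaped reward

    R_reshaped(τ) = clip(R(τ) + σ · log π_prior(τ), 0)^α

where π_prior is the pretrained policy frozen at RL start.  The clip's
lower bound is exactly 0 with no upper bound, and 0^α := 0.  Defaults:
σ = 0.001, α = 3 (σ = 0, α = 1 recovers vanilla REINFORCE exactly — the
identity is bit-exact and tested).  A replay buffer (capacity 100,
deduplicated by canonical SMILES, best reward kept, minimum evicted)
contributes 10 trajectories per step, drawn sequentially without
replacement with probability proportional to reward (uniform fallback
when all stored rewards are 0, a case the proportionality rule leaves
undefined).  Replayed trajectories get their log-probability recomputed
under the current policy before entering the loss — off-policy
correction by recomputation, without importance weights.

Optional exploration mechanisms, both applied to the reward *before*
reshaping:

* **Diversity filter (DF)** — the first occurrence of a canonical SMILES
  keeps its reward; every repeat is zeroed.
* **RND bonus** — a fixed random MLP maps fingerprints to a 32-d
  embedding; a same-shaped predictor is regressed toward it on every
  visited batch.  The bonus is the squared prediction error divided by
  the running standard deviation of all errors seen so far (count-based
  Welford, not an exponential average — the long memory keeps the
  normalization scale while a heavily-trained input's raw error, and
  hence its bonus, decays toward zero), times `bonus_scale` (default
  0.1).

Because no automatic-differentiation framework is a dependency of this
package, the networks run on a small in-package reverse-mode engine
(`molexplore.nn`): a numpy `Tensor` with a dynamic tape, the ~20
primitives a GRU policy, MLPs and kernel log-determinants need, and
Adam.  Every primitive's gradient is checked against central finite
differences in the test suite; sampling runs on a graph-free numpy twin
of the forward pass that agrees with the differentiable path to
floating-point precision (also tested).

## Population strategies

N agents attack one task round-robin (one batch per agent per cycle:
everyone samples, then everyone updates), each with its own budget, and
the benchmark is scored on the union of all agents' molecules.  The
interaction strategies are formalized from their one-line descriptions,
behind one strategy interface so alternative formulations are drop-in:

* *purge*: a molecule enters agent i's buffer only if no other buffer
  holds it (buffers provably pairwise disjoint).
* *shared* / *shared_bonus*: one buffer for all agents, optionally with
  a flat bonus `b` (default 0.1) for molecules not yet in it.  Sharing
  is expected to act as a convergence (negative) control.
* *noise*: i.i.d. Gaussian parameter noise (σ = 0.01) per agent at init,
  drawn from a stream separate from the sampling RNG.
* *rnd*: one RND state shared by the whole population.
* *ent_s* / *ce_s*: per state s, the agent-confidence vector is the
  softmax over agents of total sequence log-probability; the auxiliary
  loss is its mean entropy (ent_s) or the mean cross-entropy against the
  one-hot of the state's originating agent (ce_s).
* *diff_s*: "policy uncertainty" is per-token-averaged NLL; the loss is
  mean uncertainty on own states minus mean uncertainty on the rest of
  the population's states.
* *diff_n*: minimize −(1/(N−1)) Σ_{j≠i} mean_s [log π_i(s) − log π_j(s)]
  over agent i's own on-policy states, computed against all other agents
  simultaneously (the sequential alternative — only previously-trained
  agents — is a plausible reading too; simultaneous was chosen for
  symmetry).
* *dvd*: behavior embedding = sequence log-probabilities on a probe set
  of 32 prior-policy samples frozen at population init; maximize the
  log-determinant of the RBF kernel matrix of embeddings (bandwidth =
  median pairwise distance, log-det floored at −30; a numerically
  singular kernel — coincident embeddings — reports the floor, and the
  differentiable path adds 1e-8 jitter).
* *popnorm*: subtract the population-mean shaped return of the iteration
  from every on-policy return (adjusted returns sum to zero).

Auxiliary losses enter as `loss + λ·aux` with λ = 0.1.  With λ = 0,
bonus = 0, noise σ = 0 or RND scale = 0, each coefficient-bearing
strategy reduces bit-identically to independent agents (tested).  The
structural strategies — shared, shared_bonus, purge, popnorm — have no
zero coefficient that disables their mechanism: shared_bonus with b = 0
reduces to shared, not to independent.

## Scaling protocols and seeds

Replicate seed = base_seed + 1000·replicate; agent seed = replicate
seed + agent index.  Agent populations are therefore *nested*: the
agents of an N-agent setting are exactly the first N agents of a
2N-agent setting within the same replicate, so agent scaling runs the
maximal population once and scores nested prefixes — identical to
running each N separately, and it makes the union score exactly
monotone in N per replicate.  Budget scaling runs one agent per
(budget, replicate), optionally with RND or DF.  Score versus log2(N)
is summarized by a least-squares linear fit (slope, intercept, R²).
Strategy comparisons use one-tailed two-sample t-tests against the
independent baseline with Bonferroni correction.

## Synthetic data

The toy corpus generator composes valid SMILES from a fragment grammar
— chains over {C, N, O} with single branches off carbons and optional
benzene/cyclohexane cores — so validity holds by construction (still
asserted molecule-by-molecule).  Defaults: 600 distinct molecules, ≤ 12
heavy atoms, branch probability 0.3, ring probability 0.3.  Toy tasks
draw targets from the corpus under a pairwise ECFP4-Tanimoto cap of 0.3
(emulating "structurally dissimilar, co-active" target sets) and exclude
them from the returned pretraining split: rediscovery, not recall.  The
standard suite has four tasks with 2, 3, 3 and 4 targets.

What the toy data does *not* emulate: drug-like property distributions,
stereochemistry, realistic vocabulary size (~10 tokens versus ~40+ for
real corpora), or molecule lengths beyond ~25 tokens.  Passing tests
show the machinery — oracles, shaping, replay, population logic,
scaling bookkeeping — behaves as specified; they do not certify
benchmark scores on real drug-candidate target sets, which additionally
depend on corpus composition and model capacity.

## Desk-scale study conditions

All tests and the acceptance script use one protocol: the 600-molecule
corpus above; a 1-layer GRU with embedding 32, hidden 64, max length 60;
pretraining for 50 epochs at batch 64, learning rate 3e-3 (chosen so the
toy model comfortably exceeds ~95% sample validity, the conventional
health bar for CLMs); RL fine-tuning at the same learning rate with
batch 64, replay 10, buffer 100; budgets of 1,000–4,000 molecules;
populations of 1–8 agents; 5 replicates.  The configurable defaults of
`PolicyConfig` (embedding 64, hidden 256, 2 layers) and a 10,000-molecule
budget remain available for larger experiments.  The bandit learning
probe (two one-token molecules, rewards 1 and 0) runs pure REINFORCE
(σ = 0, α = 1) with replay at the same learning rate.

## Numerical choices and edge cases

* Tanimoto of two empty bit sets := 0 (avoids 0/0; unreachable for
  valid molecules).
* Both-empty-string edit similarity := 1 (equal strings).
* Truncated sequences (max length reached before end-of-sequence) are
  scored as-is; the detokenized prefix is usually invalid → reward 0.
* A batch is truncated to the remaining budget; the final iteration may
  be smaller than the batch size.
* The RND normalization uses denominator 1 until two errors have been
  observed.
* Canonicalization is RDKit's; within-run consistency is what the
  deduplication logic relies on, cross-toolkit byte-identity is not
  promised.

## Known limitations

* The engine is CPU-bound pure numpy; paper-scale runs (128 agents ×
  10,000 molecules, large vocabularies) are expressible but slow.
* The external-oracle contract (e.g. QSAR bioactivity models) is a
  callback taking a canonical SMILES and returning [0, 1]; no built-in
  bioactivity model ships with the package.
* Exact supplementary formulations of the cooperative losses in the
  source literature were not available; the formalizations above are
  this package's own, stated precisely so they can be swapped.
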