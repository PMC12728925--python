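"""SMILES chemical language model: tokenizer, vocabulary and GRU policy.

The policy is an autoregressive next-token model over SMILES tokens:
P(X) = prod_t P(x_t | x_<t).  Pretraining minimizes the per-sequence
negative log-likelihood (cross-entropy) over a corpus; the pretrained
model then serves both as the starting policy for reinforcement-learning
fine-tuning and, frozen, as the prior that regularizes the reshaped
reward.

Tokenization is regex-based: bracket atoms ``[...]``, the two-letter
halogens Cl/Br and ``%nn`` ring labels are single tokens; every other
character (atoms, ring digits, bonds, branches) is its own token.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

PAD, BOS, EOS = "<pad>", "<bos>", "<eos>"
SPECIALS = (PAD, BOS, EOS)

_TOKEN_RE = re.compile(r"\[[^\]]*\]|Br|Cl|%\d{2}|[A-Za-z0-9]|[=#\-\+\(\)/\\.@:~\*\$]")


class TokenizationError(ValueError):
    pass


def smiles_tokens(s: str) -> list[str]:
    """Split a SMILES string into tokens; error if any character is left over."""
    if not s:
        raise TokenizationError("cannot tokenize an empty string")
    tokens = _TOKEN_RE.findall(s)
    if "".join(tokens) != s:
        raise TokenizationError(f"string {s!r} contains untokenizable characters")
    return tokens


@dataclass(frozen=True)
class Vocabulary:
    """Bijective token <-> index map with PAD/BOS/EOS at indices 0..2."""

    tokens: tuple[str, ...]
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        if tuple(self.tokens[:3]) != SPECIALS:
            raise ValueError("vocabulary must start with PAD, BOS, EOS")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        object.__setattr__(self, "index", {t: i for i, t in enumerate(self.tokens)})

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad(self) -> int:
        return 0

    @property
    def bos(self) -> int:
        return 1

    @property
    def eos(self) -> int:
        return 2


def build_vocabulary(corpus: list[str]) -> Vocabulary:
    """Vocabulary of every token appearing in the corpus plus specials,
    in deterministic (sorted) order."""
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    seen: set[str] = set()
    for s in corpus:
        seen.update(smiles_tokens(s))
    return Vocabulary(SPECIALS + tuple(sorted(seen)))


@dataclass(frozen=True)
class TokenSequence:
    """BOS-prefixed token-index sequence, EOS-terminated unless truncated."""

    indices: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def n_predicted(self) -> int:
        """Number of next-token predictions the sequence represents."""
        return len(self.indices) - 1


def tokenize(s: str, vocab: Vocabulary, max_len: int | None = None) -> TokenSequence:
    toks = smiles_tokens(s)
    missing = [t for t in toks if t not in vocab.index]
    if missing:
        raise TokenizationError(f"tokens not in vocabulary: {sorted(set(missing))}")
    if max_len is not None and len(toks) + 1 > max_len:
        raise TokenizationError(f"sequence longer than max_len={max_len}")
    return TokenSequence((vocab.bos, *[vocab.index[t] for t in toks], vocab.eos))


def detokenize(seq: TokenSequence, vocab: Vocabulary) -> str:
    special = {vocab.pad, vocab.bos, vocab.eos}
    return "".join(vocab.tokens[i] for i in seq.indices if i not in special)


@dataclass
class PolicyConfig:
    embedding_size: int = 64
    hidden_size: int = 256
    num_layers: int = 2
    max_len: int = 100  # max generated tokens per sequence (incl. EOS)


class Policy:
    """Recurrent next-token policy over a SMILES vocabulary.

    The distribution at every step is a softmax over the vocabulary with
    PAD and BOS masked out (their logits are pinned far negative), so
    next-token probabilities sum to 1 over emittable tokens.  Sampling
    runs on a graph-free numpy path; training log-probabilities are
    computed with the autodiff graph and agree with the sampling path to
    floating-point precision.
    """

    _MASK_VAL = -1e9

    def __init__(self, vocab: Vocabulary, config: PolicyConfig | None = None,
                 seed: int = 0, _params: dict[str, Tensor] | None = None):
        self.vocab = vocab
        self.config = config or PolicyConfig()
        if _params is not None:
            self.params = _params
        else:
            rng = np.random.default_rng(seed)
            V, E, H = len(vocab), self.config.embedding_size, self.config.hidden_size
            p: dict[str, Tensor] = {
                "embed": Tensor(rng.normal(0, 0.1, size=(V, E)), requires_grad=True),
                "out_W": Tensor(nn._glorot(rng, H, V), requires_grad=True),
                "out_b": Tensor(np.zeros(V), requires_grad=True),
            }
            in_size = E
            for layer in range(self.config.num_layers):
                for k, t in nn.init_gru_params(rng, in_size, H).items():
                    p[f"l{layer}_{k}"] = t
                in_size = H
            self.params = p
        mask = np.zeros(len(vocab))
        mask[[vocab.pad, vocab.bos]] = self._MASK_VAL
        self._logit_mask = mask

    # -- parameter plumbing ------------------------------------------------

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def clone(self) -> "Policy":
        params = {k: Tensor(t.data.copy(), requires_grad=True) for k, t in self.params.items()}
        return Policy(self.vocab, PolicyConfig(**vars(self.config)), _params=params)

    def perturb(self, noise_sigma: float, rng: np.random.Generator) -> None:
        """Add i.i.d. Gaussian noise to every parameter in place."""
        for t in self.params.values():
            t.data += rng.normal(0.0, noise_sigma, size=t.data.shape)

    def _layer_params(self, layer: int) -> dict[str, Tensor]:
        prefix = f"l{layer}_"
        return {k[len(prefix):]: t for k, t in self.params.items() if k.startswith(prefix)}

    # -- numpy (sampling) path --------------------------------------------

    def _step_np(self, token_idx: np.ndarray, hidden: list[np.ndarray]) -> np.ndarray:
        """Advance hidden states in place; return (B, V) log-probabilities."""
        x = self.params["embed"].data[token_idx]
        for layer in range(self.config.num_layers):
            hidden[layer] = nn.gru_cell_np(self._layer_params(layer), x, hidden[layer])
            x = hidden[layer]
        logits = x @ self.params["out_W"].data + self.params["out_b"].data + self._logit_mask
        m = logits.max(axis=1, keepdims=True)
        return logits - (m + np.log(np.exp(logits - m).sum(axis=1, keepdims=True)))

    def _fresh_hidden(self, batch: int) -> list[np.ndarray]:
        H = self.config.hidden_size
        return [np.zeros((batch, H)) for _ in range(self.config.num_layers)]

    def sample_batch(
        self, n: int, rng: int | np.random.Generator, max_len: int | None = None
    ) -> list[tuple[TokenSequence, float]]:
        """Draw ``n`` sequences autoregressively; returns (sequence, log-prob)
        pairs.  Each sequence ends with EOS or is truncated at ``max_len``
        generated tokens.  Fixed seed gives an identical batch."""
        if n == 0:
            return []
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        max_len = max_len or self.config.max_len
        hidden = self._fresh_hidden(n)
        current = np.full(n, self.vocab.bos, dtype=np.int64)
        alive = np.ones(n, dtype=bool)
        rows = [np.full(n, self.vocab.bos, dtype=np.int64)]
        logp = np.zeros(n)
        for _ in range(max_len):
            lp = self._step_np(current, hidden)
            u = rng.random(n)
            cdf = np.exp(lp).cumsum(axis=1)
            nxt = (cdf < u[:, None]).sum(axis=1).clip(max=lp.shape[1] - 1)
            nxt = np.where(alive, nxt, self.vocab.pad)
            logp += np.where(alive, lp[np.arange(n), nxt], 0.0)
            rows.append(nxt)
            alive &= nxt != self.vocab.eos
            current = nxt
            if not alive.any():
                break
        mat = np.stack(rows, axis=1)
        out = []
        for i in range(n):
            idx = mat[i]
            idx = idx[idx != self.vocab.pad] if not alive[i] else idx
            out.append((TokenSequence(tuple(int(t) for t in idx)), float(logp[i])))
        return out

    def sequence_log_prob(self, seq: TokenSequence) -> float:
        return float(self.sequence_log_probs_np([seq])[0])

    def sequence_log_probs_np(self, seqs: list[TokenSequence]) -> np.ndarray:
        """Teacher-forced log-probabilities on the graph-free path."""
        inputs, targets, mask = self._pad(seqs)
        hidden = self._fresh_hidden(len(seqs))
        total = np.zeros(len(seqs))
        for t in range(inputs.shape[1]):
            lp = self._step_np(inputs[:, t], hidden)
            total += lp[np.arange(len(seqs)), targets[:, t]] * mask[:, t]
        return total

    # -- graph (training) path --------------------------------------------

    def _pad(self, seqs: list[TokenSequence]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        L = max(len(s) for s in seqs)
        for s in seqs:
            if s.n_predicted > self.config.max_len:
                raise ValueError(f"sequence longer than max_len={self.config.max_len}")
        idx = np.full((len(seqs), L), self.vocab.pad, dtype=np.int64)
        for i, s in enumerate(seqs):
            idx[i, : len(s)] = s.indices
        inputs, targets = idx[:, :-1], idx[:, 1:]
        mask = np.zeros_like(targets, dtype=float)
        for i, s in enumerate(seqs):
            mask[i, : s.n_predicted] = 1.0
        return inputs, targets, mask

    def sequence_log_probs_graph(self, seqs: list[TokenSequence]) -> Tensor:
        """Differentiable per-sequence log-probabilities, shape (B,)."""
        inputs, targets, mask = self._pad(seqs)
        B, L = inputs.shape
        H = self.config.hidden_size
        hidden: list[Tensor] = [Tensor(np.zeros((B, H))) for _ in range(self.config.num_layers)]
        total = Tensor(np.zeros(B))
        mask_t = Tensor(self._logit_mask)
        for t in range(L):
            x = self.params["embed"].rows(inputs[:, t])
            for layer in range(self.config.num_layers):
                hidden[layer] = nn.gru_cell(self._layer_params(layer), x, hidden[layer])
                x = hidden[layer]
            logits = x @ self.params["out_W"] + self.params["out_b"] + mask_t
            lp = nn.log_softmax(logits, axis=1)
            total = total + lp.select(targets[:, t]) * Tensor(mask[:, t])
        return total

    def next_token_log_probs(self, prefix: TokenSequence) -> np.ndarray:
        """Log-distribution over the next token given a (BOS-led) prefix."""
        hidden = self._fresh_hidden(1)
        lp = None
        for tok in prefix.indices:
            lp = self._step_np(np.array([tok]), hidden)
        return lp[0]

    # -- checkpointing -----------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "format_version": 1,
            "tokens": list(self.vocab.tokens),
            "config": vars(self.config),
        }
        arrays = {k: t.data for k, t in self.params.items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "Policy":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode())
            params = {
                k: Tensor(npz[k].copy(), requires_grad=True)
                for k in npz.files if k != "__meta__"
            }
        vocab = Vocabulary(tuple(meta["tokens"]))
        return cls(vocab, PolicyConfig(**meta["config"]), _params=params)


def pretrain(
    policy: Policy,
    corpus: list[str],
    epochs: int = 10,
    batch_size: int = 64,
    lr: float = 1e-3,
    seed: int = 0,
) -> list[float]:
    """Cross-entropy (negative log-likelihood) pretraining.

    Minimizes the mean per-sequence NLL over the corpus by Adam and
    returns the per-epoch mean NLL trace.  Deterministic for a fixed
    seed.  Raises if the loss becomes non-finite.
    """
    rng = np.random.default_rng(seed)
    seqs = [tokenize(s, policy.vocab, policy.config.max_len + 1) for s in corpus]
    opt = nn.Adam(policy.parameters(), lr=lr)
    trace: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(len(seqs))
        epoch_nll = 0.0
        for start in range(0, len(seqs), batch_size):
            batch = [seqs[i] for i in order[start : start + batch_size]]
            opt.zero_grad()
            loss = -(policy.sequence_log_probs_graph(batch).mean())
            if not np.isfinite(loss.data):
                raise FloatingPointError("pretraining NLL became non-finite")
            loss.backward()
            opt.step()
            epoch_nll += float(loss.data) * len(batch)
        trace.append(epoch_nll / len(seqs))
    return trace
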