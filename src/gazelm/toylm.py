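"""Table-driven toy language model.

A :class:`ToyLM` is an explicit order-k Markov model over a small word
vocabulary: every reachable context tuple maps to a probability vector over
the next word. Because the table is explicit, every downstream quantity —
entropy, surprisal, top-k candidates, cosine similarity — has a brute-force
hand-checkable value, which makes the toy model the oracle backend for the
whole pipeline. It satisfies the same :class:`~gazelm.predictability.LMAdapter`
contract as a transformer backend; each word is a single piece.

Embeddings are fixed unit vectors (not genuinely contextual): semantic
relatedness is encoded by construction, e.g. a "related" pair placed at
cosine 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ToyLM",
    "build_toy_lm",
    "uniform_lm",
    "degenerate_cycle_lm",
    "random_lm",
    "embeddings_with_similarity",
    "toy_lm_from_config",
]

# Finite stand-in for log(0) so that softmax recovers exact zeros by underflow.
_NEG_INF_LOGIT = -1.0e9

_ROW_TOL = 1e-9


@dataclass
class ToyLM:
    """Explicit conditional-table language model over whole words."""

    vocabulary: list[str]
    order: int
    conditional_table: dict[tuple[str, ...], np.ndarray]
    embeddings: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {w: i for i, w in enumerate(self.vocabulary)}
        if len(self._index) != len(self.vocabulary):
            raise ValueError("vocabulary contains duplicate words")
        for ctx, row in self.conditional_table.items():
            if len(ctx) != self.order:
                raise ValueError(
                    f"context {ctx!r} has length {len(ctx)}, expected order {self.order}"
                )
            row = np.asarray(row, dtype=float)
            if row.shape != (len(self.vocabulary),):
                raise ValueError(f"row for context {ctx!r} has wrong length")
            if np.any(row < 0):
                raise ValueError(f"row for context {ctx!r} has negative probabilities")
            if abs(row.sum() - 1.0) > _ROW_TOL:
                raise ValueError(
                    f"row for context {ctx!r} sums to {row.sum():.12f}, not 1"
                )
            self.conditional_table[ctx] = row
        if self.embeddings:
            dims = {np.asarray(v).shape for v in self.embeddings.values()}
            if len(dims) != 1:
                raise ValueError("embeddings have inconsistent dimensions")
            missing = set(self.vocabulary) - set(self.embeddings)
            if missing:
                raise ValueError(f"words without embeddings: {sorted(missing)}")
            for w, v in self.embeddings.items():
                v = np.asarray(v, dtype=float)
                n = np.linalg.norm(v)
                if not np.isclose(n, 1.0, atol=1e-6):
                    raise ValueError(f"embedding for {w!r} is not unit norm ({n})")
                self.embeddings[w] = v

    # -- LMAdapter contract -------------------------------------------------

    @property
    def vocab_size(self) -> int:
        return len(self.vocabulary)

    def tokenize(self, word: str, *, initial: bool = False) -> list[int]:
        try:
            return [self._index[word]]
        except KeyError:
            raise KeyError(f"word {word!r} is not in the toy vocabulary") from None

    def piece(self, token_id: int) -> str:
        return self.vocabulary[token_id]

    def is_word_initial(self, token_id: int) -> bool:
        return True

    def context_key(self, context_ids: Sequence[int]) -> tuple[str, ...]:
        if self.order == 0:
            return ()
        if len(context_ids) < self.order:
            raise ValueError(
                f"context of {len(context_ids)} words is shorter than order {self.order}"
            )
        return tuple(self.vocabulary[t] for t in context_ids[-self.order:])

    def next_word_probs(self, context_ids: Sequence[int]) -> np.ndarray:
        key = self.context_key(context_ids)
        try:
            return self.conditional_table[key]
        except KeyError:
            raise KeyError(f"context {key!r} is unreachable (no conditional row)") from None

    def logits(self, context_ids: Sequence[int]) -> np.ndarray:
        probs = self.next_word_probs(context_ids)
        with np.errstate(divide="ignore"):
            logp = np.log(probs)
        return np.where(np.isfinite(logp), logp, _NEG_INF_LOGIT)

    def embed_word(self, context_ids: Sequence[int], word: str) -> np.ndarray:
        # Toy embeddings are fixed per word (context-free by design).
        if not self.embeddings:
            raise ValueError("this toy model carries no embedding table")
        try:
            return self.embeddings[word]
        except KeyError:
            raise KeyError(f"word {word!r} has no embedding") from None


def build_toy_lm(
    vocabulary: Sequence[str],
    order: int,
    conditional_table: Mapping[Sequence[str] | str, Sequence[float]],
    embeddings: Mapping[str, Sequence[float]] | None = None,
) -> ToyLM:
    """Validated constructor; contexts may be given as tuples or single words."""
    table: dict[tuple[str, ...], np.ndarray] = {}
    for ctx, row in conditional_table.items():
        if isinstance(ctx, str):
            ctx = (ctx,)
        table[tuple(ctx)] = np.asarray(row, dtype=float)
    emb = {w: np.asarray(v, dtype=float) for w, v in (embeddings or {}).items()}
    return ToyLM(list(vocabulary), order, table, emb)


def uniform_lm(vocabulary: Sequence[str], order: int = 1) -> ToyLM:
    """Every context predicts every word with equal probability 1/V."""
    vocab = list(vocabulary)
    row = np.full(len(vocab), 1.0 / len(vocab))
    if order == 0:
        contexts: list[tuple[str, ...]] = [()]
    else:
        contexts = [(w,) for w in vocab] if order == 1 else _all_tuples(vocab, order)
    table = {c: row.copy() for c in contexts}
    return ToyLM(vocab, order, table, _basis_embeddings(vocab))


def degenerate_cycle_lm(vocabulary: Sequence[str]) -> ToyLM:
    """Deterministic bigram model: each word predicts the next in the cycle
    with probability 1, so entropy and surprisal are exactly zero on its own
    generated text."""
    vocab = list(vocabulary)
    table = {}
    for i, w in enumerate(vocab):
        row = np.zeros(len(vocab))
        row[(i + 1) % len(vocab)] = 1.0
        table[(w,)] = row
    return ToyLM(vocab, 1, table, _basis_embeddings(vocab))


def random_lm(
    vocabulary: Sequence[str],
    seed: int,
    *,
    order: int = 1,
    concentration: float = 0.1,
    embedding_dim: int = 16,
) -> ToyLM:
    """Bigram model with Dirichlet-sampled rows.

    A concentration below 1 yields a realistic mix of constraining (low
    entropy) and neutral (high entropy) contexts, which the downstream
    entropy × surprisal analyses need for leverage.
    """
    if order != 1:
        raise ValueError("random_lm generates bigram (order-1) tables")
    rng = np.random.default_rng(seed)
    vocab = list(vocabulary)
    v = len(vocab)
    table = {(w,): rng.dirichlet(np.full(v, concentration)) for w in vocab}
    emb = rng.standard_normal((v, embedding_dim))
    emb /= np.linalg.norm(emb, axis=1, keepdims=True)
    return ToyLM(vocab, 1, table, {w: emb[i] for i, w in enumerate(vocab)})


def embeddings_with_similarity(
    vocabulary: Sequence[str],
    *,
    dim: int | None = None,
    related_pairs: Mapping[tuple[str, str], float] | None = None,
) -> dict[str, np.ndarray]:
    """Unit embeddings with exact pairwise cosines.

    Words start on orthogonal basis vectors (cosine 0); each related pair
    (a, b) ↦ c replaces b's vector with c·e_a + sqrt(1−c²)·e_b, giving
    cos(a, b) = c exactly.
    """
    vocab = list(vocabulary)
    dim = dim or len(vocab)
    if dim < len(vocab):
        raise ValueError("dimension must be at least the vocabulary size")
    emb = {w: _basis_vec(dim, i) for i, w in enumerate(vocab)}
    idx = {w: i for i, w in enumerate(vocab)}
    for (a, b), c in (related_pairs or {}).items():
        if not (-1.0 <= c <= 1.0):
            raise ValueError(f"cosine {c} out of range for pair ({a}, {b})")
        emb[b] = c * _basis_vec(dim, idx[a]) + np.sqrt(1 - c * c) * _basis_vec(dim, idx[b])
    return emb


def toy_lm_from_config(config: Mapping) -> ToyLM:
    """Build a toy model from a plain mapping (YAML/JSON fixture spec).

    Expected keys: ``vocabulary`` (list), ``order`` (int), ``conditional_table``
    (mapping from space-joined context to row), optional ``embeddings``.
    """
    table = {
        tuple(ctx.split()) if ctx else (): row
        for ctx, row in config["conditional_table"].items()
    }
    return build_toy_lm(
        config["vocabulary"], int(config["order"]), table, config.get("embeddings")
    )


def _basis_vec(dim: int, i: int) -> np.ndarray:
    v = np.zeros(dim)
    v[i] = 1.0
    return v


def _basis_embeddings(vocab: Sequence[str]) -> dict[str, np.ndarray]:
    return {w: _basis_vec(len(vocab), i) for i, w in enumerate(vocab)}


def _all_tuples(vocab: Sequence[str], order: int) -> list[tuple[str, ...]]:
    from itertools import product

    return list(product(vocab, repeat=order))
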