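"""Word-by-word predictability metrics from a causal language model.

An incremental moving window walks each passage: for the target at position
``i`` the model sees exactly words ``1..i-1`` and we record, *before* the
target is revealed, the Shannon entropy of the next-token distribution, and,
*at* the target, its probability (chain rule over its subword pieces),
surprisal, the top-k candidate next words, and the cosine similarity between
contextual embeddings of the model's top prediction and the target.

Entropy quantifies how constraining the preceding context is (low entropy =
few plausible continuations); surprisal quantifies how unexpected the actual
word is. Both are computed in nats internally and reported in bits.

Any backend satisfying :class:`LMAdapter` plugs in: the table-driven toy
model in :mod:`gazelm.toylm` (used throughout the test suite) or a
transformer backend such as GPT-2 (:mod:`gazelm.hf_backend`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from ._text import normalize_word

__all__ = [
    "LMAdapter",
    "PredictionState",
    "softmax_normalize",
    "shannon_entropy",
    "word_surprisal",
    "incremental_metrics",
    "top_k_candidates",
    "top_k_accuracy",
    "target_prediction_similarity",
]

log = logging.getLogger(__name__)

LN2 = math.log(2.0)

#: Ceiling (in bits) applied when a subword probability underflows to zero.
DEFAULT_SURPRISAL_CAP_BITS = 64.0


@runtime_checkable
class LMAdapter(Protocol):
    """Contract a causal-LM backend must satisfy.

    Tokens are integer ids over a fixed inventory of subword pieces (a whole
    word may span several pieces; in the toy backend every word is a single
    piece). ``logits`` must return finite scores for every piece.
    """

    @property
    def vocab_size(self) -> int: ...

    def tokenize(self, word: str, *, initial: bool = False) -> list[int]:
        """Subword ids for ``word``; ``initial`` marks a passage-initial word
        (backends with byte-pair vocabularies prepend a space otherwise)."""
        ...

    def piece(self, token_id: int) -> str:
        """Text of one piece, with any word-boundary marker preserved."""
        ...

    def is_word_initial(self, token_id: int) -> bool:
        """Whether this piece starts a new word (used when decoding candidate
        words from subword continuations)."""
        ...

    def logits(self, context_ids: Sequence[int]) -> np.ndarray:
        """Prediction scores over the next piece given the context."""
        ...

    def embed_word(self, context_ids: Sequence[int], word: str) -> np.ndarray:
        """Contextual embedding of ``word`` appended to ``context_ids``
        (mean-pooled over its pieces)."""
        ...


@dataclass
class PredictionState:
    """Per-word LM outputs for one target position."""

    word_id: object
    target_probability: float
    entropy_bits: float
    surprisal_bits: float
    top_candidates: list[tuple[str, float]] = field(default_factory=list)
    top_prediction_similarity: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.target_probability <= 1.0):
            raise ValueError(
                f"target probability must lie in (0, 1], got {self.target_probability}"
            )
        expected = -math.log2(self.target_probability)
        if not math.isclose(expected, self.surprisal_bits, rel_tol=0, abs_tol=1e-9):
            raise ValueError(
                "surprisal inconsistent with target probability: "
                f"-log2({self.target_probability}) = {expected} != {self.surprisal_bits}"
            )


def softmax_normalize(logits: np.ndarray) -> np.ndarray:
    """Softmax with max-subtraction for overflow safety.

    Invariant under adding a constant to all logits; output is non-negative
    and sums to 1.
    """
    logits = np.asarray(logits, dtype=float)
    if logits.size == 0:
        raise ValueError("cannot normalize an empty logit vector")
    if not np.all(np.isfinite(logits)):
        raise ValueError("logits must be finite")
    shifted = logits - logits.max()
    expd = np.exp(shifted)
    return expd / expd.sum()


def shannon_entropy(p: np.ndarray) -> float:
    """Shannon entropy of a probability vector, in bits, with 0·log 0 := 0."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("probability vector has negative entries")
    total = p.sum()
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-6):
        raise ValueError(f"probability vector sums to {total}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / LN2) + 0.0  # +0.0 avoids -0.0


def _next_piece_probs(lm: LMAdapter, context_ids: Sequence[int]) -> np.ndarray:
    return softmax_normalize(lm.logits(context_ids))


def word_surprisal(
    lm: LMAdapter,
    context_ids: Sequence[int],
    target: str,
    *,
    initial: bool = False,
    cap_bits: float = DEFAULT_SURPRISAL_CAP_BITS,
) -> tuple[float, float]:
    """Probability and surprisal (bits) of a whole word given a context.

    The word probability is the chain-rule product of the conditional
    probabilities of its subword pieces, so surprisal is additive over
    pieces. A piece whose conditional probability underflows to exactly
    zero caps the word's surprisal at ``cap_bits`` (logged).
    """
    ids = lm.tokenize(target, initial=initial)
    if not ids:
        raise ValueError(f"target {target!r} tokenizes to no pieces")
    ctx = list(context_ids)
    surprisal_bits = 0.0
    for tid in ids:
        probs = _next_piece_probs(lm, ctx)
        p_piece = float(probs[tid])
        if p_piece <= 0.0:
            log.warning(
                "zero conditional probability for piece %r of %r; capping surprisal at %g bits",
                lm.piece(tid), target, cap_bits,
            )
            return 2.0 ** (-cap_bits), cap_bits
        surprisal_bits += -math.log2(p_piece)
        ctx.append(tid)
    surprisal_bits = min(surprisal_bits, cap_bits)
    return 2.0 ** (-surprisal_bits), surprisal_bits


def top_k_candidates(
    lm: LMAdapter,
    context_ids: Sequence[int],
    k: int,
    *,
    n_first_pieces: int = 50,
    max_pieces_per_word: int = 8,
) -> list[tuple[str, float]]:
    """The k most probable next *words* with their chain-rule probabilities.

    Candidate words are decoded from the subword distribution: each of the
    ``n_first_pieces`` most probable word-initial first pieces is extended
    greedily with continuation pieces until the next greedy piece would start
    a new word, then candidates are re-ranked by full chain probability.
    Ties are broken by vocabulary index of the first piece, so the ordering
    is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > lm.vocab_size:
        raise ValueError(f"k={k} exceeds vocabulary size {lm.vocab_size}")
    probs = _next_piece_probs(lm, context_ids)
    # Stable descending sort; ties resolved toward the lower vocabulary index.
    order = np.lexsort((np.arange(probs.size), -probs))
    n_first = max(n_first_pieces, k)  # k words need at least k first pieces
    first_ids = [int(t) for t in order[:n_first] if lm.is_word_initial(int(t))]

    candidates: dict[str, tuple[float, int]] = {}
    for first in first_ids:
        chain_p = float(probs[first])
        pieces = [first]
        ctx = list(context_ids) + [first]
        while len(pieces) < max_pieces_per_word:
            cont = _next_piece_probs(lm, ctx)
            nxt = int(np.lexsort((np.arange(cont.size), -cont))[0])
            if lm.is_word_initial(nxt):
                break
            chain_p *= float(cont[nxt])
            pieces.append(nxt)
            ctx.append(nxt)
        word = "".join(lm.piece(t) for t in pieces).strip()
        prev = candidates.get(word)
        if prev is None or chain_p > prev[0]:
            candidates[word] = (chain_p, first)
    ranked = sorted(candidates.items(), key=lambda kv: (-kv[1][0], kv[1][1]))
    return [(w, p) for w, (p, _) in ranked[:k]]


def target_prediction_similarity(
    lm: LMAdapter,
    context_ids: Sequence[int],
    predicted: str,
    target: str,
) -> float:
    """Cosine similarity of contextual embeddings of prediction and target.

    Both words are embedded in the *same* preceding context, so the measure
    is symmetric in its two word arguments.
    """
    u = np.asarray(lm.embed_word(context_ids, predicted), dtype=float)
    v = np.asarray(lm.embed_word(context_ids, target), dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("zero-norm embedding vector")
    return float(np.dot(u, v) / (nu * nv))


def incremental_metrics(
    lm: LMAdapter,
    words: Sequence[str],
    word_ids: Sequence[object] | None = None,
    *,
    k_max: int = 10,
    compute_similarity: bool = True,
    max_context: int | None = None,
) -> list[PredictionState]:
    """Moving-window predictability metrics for every non-initial word.

    The first word of the passage only ever serves as context, so a passage
    of n words yields n-1 states. For the target at position i the context
    is exactly words 1..i-1; entropy is taken over the next-piece
    distribution at the target's first position, before the target is
    revealed.
    """
    if len(words) < 2:
        raise ValueError("a passage needs at least 2 words to yield metrics")
    if word_ids is None:
        word_ids = list(range(1, len(words)))
    elif len(word_ids) != len(words) - 1:
        raise ValueError("word_ids must cover the non-initial words (len(words) - 1)")

    context: list[int] = list(lm.tokenize(words[0], initial=True))
    states: list[PredictionState] = []
    for target, wid in zip(words[1:], word_ids):
        if max_context is not None and len(context) > max_context:
            raise ValueError(
                f"context of {len(context)} pieces exceeds the backend window of {max_context}"
            )
        probs = _next_piece_probs(lm, context)
        entropy_bits = shannon_entropy(probs)
        p, s_bits = word_surprisal(lm, context, target)
        top = top_k_candidates(lm, context, min(k_max, lm.vocab_size))
        similarity = None
        if compute_similarity and top:
            similarity = target_prediction_similarity(lm, context, top[0][0], target)
        states.append(
            PredictionState(
                word_id=wid,
                target_probability=p,
                entropy_bits=entropy_bits,
                surprisal_bits=s_bits,
                top_candidates=top,
                top_prediction_similarity=similarity,
            )
        )
        context.extend(lm.tokenize(target))
    return states


def top_k_accuracy(
    states: Sequence[PredictionState],
    targets: Sequence[str],
    k: int,
) -> float:
    """Fraction of targets found among the top-k candidate words.

    Matching is case-insensitive on punctuation-stripped forms, the same
    matcher used to score human cloze guesses. Non-decreasing in k.
    """
    if len(states) == 0:
        raise ValueError("no prediction states supplied")
    if len(states) != len(targets):
        raise ValueError("states and targets differ in length")
    hits = 0
    for state, target in zip(states, targets):
        want = normalize_word(target)
        got = {normalize_word(w) for w, _ in state.top_candidates[:k]}
        hits += want in got
    return hits / len(states)
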