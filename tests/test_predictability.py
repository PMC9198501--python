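"""Information-theoretic metrics and the moving-window walker."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazelm import (
    incremental_metrics,
    shannon_entropy,
    softmax_normalize,
    target_prediction_similarity,
    top_k_accuracy,
    top_k_candidates,
    word_surprisal,
)
from gazelm.predictability import PredictionState


class TwoPieceLM:
    """Minimal multi-subword adapter for chain-rule and decoding checks.

    Pieces: 0="he" (word-initial), 1="llo" (continuation), 2="hi"
    (word-initial). Words: "hello" -> [0, 1], "hi" -> [2]. The next-piece
    distribution is fixed: P(he)=0.5, P(llo)=0.5 after "he", else
    P(hi)=0.5 — so P(hello) = 0.25 and P(hi) = 0.5.
    """

    vocab_size = 3
    _words = {"hello": [0, 1], "hi": [2]}
    _pieces = ["he", "llo", "hi"]

    def tokenize(self, word, *, initial=False):
        return list(self._words[word])

    def piece(self, token_id):
        return self._pieces[token_id]

    def is_word_initial(self, token_id):
        return token_id != 1

    def logits(self, context_ids):
        if context_ids and context_ids[-1] == 0:  # after "he": only "llo" or "hi"
            p = np.array([1e-12, 0.5, 0.5])
        else:
            p = np.array([0.5, 1e-12, 0.5])
        return np.log(p)

    def embed_word(self, context_ids, word):
        return np.zeros(3)  # zero-norm, for the error path


class TestSoftmax:
    def test_analytic_values(self):
        np.testing.assert_allclose(softmax_normalize([0.0, 0.0]), [0.5, 0.5], atol=1e-12)
        np.testing.assert_allclose(
            softmax_normalize([math.log(2), 0.0]), [2 / 3, 1 / 3], atol=1e-12
        )

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-30, 30), min_size=1, max_size=8),
        st.floats(-100, 100),
    )
    def test_shift_invariance_and_normalization(self, logits, shift):
        p = softmax_normalize(np.array(logits))
        q = softmax_normalize(np.array(logits) + shift)
        np.testing.assert_allclose(p, q, atol=1e-9)
        assert p.min() >= 0 and abs(p.sum() - 1) < 1e-9

    def test_rejects_empty_and_nonfinite(self):
        with pytest.raises(ValueError):
            softmax_normalize(np.array([]))
        with pytest.raises(ValueError):
            softmax_normalize(np.array([0.0, np.inf]))


class TestEntropy:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.25, 0.25, 0.25, 0.25], 2.0),
            ([1.0, 0.0, 0.0], 0.0),
            ([0.5, 0.25, 0.25], 1.5),
        ],
    )
    def test_analytic_values(self, p, expected):
        assert shannon_entropy(np.array(p)) == pytest.approx(expected, abs=1e-12)

    def test_rejects_negative_and_unnormalized(self):
        with pytest.raises(ValueError):
            shannon_entropy(np.array([0.5, -0.5, 1.0]))
        with pytest.raises(ValueError):
            shannon_entropy(np.array([0.5, 0.2]))

    def test_bounded_by_log2_v_with_equality_iff_uniform(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            v = rng.integers(2, 12)
            p = rng.dirichlet(np.ones(v))
            h = shannon_entropy(p)
            assert 0.0 <= h <= math.log2(v) + 1e-12
        assert shannon_entropy(np.full(8, 1 / 8)) == pytest.approx(3.0, abs=1e-12)


class TestWordSurprisal:
    def test_single_piece_half_probability_is_one_bit(self, hand_lm):
        ctx = hand_lm.tokenize("a")
        p, s = word_surprisal(hand_lm, ctx, "a")  # P(a|a) = 0.5
        assert (p, s) == (pytest.approx(0.5, abs=1e-12), pytest.approx(1.0, abs=1e-12))

    def test_chain_rule_additivity_over_pieces(self):
        lm = TwoPieceLM()
        p, s = word_surprisal(lm, [2], "hello")  # 0.5 * 0.5
        assert p == pytest.approx(0.25, abs=1e-9)
        assert s == pytest.approx(2.0, abs=1e-9)
        # additivity: word surprisal equals the sum of piece surprisals
        p1, s1 = word_surprisal(lm, [2], "hi")
        assert s1 == pytest.approx(1.0, abs=1e-9)

    def test_toy_bigram_oracle(self, hand_lm):
        ctx = hand_lm.tokenize("a")
        p, s = word_surprisal(hand_lm, ctx, "b")  # table says 0.25
        assert s == pytest.approx(2.0, abs=1e-9)

    def test_zero_probability_is_capped_and_logged(self, hand_lm, caplog):
        ctx = hand_lm.tokenize("b")  # row (1, 0, 0): P(c|b) = 0
        with caplog.at_level("WARNING"):
            p, s = word_surprisal(hand_lm, ctx, "c", cap_bits=50.0)
        assert s == 50.0 and p == pytest.approx(2.0**-50)
        assert "capping" in caplog.text


class TestIncrementalMetrics:
    def test_three_word_passage_yields_two_states(self, hand_lm):
        states = incremental_metrics(hand_lm, ["a", "b", "a"], compute_similarity=False)
        assert len(states) == 2

    def test_exhaustive_oracle_against_conditional_table(self, study_lm):
        """Pipeline H, p, S must equal brute-force values computed straight
        from the explicit conditional table at every position."""
        from gazelm import sample_passages

        corpus = sample_passages(study_lm, 1, 40, seed=5)
        words = corpus.table["surface"].tolist()
        states = incremental_metrics(study_lm, words, compute_similarity=False)
        idx = {w: i for i, w in enumerate(study_lm.vocabulary)}
        for i, state in enumerate(states, start=1):
            row = study_lm.conditional_table[(words[i - 1],)]
            nz = row[row > 0]
            h = -(nz * np.log2(nz)).sum()
            p = row[idx[words[i]]]
            assert state.entropy_bits == pytest.approx(h, abs=1e-9)
            assert state.target_probability == pytest.approx(p, abs=1e-9)
            assert state.surprisal_bits == pytest.approx(-math.log2(p), abs=1e-9)

    def test_degenerate_model_gives_zero_entropy_and_surprisal(self, degenerate):
        states = incremental_metrics(
            degenerate, ["the", "end", "is", "near"], compute_similarity=False
        )
        for s in states:
            assert s.entropy_bits == 0.0
            assert s.surprisal_bits == 0.0
            assert s.target_probability == 1.0

    def test_prefix_invariance(self, study_lm):
        """Metrics for word i depend only on words 1..i-1."""
        from gazelm import sample_passages

        corpus = sample_passages(study_lm, 1, 20, seed=9)
        words = corpus.table["surface"].tolist()
        states = incremental_metrics(study_lm, words, compute_similarity=False)
        mutated = words[:10] + list(reversed(words[10:]))
        states2 = incremental_metrics(study_lm, mutated, compute_similarity=False)
        for s1, s2 in zip(states[:9], states2[:9]):
            assert s1.entropy_bits == s2.entropy_bits
            assert s1.surprisal_bits == s2.surprisal_bits

    def test_surprisal_probability_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            PredictionState(
                word_id=1, target_probability=0.5, entropy_bits=1.0, surprisal_bits=2.0
            )

    def test_too_short_passage_rejected(self, hand_lm):
        with pytest.raises(ValueError):
            incremental_metrics(hand_lm, ["a"])


class TestTopK:
    def test_top1_is_modal_word_and_topv_is_whole_vocab(self, hand_lm):
        ctx = hand_lm.tokenize("a")
        top1 = top_k_candidates(hand_lm, ctx, 1)
        assert top1 == [("a", pytest.approx(0.5))]
        top3 = top_k_candidates(hand_lm, ctx, 3)
        assert {w for w, _ in top3} == {"a", "b", "c"}

    def test_tie_broken_by_vocabulary_index_stably(self, hand_lm):
        ctx = hand_lm.tokenize("a")
        runs = [top_k_candidates(hand_lm, ctx, 3) for _ in range(3)]
        assert runs[0] == runs[1] == runs[2]
        # b and c tie at 0.25; b has the lower vocabulary index
        assert [w for w, _ in runs[0]] == ["a", "b", "c"]

    def test_k_larger_than_vocab_rejected(self, hand_lm):
        with pytest.raises(ValueError):
            top_k_candidates(hand_lm, hand_lm.tokenize("a"), 4)

    def test_multi_piece_decoding_reranks_by_chain_probability(self):
        lm = TwoPieceLM()
        # From empty-ish context [2]: P(hi)=0.5, P(hello)=0.5*0.5=0.25.
        top = top_k_candidates(lm, [2], 2)
        assert top[0][0] == "hi" and top[0][1] == pytest.approx(0.5, abs=1e-9)
        assert top[1][0] == "hello" and top[1][1] == pytest.approx(0.25, abs=1e-9)


class TestTopKAccuracy:
    def test_degenerate_model_is_perfect_at_k1(self, degenerate):
        words = ["the", "end", "is", "near"]
        states = incremental_metrics(degenerate, words, compute_similarity=False)
        assert top_k_accuracy(states, words[1:], 1) == 1.0

    def test_monotone_nondecreasing_in_k_and_one_at_v(self, study_lm):
        from gazelm import sample_passages

        corpus = sample_passages(study_lm, 1, 30, seed=2)
        words = corpus.table["surface"].tolist()
        states = incremental_metrics(
            study_lm, words, k_max=study_lm.vocab_size, compute_similarity=False
        )
        accs = [top_k_accuracy(states, words[1:], k) for k in (1, 2, 5, 10, study_lm.vocab_size)]
        assert all(a <= b for a, b in zip(accs, accs[1:]))
        assert accs[-1] == 1.0  # in-vocabulary targets always found at k=V

    def test_rejects_empty_or_mismatched(self, degenerate):
        with pytest.raises(ValueError):
            top_k_accuracy([], [], 1)


class TestSimilarity:
    def test_identical_words_have_cosine_one(self, hand_lm):
        assert target_prediction_similarity(hand_lm, [0], "b", "b") == pytest.approx(1.0)

    def test_orthogonal_and_constructed_pairs(self, hand_lm):
        assert target_prediction_similarity(hand_lm, [0], "a", "b") == pytest.approx(0.0, abs=1e-12)
        assert target_prediction_similarity(hand_lm, [0], "b", "c") == pytest.approx(0.8, abs=1e-9)

    def test_symmetry_in_word_arguments(self, hand_lm):
        ab = target_prediction_similarity(hand_lm, [0], "b", "c")
        ba = target_prediction_similarity(hand_lm, [0], "c", "b")
        assert ab == ba

    def test_zero_norm_vector_rejected(self):
        lm = TwoPieceLM()
        with pytest.raises(ValueError, match="zero-norm"):
            target_prediction_similarity(lm, [2], "hi", "hello")
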