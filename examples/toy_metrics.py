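"""Moving-window predictability metrics on a hand-checkable toy model.

Builds a three-word bigram language model with an explicit conditional
table, walks a short passage word by word, and prints each target's
entropy (uncertainty *before* the word), surprisal (unexpectedness *at*
the word), top predictions, and target-prediction similarity.
"""

from gazelm import build_toy_lm, incremental_metrics
from gazelm.toylm import embeddings_with_similarity

vocab = ["sun", "rises", "sets"]
lm = build_toy_lm(
    vocab,
    order=1,
    conditional_table={
        "sun": [0.0, 0.5, 0.5],     # after "sun": rises or sets, a coin flip
        "rises": [1.0, 0.0, 0.0],   # after "rises": always "sun"
        "sets": [0.5, 0.25, 0.25],
    },
    embeddings=embeddings_with_similarity(vocab, related_pairs={("rises", "sets"): 0.8}),
)

passage = ["sun", "rises", "sun", "sets", "sun"]
states = incremental_metrics(lm, passage)

print(f"{'target':<8} {'p':>6} {'H bits':>7} {'S bits':>7}  top prediction (sim)")
for word, s in zip(passage[1:], states):
    top_word, top_p = s.top_candidates[0]
    print(
        f"{word:<8} {s.target_probability:>6.3f} {s.entropy_bits:>7.3f} "
        f"{s.surprisal_bits:>7.3f}  {top_word} @ {top_p:.2f} "
        f"(cos {s.top_prediction_similarity:+.2f})"
    )

print(
    "\nEntropy is the uncertainty of the context before the target appears\n"
    "(1 bit for the sun->rises/sets coin flip, 0 after 'rises'); surprisal\n"
    "is -log2 of the target's probability (1 bit for a 50% word, 0 for a\n"
    "certain one). The similarity column compares contextual embeddings of\n"
    "the model's top prediction and the actual target: 1.0 when the\n"
    "prediction was right, 0.8 for the constructed related pair rises/sets."
)
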