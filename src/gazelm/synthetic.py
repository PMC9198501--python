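"""Synthetic study generator with known ground truth.

Emulates the statistical structure of a passage-reading eye-tracking study:
passages sampled from an explicit toy language model, per-participant gaze
records drawn from logistic (skip, regression-in) and log-normal (first
fixation, gaze duration) models whose linear predictors use the word's
entropy, surprisal, their interaction, log frequency, length and position
in sentence, with crossed random intercepts for participant, word item and
text; and word-by-word cloze norms sampled from the toy model's own
conditional distributions.

Because every coefficient and random-effect standard deviation is known,
the downstream mixed models can be checked for parameter recovery, and the
cloze summaries have analytic expectations.

Default generative coefficients are anchored, where the underlying study
reports an effect, to its scale and sign (e.g. the entropy odds ratio on
skipping of 0.93/bit, the surprisal slope of 0.02/bit on log gaze duration,
the surprisal odds ratio 1.25/bit on regressions, a ~45% base skip rate);
the remaining values are field-realistic choices documented in the methods
note. What the generator deliberately does not imitate: saccade-planning
dynamics, parafoveal preview, refixation sequences — only the statistical
structure the analysis models assume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._text import normalize_word
from .corpus import PassageCorpus
from .predictability import PredictionState
from .toylm import ToyLM

__all__ = [
    "GazeSimConfig",
    "DEFAULT_BETAS",
    "pseudo_vocabulary",
    "sample_passages",
    "simulate_gaze",
    "sample_cloze_responses",
    "simulate_cloze",
    "toy_frequency_table",
]

#: Linear-predictor terms of each generative model, in order.
TERMS = (
    "intercept",
    "entropy",
    "surprisal",
    "entropy_x_surprisal",
    "log_frequency",
    "length",
    "word_number",
)

#: Default generative coefficients for the four outcome models. Entropy and
#: surprisal enter in bits; durations are modelled on the natural-log
#: millisecond scale. word_number is left at zero in the binary models so the
#: simulator carries genuinely null terms for calibration checks.
DEFAULT_BETAS: dict[str, dict[str, float]] = {
    "skip": {
        "intercept": -0.1,
        "entropy": -0.073,          # OR 0.93 per bit
        "surprisal": -0.05,
        "entropy_x_surprisal": -0.01,
        "log_frequency": 0.25,
        "length": -0.12,
        "word_number": 0.0,
    },
    "first_fixation": {
        "intercept": 5.35,
        "entropy": 0.01,
        "surprisal": 0.01,
        "entropy_x_surprisal": -0.004,
        "log_frequency": -0.02,
        "length": 0.01,
        "word_number": -0.002,
    },
    "gaze": {
        "intercept": 5.40,
        "entropy": 0.01,
        "surprisal": 0.02,
        "entropy_x_surprisal": 0.0,
        "log_frequency": -0.02,
        "length": 0.012,
        "word_number": -0.002,
    },
    "regression": {
        "intercept": -1.7,
        "entropy": 0.077,           # OR 1.08 per bit
        "surprisal": 0.223,         # OR 1.25 per bit
        "entropy_x_surprisal": 0.0,
        "log_frequency": -0.05,
        "length": 0.02,
        "word_number": 0.0,
    },
}


@dataclass
class GazeSimConfig:
    """Generative settings for :func:`simulate_gaze`.

    beta maps one coefficient set per outcome model (keys of
    :data:`DEFAULT_BETAS`); sd_* are the random-intercept standard
    deviations shared across the four models plus the residual SD of the
    log-duration models. ``refix_prob``/``refix_sd`` govern the
    non-negative multiplicative increment that keeps gaze ≥ FFD, and
    ``total_extra_prob``/``total_extra_sd`` likewise for total ≥ gaze.
    """

    n_participants: int = 20
    beta: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_BETAS.items()}
    )
    sd_participant: float = 0.15
    sd_item: float = 0.10
    sd_text: float = 0.05
    sd_resid: float = 0.30
    refix_prob: float = 0.35
    refix_sd: float = 0.40
    total_extra_prob: float = 0.40
    total_extra_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        for name in ("sd_participant", "sd_item", "sd_text", "sd_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        missing = set(DEFAULT_BETAS) - set(self.beta)
        if missing:
            raise ValueError(f"beta lacks outcome models: {sorted(missing)}")
        for outcome, coefs in self.beta.items():
            unknown = set(coefs) - set(TERMS)
            if unknown:
                raise ValueError(f"unknown terms for {outcome}: {sorted(unknown)}")

    def with_null_effects(self) -> "GazeSimConfig":
        """Copy with every coefficient (including intercepts) set to zero."""
        zero = {k: {t: 0.0 for t in TERMS} for k in self.beta}
        return replace(self, beta=zero)

    def marginal_intercept_shift(self, outcome: str) -> float:
        """Known offset between a configured intercept and the marginal one.

        The non-negative refixation increment that keeps gaze >= FFD has
        mean refix_prob * refix_sd * sqrt(2/pi); it shifts the marginal
        log-gaze intercept by exactly that amount while leaving every slope
        untouched. Other outcomes have no shift.
        """
        if outcome == "gaze":
            return self.refix_prob * self.refix_sd * math.sqrt(2.0 / math.pi)
        return 0.0


def pseudo_vocabulary(n: int, seed: int = 20_260_101) -> list[str]:
    """Distinct lowercase pseudo-words with naturally varying lengths.

    Word lengths are drawn from 2-9 letters (roughly the spread of English
    content words) so the length-in-letters covariate has variance; the
    list is deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    letters = np.array(list("abcdefghijklmnopqrstuvwxyz"))
    lengths = rng.integers(2, 10, size=4 * n)
    words: list[str] = []
    seen: set[str] = set()
    i = 0
    while len(words) < n:
        if i >= len(lengths):  # top up if collisions exhausted the draw
            lengths = np.concatenate([lengths, rng.integers(2, 10, size=4 * n)])
        w = "".join(rng.choice(letters, size=lengths[i]))
        i += 1
        if w not in seen:
            seen.add(w)
            words.append(w)
    return words


def sample_passages(
    lm: ToyLM,
    n_passages: int,
    length: int,
    seed: int,
    *,
    sentence_every: int = 11,
) -> PassageCorpus:
    """Sample passages from the toy model's conditional table.

    The initial order-length context is drawn uniformly from the table's
    contexts; every subsequent word from the conditional row. Words every
    ``sentence_every`` positions are marked sentence-final so the
    word-number-in-sentence covariate varies. Identical seeds reproduce the
    corpus bit-identically.
    """
    if length <= lm.order:
        raise ValueError(f"passage length {length} must exceed model order {lm.order}")
    rng = np.random.default_rng(seed)
    contexts = sorted(lm.conditional_table)
    v = lm.vocab_size
    rows = []
    wid = 0
    for tid in range(1, n_passages + 1):
        start = contexts[rng.integers(len(contexts))]
        words = list(start)
        while len(words) < length:
            key = tuple(words[-lm.order:]) if lm.order else ()
            row = lm.conditional_table.get(key)
            if row is None:
                raise KeyError(f"context {key!r} is unreachable (no conditional row)")
            words.append(lm.vocabulary[rng.choice(v, p=row)])
        wn = 1
        for pos, surface in enumerate(words):
            final = (pos + 1) % sentence_every == 0 or pos == length - 1
            rows.append((wid, tid, pos, surface, wn, final))
            wid += 1
            wn = 1 if final else wn + 1
    table = pd.DataFrame(
        rows,
        columns=["word_id", "text_id", "position", "surface",
                 "word_number_in_sentence", "sentence_final"],
    )
    return PassageCorpus(table)


def toy_frequency_table(vocabulary: Sequence[str]) -> dict[str, float]:
    """Zipf-like per-million frequencies for the toy vocabulary.

    Word i (1-based in vocabulary order) gets 10000 / i occurrences per
    million, so log10 frequency spans a realistic few decades.
    """
    return {w: 10000.0 / (i + 1) for i, w in enumerate(vocabulary)}


def _design_row(metrics_row, log_freq: float, length: int, word_number: int) -> dict[str, float]:
    h = metrics_row["entropy_bits"]
    s = metrics_row["surprisal_bits"]
    return {
        "intercept": 1.0,
        "entropy": h,
        "surprisal": s,
        "entropy_x_surprisal": h * s,
        "log_frequency": log_freq,
        "length": float(length),
        "word_number": float(word_number),
    }


def _linear_predictor(x: pd.DataFrame, coefs: Mapping[str, float]) -> np.ndarray:
    eta = np.zeros(len(x))
    for term, b in coefs.items():
        if b != 0.0:
            eta = eta + b * x[term].to_numpy()
    return eta


def simulate_gaze(
    corpus: PassageCorpus,
    metrics: Sequence[PredictionState] | pd.DataFrame,
    config: GazeSimConfig,
    frequency: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Draw per-participant gaze records for every word carrying metrics.

    One row per participant × word. Skips and regressions are Bernoulli
    draws from logistic models; first fixation durations are log-normal;
    gaze duration is the FFD-model draw times a non-negative refixation
    increment drawn from its own linear predictor (so the log-gaze model
    stays linear with the configured slopes; the rare cell where the gaze
    draw falls below the FFD draw is clamped and counted in
    ``.attrs['n_gaze_clamped']``); total time multiplies gaze by a further
    non-negative re-reading factor. Skipped words carry absent (NaN)
    durations, never zeros. Random intercepts are one shared draw per
    participant/item/text across the four models.
    """
    if isinstance(metrics, pd.DataFrame):
        mtable = metrics.copy()
    else:
        mtable = pd.DataFrame(
            {
                "word_id": [s.word_id for s in metrics],
                "entropy_bits": [s.entropy_bits for s in metrics],
                "surprisal_bits": [s.surprisal_bits for s in metrics],
            }
        )
    words = corpus.table.set_index("word_id")
    missing = set(mtable["word_id"]) - set(words.index)
    if missing:
        raise ValueError(f"metrics reference unknown word_ids: {sorted(missing)[:10]}")
    non_initial = words.index[words["position"] > 0]
    lacking = sorted(set(non_initial) - set(mtable["word_id"]))
    if lacking:
        raise ValueError(f"metrics missing for non-initial words: {lacking[:10]}")

    if frequency is None:
        vocab = sorted(set(words["surface"].map(normalize_word)))
        frequency = {w: float(np.log10(f)) for w, f in toy_frequency_table(vocab).items()}

    mtable = mtable.merge(
        words[["text_id", "surface", "word_number_in_sentence"]],
        left_on="word_id",
        right_index=True,
    )
    design_rows = []
    for _, row in mtable.iterrows():
        key = normalize_word(str(row["surface"]))
        if key not in frequency:
            raise ValueError(f"no frequency for word {row['surface']!r} (id {row['word_id']})")
        design_rows.append(
            _design_row(row, frequency[key], len(key), int(row["word_number_in_sentence"]))
        )
    design = pd.DataFrame(design_rows)
    n_words = len(mtable)
    n = config.n_participants

    rng = np.random.default_rng(config.seed)
    participants = np.arange(1, n + 1)
    u_part = rng.normal(0.0, config.sd_participant, size=n)
    item_ids = mtable["word_id"].to_numpy()
    u_item = rng.normal(0.0, config.sd_item, size=n_words)
    text_ids = mtable["text_id"].to_numpy()
    uniq_texts = pd.unique(text_ids)
    u_text_map = dict(zip(uniq_texts, rng.normal(0.0, config.sd_text, size=len(uniq_texts))))
    u_text = np.array([u_text_map[t] for t in text_ids])

    eta = {k: _linear_predictor(design, config.beta[k]) for k in DEFAULT_BETAS}

    frames = []
    n_clamped = 0
    for i, pid in enumerate(participants):
        re_sum = u_part[i] + u_item + u_text
        p_skip = 1.0 / (1.0 + np.exp(-(eta["skip"] + re_sum)))
        skipped = rng.random(n_words) < p_skip

        eps = rng.normal(0.0, config.sd_resid, size=n_words)
        log_ffd = eta["first_fixation"] + re_sum + eps
        refix = (rng.random(n_words) < config.refix_prob) * np.abs(
            rng.normal(0.0, config.refix_sd, size=n_words)
        )
        log_gaze = eta["gaze"] + re_sum + eps + refix
        clamp = log_gaze < log_ffd
        n_clamped += int((clamp & ~skipped).sum())
        log_gaze = np.maximum(log_gaze, log_ffd)
        extra = (rng.random(n_words) < config.total_extra_prob) * np.abs(
            rng.normal(0.0, config.total_extra_sd, size=n_words)
        )
        log_total = log_gaze + extra

        p_reg = 1.0 / (1.0 + np.exp(-(eta["regression"] + re_sum)))
        regression = rng.random(n_words) < p_reg

        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "word_id": item_ids,
                    "skipped": skipped,
                    "first_fixation_ms": np.where(skipped, np.nan, np.exp(log_ffd)),
                    "gaze_ms": np.where(skipped, np.nan, np.exp(log_gaze)),
                    "total_ms": np.where(skipped, np.nan, np.exp(log_total)),
                    "regression_in": regression,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.attrs["n_gaze_clamped"] = n_clamped
    return out


def sample_cloze_responses(
    lm: ToyLM,
    corpus: PassageCorpus,
    n_respondents: int,
    seed: int,
) -> pd.DataFrame:
    """Simulated word-by-word cloze task: every respondent guesses each
    non-initial word from the toy model's conditional distribution given
    the true preceding context.

    Returns one row per respondent × word: ``respondent_id, word_id,
    guess, target``.
    """
    if n_respondents < 1:
        raise ValueError("need at least one respondent")
    rng = np.random.default_rng(seed)
    vocab = np.asarray(lm.vocabulary, dtype=object)
    rows = []
    for _, passage in corpus.passages():
        surfaces = passage["surface"].tolist()
        ids = passage["word_id"].tolist()
        context = list(lm.tokenize(surfaces[0], initial=True))
        for pos in range(1, len(surfaces)):
            probs = lm.next_word_probs(context)
            guesses = vocab[rng.choice(lm.vocab_size, size=n_respondents, p=probs)]
            rows.append(
                pd.DataFrame(
                    {
                        "respondent_id": np.arange(1, n_respondents + 1),
                        "word_id": ids[pos],
                        "guess": guesses,
                        "target": surfaces[pos],
                    }
                )
            )
            context.extend(lm.tokenize(surfaces[pos]))
    return pd.concat(rows, ignore_index=True)


def simulate_cloze(
    lm: ToyLM,
    corpus: PassageCorpus,
    n_respondents: int,
    seed: int,
) -> pd.Series:
    """Cloze norms from the simulated task: per non-initial word, the
    fraction of respondents whose guess matched the actual next word
    (matching normalized forms, as when scoring human accuracy).

    Finite respondent pools floor rare words at exactly zero — the cloze
    floor effect real norms exhibit.
    """
    responses = sample_cloze_responses(lm, corpus, n_respondents, seed)
    hits = responses["guess"].map(normalize_word) == responses["target"].map(normalize_word)
    norms = hits.groupby(responses["word_id"]).mean()
    norms.name = "cloze_probability"
    return norms
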