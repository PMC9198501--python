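"""Validity checks of LM predictions against word-by-word cloze norms.

Cloze norms estimate a word's predictability as the fraction of human
respondents who guess it from the preceding context. A finite respondent
pool floors rare continuations at exactly zero, so the share of zero-cloze
words and the logit-scale shape of the distribution are the diagnostic
summaries, alongside a human-vs-model next-word accuracy comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._text import normalize_word
from .predictability import PredictionState, top_k_accuracy

__all__ = [
    "AccuracySummary",
    "probability_to_logit",
    "zero_probability_fraction",
    "human_accuracy_stats",
    "model_accuracy_curve",
]

log = logging.getLogger(__name__)


@dataclass
class AccuracySummary:
    """Next-word prediction accuracy, human side and/or model side.

    ``per_respondent`` holds each human respondent's fraction of exact
    matches; ``model_topk`` maps k → (accuracy, SEM across passages; SEM is
    None with fewer than two passages).
    """

    per_respondent: pd.Series | None = None
    mean: float | None = None
    sd: float | None = None
    maximum: float | None = None
    model_topk: dict[int, tuple[float, float | None]] = field(default_factory=dict)


def probability_to_logit(p):
    """ln(p / (1-p)) with ±inf sentinels at 0 and 1, never clipped.

    Accepts scalars or arrays; strictly monotone on (0, 1), so order
    statistics of probabilities are preserved on the logit scale.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        out = np.where(arr == 0.0, -np.inf, np.where(arr == 1.0, np.inf, np.log(arr / (1.0 - arr))))
    if np.isscalar(p) or np.ndim(p) == 0:
        return float(out)
    return out


def zero_probability_fraction(norms: pd.Series | np.ndarray) -> float:
    """Share of word tokens whose cloze probability is exactly zero."""
    vals = np.asarray(pd.Series(norms).dropna(), dtype=float)
    if vals.size == 0:
        raise ValueError("no cloze norms supplied")
    return float((vals == 0.0).mean())


def human_accuracy_stats(responses: pd.DataFrame) -> AccuracySummary:
    """Per-respondent next-word accuracy from scored cloze responses.

    ``responses`` needs columns respondent_id, guess, target; a guess scores
    a hit when its normalized form (case-insensitive, punctuation-stripped —
    the same matcher used for model top-k accuracy) equals the target's.
    Respondents with no scored items are excluded with a log entry.
    """
    required = {"respondent_id", "guess", "target"}
    if not required <= set(responses.columns):
        raise ValueError(f"responses table needs columns {sorted(required)}")
    scored = responses.dropna(subset=["guess", "target"])
    excluded = set(responses["respondent_id"]) - set(scored["respondent_id"])
    if excluded:
        log.info("excluding %d respondents with no scored guesses", len(excluded))
    if scored.empty:
        raise ValueError("no scorable responses")
    hits = scored["guess"].map(normalize_word) == scored["target"].map(normalize_word)
    per = hits.groupby(scored["respondent_id"]).mean()
    return AccuracySummary(
        per_respondent=per,
        mean=float(per.mean()),
        sd=float(per.std(ddof=1)) if len(per) > 1 else 0.0,
        maximum=float(per.max()),
    )


def model_accuracy_curve(
    states: list[PredictionState],
    targets: list[str],
    passage_ids: list | None = None,
    *,
    k_max: int = 10,
) -> AccuracySummary:
    """Model top-k accuracy for k = 1..k_max with SEM across passages.

    The grouping unit for the standard error is the passage; with fewer
    than two passages the SEM is reported as None.
    """
    if len(states) != len(targets):
        raise ValueError("states and targets differ in length")
    if any(len(s.top_candidates) < k_max for s in states):
        raise ValueError(f"states carry fewer than k_max={k_max} candidates")
    if passage_ids is not None and len(passage_ids) != len(states):
        raise ValueError("passage_ids must align with states")

    curve: dict[int, tuple[float, float | None]] = {}
    for k in range(1, k_max + 1):
        acc = top_k_accuracy(states, targets, k)
        sem = None
        if passage_ids is not None:
            df = pd.DataFrame({"pid": passage_ids, "hit": [
                normalize_word(t) in {normalize_word(w) for w, _ in s.top_candidates[:k]}
                for s, t in zip(states, targets)
            ]})
            per_passage = df.groupby("pid")["hit"].mean()
            if len(per_passage) >= 2:
                sem = float(per_passage.std(ddof=1) / math.sqrt(len(per_passage)))
        curve[k] = (acc, sem)
    return AccuracySummary(model_topk=curve)
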