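"""Shared fixtures: hand-checkable toy models and small synthetic studies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gazelm import (
    GazeSimConfig,
    build_toy_lm,
    degenerate_cycle_lm,
    incremental_metrics,
    merge_observations,
    random_lm,
    sample_passages,
    simulate_gaze,
    uniform_lm,
)
from gazelm.pipeline import states_to_frame
from gazelm.synthetic import pseudo_vocabulary, toy_frequency_table
from gazelm.toylm import embeddings_with_similarity


@pytest.fixture
def hand_lm():
    """3-word bigram model with a hand-computed conditional table.

    Context "a" -> (0.5, 0.25, 0.25) over (a, b, c); "b" and "c" rows are
    degenerate-ish for easy hand checks. Embeddings put (b, c) at cosine
    0.8 and everything else orthogonal.
    """
    emb = embeddings_with_similarity(["a", "b", "c"], related_pairs={("b", "c"): 0.8})
    return build_toy_lm(
        ["a", "b", "c"],
        1,
        {
            "a": [0.5, 0.25, 0.25],
            "b": [1.0, 0.0, 0.0],
            "c": [0.25, 0.25, 0.5],
        },
        emb,
    )


@pytest.fixture
def uniform4():
    return uniform_lm(["a", "b", "c", "d"])


@pytest.fixture
def degenerate():
    return degenerate_cycle_lm(["the", "end", "is", "near"])


@pytest.fixture(scope="session")
def study_lm():
    """Session-wide richer toy model for statistical tests."""
    return random_lm(pseudo_vocabulary(60), seed=7)


@pytest.fixture(scope="session")
def study_log_freq(study_lm):
    return {w: float(np.log10(f)) for w, f in toy_frequency_table(study_lm.vocabulary).items()}


def make_study(lm, log_freq, *, n_passages, length, config, corpus_seed=11,
               compute_similarity=False):
    """Sample passages, metrics, gaze and the merged observation table."""
    corpus = sample_passages(lm, n_passages, length, corpus_seed)
    states = []
    for _, passage in corpus.passages():
        states += incremental_metrics(
            lm,
            passage["surface"].tolist(),
            passage["word_id"].tolist()[1:],
            k_max=10,
            compute_similarity=compute_similarity,
        )
    metrics = states_to_frame(states)
    gaze = simulate_gaze(corpus, metrics, config, log_freq)
    obs = merge_observations(corpus, gaze, metrics, frequency=log_freq)
    return corpus, states, metrics, gaze, obs


@pytest.fixture(scope="session")
def small_study(study_lm, study_log_freq):
    """2 passages x 60 words x 12 participants: fast but non-trivial."""
    config = GazeSimConfig(n_participants=12, seed=3)
    return make_study(
        study_lm, study_log_freq, n_passages=2, length=60, config=config,
        compute_similarity=True,
    )


@pytest.fixture(scope="session")
def degenerate_fits(study_lm, study_log_freq):
    """Zero random-effect variance study plus its mixed fits (one R batch).

    In this limit the crossed mixed models collapse to single-level
    regressions, giving an exact oracle for the fixed effects.
    """
    from gazelm import duration_model, fit_mixed_many, regression_model, skip_model

    config = GazeSimConfig(
        n_participants=40, seed=21,
        sd_participant=0.0, sd_item=0.0, sd_text=0.0,
    )
    corpus, _, metrics, gaze, obs = make_study(
        study_lm, study_log_freq, n_passages=3, length=80, config=config,
    )
    fixated = obs.loc[~obs["skipped"]]
    fits = fit_mixed_many(
        [
            ("skip", skip_model(), obs),
            ("gaze", duration_model("gaze"), fixated),
            ("regression", regression_model(), obs),
        ]
    )
    return obs, fixated, fits


def design_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effect design of the standard analyses, for single-level oracles."""
    import statsmodels.api as sm

    x = table[["entropy_bits", "surprisal_bits", "log_frequency",
               "length_letters", "word_number_in_sentence"]].copy()
    x["interaction"] = x["entropy_bits"] * x["surprisal_bits"]
    return sm.add_constant(x)
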