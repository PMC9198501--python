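"""Synthetic study generator: passages, gaze records, cloze responses."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from gazelm import (
    GazeSimConfig,
    degenerate_cycle_lm,
    sample_passages,
    simulate_cloze,
    simulate_gaze,
    uniform_lm,
)
from gazelm.synthetic import TERMS, pseudo_vocabulary, toy_frequency_table
from tests.conftest import make_study


def zero_config(n_participants=200, seed=0, overrides=None):
    beta = {k: {t: 0.0 for t in TERMS} for k in ("skip", "first_fixation", "gaze", "regression")}
    for (model, term), val in (overrides or {}).items():
        beta[model][term] = val
    return GazeSimConfig(
        n_participants=n_participants, beta=beta,
        sd_participant=0.0, sd_item=0.0, sd_text=0.0, sd_resid=0.0,
        refix_prob=0.0, total_extra_prob=0.0, seed=seed,
    )


class TestSamplePassages:
    def test_identical_seed_reproduces_corpus(self, study_lm):
        a = sample_passages(study_lm, 2, 30, seed=42)
        b = sample_passages(study_lm, 2, 30, seed=42)
        pd.testing.assert_frame_equal(a.table, b.table)
        c = sample_passages(study_lm, 2, 30, seed=43)
        assert not a.table["surface"].equals(c.table["surface"])

    def test_degenerate_model_yields_constant_cycle(self):
        lm = degenerate_cycle_lm(["u", "v", "w"])
        corpus = sample_passages(lm, 1, 9, seed=0)
        words = corpus.table["surface"].tolist()
        start = ["u", "v", "w"].index(words[0])
        expected = [["u", "v", "w"][(start + i) % 3] for i in range(9)]
        assert words == expected

    def test_length_must_exceed_order(self, study_lm):
        with pytest.raises(ValueError):
            sample_passages(study_lm, 1, 1, seed=0)

    def test_corpus_scale_configuration(self, study_lm):
        corpus = sample_passages(study_lm, 5, 50, seed=0)
        assert corpus.n_tokens == 250
        assert corpus.table["text_id"].nunique() == 5


class TestSimulateGaze:
    def test_null_model_skips_at_one_half(self, study_lm, study_log_freq):
        _, _, metrics, gaze, _ = make_study(
            study_lm, study_log_freq, n_passages=1, length=30,
            config=zero_config(n_participants=200),
        )
        rate = gaze["skipped"].mean()
        # 200 x 29 Bernoulli(0.5) draws: 4 sigma ~ 0.026
        assert abs(rate - 0.5) < 0.026

    def test_entropy_coefficient_raises_skip_rate_across_tertiles(
        self, study_lm, study_log_freq
    ):
        # centre the logit so skip rates sit mid-range across the entropy span
        cfg = zero_config(n_participants=200,
                          overrides={("skip", "intercept"): -4.75,
                                     ("skip", "entropy"): 1.0})
        corpus, _, metrics, gaze, _ = make_study(
            study_lm, study_log_freq, n_passages=2, length=60, config=cfg,
        )
        merged = gaze.merge(metrics[["word_id", "entropy_bits"]], on="word_id")
        tertile = pd.qcut(merged["entropy_bits"], 3, labels=False, duplicates="drop")
        rates = merged.groupby(tertile)["skipped"].mean()
        assert rates.is_monotonic_increasing

    def test_ffd_surprisal_slope_recovered_by_ols(self, study_lm, study_log_freq):
        from dataclasses import replace

        estimates, ses = [], []
        for seed in range(5):  # average over replicates for a stable oracle
            cfg = replace(
                zero_config(
                    n_participants=100, seed=seed,
                    overrides={("first_fixation", "intercept"): 5.4,
                               ("first_fixation", "surprisal"): 0.05},
                ),
                sd_resid=0.3,
            )
            _, _, metrics, gaze, obs = make_study(
                study_lm, study_log_freq, n_passages=2, length=60, config=cfg,
            )
            fixated = obs.loc[~obs["skipped"]]
            # word-level oracle: regress each word's sample-mean log FFD on
            # its surprisal (removes participant pseudo-replication)
            per_word = fixated.groupby("word_id").agg(
                mean_log_ffd=("first_fixation_ms", lambda x: np.log(x).mean()),
                surprisal=("surprisal_bits", "first"),
            )
            fit = sm.OLS(
                per_word["mean_log_ffd"], sm.add_constant(per_word["surprisal"])
            ).fit()
            estimates.append(fit.params["surprisal"])
            ses.append(fit.bse["surprisal"])
        pooled_se = np.mean(ses) / np.sqrt(len(ses))
        assert abs(np.mean(estimates) - 0.05) < 2 * pooled_se

    def test_row_count_and_duration_invariants(self, small_study):
        corpus, _, metrics, gaze, _ = small_study
        assert len(gaze) == 12 * len(metrics)
        skipped = gaze.loc[gaze["skipped"]]
        assert skipped[["first_fixation_ms", "gaze_ms", "total_ms"]].isna().all().all()
        fixated = gaze.loc[~gaze["skipped"]]
        assert (fixated["gaze_ms"] >= fixated["first_fixation_ms"] - 1e-9).all()
        assert (fixated["total_ms"] >= fixated["gaze_ms"] - 1e-9).all()
        assert (fixated["first_fixation_ms"] > 0).all()

    def test_identical_seed_reproduces_records(self, study_lm, study_log_freq):
        cfg = GazeSimConfig(n_participants=5, seed=77)
        out = [
            make_study(study_lm, study_log_freq, n_passages=1, length=25, config=cfg)[3]
            for _ in range(2)
        ]
        pd.testing.assert_frame_equal(out[0], out[1])

    def test_missing_covariate_names_words(self, study_lm, study_log_freq):
        corpus, _, metrics, _, _ = make_study(
            study_lm, study_log_freq, n_passages=1, length=20,
            config=GazeSimConfig(n_participants=3, seed=0),
        )
        partial = {k: v for k, v in study_log_freq.items()
                   if k != corpus.table["surface"].iloc[5]}
        with pytest.raises(ValueError, match="no frequency"):
            simulate_gaze(corpus, metrics, GazeSimConfig(n_participants=3, seed=0), partial)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GazeSimConfig(n_participants=1)
        with pytest.raises(ValueError):
            GazeSimConfig(sd_item=-0.1)
        with pytest.raises(ValueError, match="unknown terms"):
            GazeSimConfig(beta={**{k: {} for k in ("skip", "first_fixation", "gaze", "regression")},
                                "skip": {"nope": 1.0}})


class TestSimulateCloze:
    def test_degenerate_model_gives_cloze_one_everywhere(self):
        lm = degenerate_cycle_lm(["u", "v", "w"])
        corpus = sample_passages(lm, 1, 9, seed=0)
        norms = simulate_cloze(lm, corpus, 15, seed=1)
        assert (norms == 1.0).all()

    def test_uniform_model_converges_to_quarter(self):
        lm = uniform_lm(["a", "b", "c", "d"])
        corpus = sample_passages(lm, 1, 12, seed=0)
        norms = simulate_cloze(lm, corpus, 10_000, seed=2)
        assert np.abs(norms - 0.25).max() < 0.02

    def test_finite_respondents_floor_rare_words_at_zero(self):
        from gazelm import build_toy_lm

        # rare continuation: P(b|a) = 0.01
        lm = build_toy_lm(["a", "b"], 1, {"a": [0.99, 0.01], "b": [1.0, 0.0]})
        corpus = sample_passages(lm, 1, 60, seed=3)
        norms = simulate_cloze(lm, corpus, 20, seed=4)
        targets = corpus.table.set_index("word_id")["surface"]
        rare = norms[targets.loc[norms.index] == "b"]
        if len(rare):  # the passage contains at least one rare word by construction
            assert (rare == 0.0).any()
        assert norms.between(0, 1).all()

    def test_determinism_and_respondent_validation(self, study_lm):
        corpus = sample_passages(study_lm, 1, 15, seed=5)
        a = simulate_cloze(study_lm, corpus, 30, seed=6)
        b = simulate_cloze(study_lm, corpus, 30, seed=6)
        pd.testing.assert_series_equal(a, b)
        with pytest.raises(ValueError):
            simulate_cloze(study_lm, corpus, 0, seed=0)


def test_pseudo_vocabulary_is_distinct_with_varying_lengths():
    vocab = pseudo_vocabulary(100)
    assert len(set(vocab)) == 100
    lengths = {len(w) for w in vocab}
    assert lengths <= set(range(2, 10)) and len(lengths) > 3


def test_toy_frequency_table_is_zipf_like():
    freqs = toy_frequency_table(["a", "b", "c", "d"])
    assert freqs["a"] == 10000.0 and freqs["b"] == 5000.0
    assert all(f > 0 for f in freqs.values())
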