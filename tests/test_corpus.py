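"""Corpus I/O: loaders, validation, and the observation merge."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gazelm import (
    PassageCorpus,
    load_cloze_norms,
    load_eye_movement_report,
    load_frequency_table,
    load_passages,
    merge_observations,
)


class TestPassageCorpus:
    def test_two_passages_get_unique_ids(self):
        corpus = PassageCorpus.from_passages([["a", "b", "c"], ["d", "e", "f"]])
        assert corpus.n_tokens == 6
        assert corpus.table["text_id"].nunique() == 2
        assert corpus.table["word_id"].is_unique

    def test_word_number_resets_after_sentence_final(self):
        corpus = PassageCorpus.from_passages([["A", "b.", "C", "d."]])
        assert corpus.table["word_number_in_sentence"].tolist() == [1, 2, 1, 2]

    def test_empty_passage_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            PassageCorpus.from_passages([["a"], []])

    def test_duplicate_word_ids_rejected(self):
        table = PassageCorpus.from_passages([["a", "b"]]).table
        bad = pd.concat([table, table], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            PassageCorpus(bad)

    def test_type_counting_is_case_insensitive_and_punctuation_stripped(self):
        corpus = PassageCorpus.from_passages([["The", "dog.", "the", "dog"]])
        assert corpus.n_types() == 2
        assert corpus.n_types(normalize=False) == 4

    def test_load_passages_round_trip(self, tmp_path):
        corpus = PassageCorpus.from_passages([["A", "b.", "C", "d."], ["x", "y"]])
        path = tmp_path / "passages.csv"
        corpus.table.rename(columns={"surface": "word"}).to_csv(path, index=False)
        loaded = load_passages(path)
        pd.testing.assert_frame_equal(
            loaded.table[corpus.table.columns], corpus.table
        )


class TestGazeReport:
    def _frame(self):
        return pd.DataFrame(
            {
                "Participant_ID": [1, 1, 1, 2, 2, 2],
                "Word_Unique_ID": [10, 11, 12, 10, 11, 12],
                "IA_SKIP": [0, 1, 0, 0, 0, 0],
                "IA_FIRST_FIXATION_DURATION": [200, 0, 180, 210, 250, 190],
                "IA_FIRST_RUN_DWELL_TIME": [250, 0, 180, 210, 260, 195],
                "IA_DWELL_TIME": [400, 0, 180, 500, 260, 195],
                "IA_REGRESSION_IN": [1, 0, 0, 0, 1, 0],
            }
        )

    def test_toy_table_loads_six_records(self, tmp_path):
        path = tmp_path / "gaze.csv"
        self._frame().to_csv(path, index=False)
        gaze = load_eye_movement_report(path)
        assert len(gaze) == 6
        assert gaze.loc[gaze["skipped"], ["first_fixation_ms", "gaze_ms", "total_ms"]].isna().all().all()
        assert gaze["regression_in"].sum() == 2

    def test_ordering_violation_dropped_and_counted(self, tmp_path):
        df = self._frame()
        df.loc[5, "IA_FIRST_RUN_DWELL_TIME"] = 100  # gaze < first fixation
        path = tmp_path / "gaze.csv"
        df.to_csv(path, index=False)
        gaze = load_eye_movement_report(path)
        assert len(gaze) == 5
        assert gaze.attrs["n_dropped_invalid"] == 1

    def test_unmapped_required_column_named(self, tmp_path):
        df = self._frame().drop(columns=["IA_SKIP"])
        path = tmp_path / "gaze.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="IA_SKIP"):
            load_eye_movement_report(path)


class TestClozeAndFrequency:
    def test_cloze_norms_load_and_preserve_zeros(self, tmp_path):
        path = tmp_path / "cloze.csv"
        pd.DataFrame({"word_id": [1, 2, 3, 4, 5],
                      "cloze_probability": [0.0, 0.5, 1.0, 0.0, 0.2]}).to_csv(path, index=False)
        norms = load_cloze_norms(path)
        assert len(norms) == 5
        assert (norms == 0.0).sum() == 2

    def test_cloze_value_above_one_rejected(self, tmp_path):
        path = tmp_path / "cloze.csv"
        pd.DataFrame({"word_id": [1], "cloze_probability": [1.2]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="1.2"):
            load_cloze_norms(path)

    def test_frequency_log10_and_case_insensitive(self, tmp_path):
        path = tmp_path / "freq.csv"
        pd.DataFrame({"word": ["The", "cat"], "per_million": [100.0, 1.0]}).to_csv(path, index=False)
        freq = load_frequency_table(path)
        assert freq["the"] == pytest.approx(2.0)
        assert freq["cat"] == pytest.approx(0.0)

    def test_non_positive_frequency_rejected(self, tmp_path):
        path = tmp_path / "freq.csv"
        pd.DataFrame({"word": ["x"], "per_million": [0.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="non-positive"):
            load_frequency_table(path)


class TestMerge:
    def _inputs(self):
        corpus = PassageCorpus.from_passages([["aa", "bb", "cc", "dd"]])
        wids = corpus.table["word_id"].tolist()
        gaze = pd.DataFrame(
            {
                "participant_id": [1] * 4 + [2] * 4,
                "word_id": wids * 2,
                "skipped": [False, True, False, False] * 2,
                "first_fixation_ms": [200, np.nan, 210, 190] * 2,
                "gaze_ms": [220, np.nan, 210, 200] * 2,
                "total_ms": [250, np.nan, 300, 200] * 2,
                "regression_in": [False, False, True, False] * 2,
            }
        )
        metrics = pd.DataFrame(
            {
                "word_id": wids[1:],
                "entropy_bits": [1.0, 2.0, 1.5],
                "surprisal_bits": [0.5, 3.0, 1.0],
                "target_probability": [2**-0.5, 2**-3.0, 0.5],
            }
        )
        freq = {"aa": 2.0, "bb": 1.5, "cc": 1.0, "dd": 0.5}
        return corpus, gaze, metrics, freq

    def test_initial_word_excluded_and_counts_conserved(self):
        corpus, gaze, metrics, freq = self._inputs()
        obs = merge_observations(corpus, gaze, metrics, frequency=freq)
        assert len(obs) == 6  # 2 participants x 3 non-initial words
        assert obs.attrs["n_skipped"] + obs.attrs["n_fixated"] == len(obs)
        assert set(obs["length_letters"]) == {2}

    def test_missing_frequency_drops_and_counts(self):
        corpus, gaze, metrics, freq = self._inputs()
        del freq["cc"]
        obs = merge_observations(corpus, gaze, metrics, frequency=freq)
        assert obs.attrs["n_dropped_frequency"] == 2
        assert len(obs) == 4

    def test_metric_missing_for_fixated_word_is_error(self):
        corpus, gaze, metrics, freq = self._inputs()
        fixated_word = corpus.table["word_id"].iloc[2]  # fixated by everyone
        lacking = metrics.loc[metrics["word_id"] != fixated_word]
        with pytest.raises(ValueError, match="metrics missing"):
            merge_observations(corpus, gaze, lacking, frequency=freq)

    def test_metric_missing_for_skipped_only_word_is_dropped(self):
        corpus, gaze, metrics, freq = self._inputs()
        skipped_word = corpus.table["word_id"].iloc[1]  # skipped by everyone
        lacking = metrics.loc[metrics["word_id"] != skipped_word]
        obs = merge_observations(corpus, gaze, lacking, frequency=freq)
        assert len(obs) == 4  # both participants' rows on that word dropped

    def test_cloze_join_is_optional_and_preserves_zeros(self):
        corpus, gaze, metrics, freq = self._inputs()
        cloze = pd.Series([0.0, 0.4, 0.0], index=metrics["word_id"].values)
        obs = merge_observations(corpus, gaze, metrics, cloze=cloze, frequency=freq)
        assert (obs["cloze_probability"] == 0.0).sum() == 4

    def test_unknown_word_id_rejected(self):
        corpus, gaze, metrics, freq = self._inputs()
        gaze.loc[0, "word_id"] = 999
        with pytest.raises(ValueError, match="unknown word_ids"):
            merge_observations(corpus, gaze, metrics, frequency=freq)

    def test_round_trip_write_read_identical(self, tmp_path):
        corpus, gaze, metrics, freq = self._inputs()
        obs = merge_observations(corpus, gaze, metrics, frequency=freq)
        path = tmp_path / "obs.csv"
        obs.to_csv(path, index=False)
        back = pd.read_csv(path)
        for col in ("entropy_bits", "surprisal_bits", "first_fixation_ms", "log_frequency"):
            np.testing.assert_array_equal(back[col].values, obs[col].values)
        assert back["skipped"].tolist() == obs["skipped"].tolist()
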