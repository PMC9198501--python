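"""Reading-corpus I/O: passages, eye-movement reports, cloze norms, frequencies.

The unit of analysis is the interest-area (word) report familiar from
eye-tracking corpora of passage reading: one row per participant × word
carrying a first-pass skip indicator, first fixation duration, gaze
duration, total reading time and a regression-in indicator.
``merge_observations`` joins those records with per-word predictability
metrics, cloze norms and frequency/length covariates into the one-row-per-
observation table the mixed models consume.

All tables are plain delimited text (comma or tab, autodetected or set via
``sep``); column names are config-driven with defaults matching the
Provo/EyeLink interest-area export dialect, and unknown extra columns are
ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._text import is_sentence_final, letter_count, normalize_word

__all__ = [
    "PassageCorpus",
    "load_passages",
    "load_eye_movement_report",
    "load_cloze_norms",
    "load_frequency_table",
    "merge_observations",
    "PROVO_GAZE_COLUMNS",
]

log = logging.getLogger(__name__)

CORPUS_COLUMNS = [
    "word_id",
    "text_id",
    "position",
    "surface",
    "word_number_in_sentence",
    "sentence_final",
]

#: Default column map for the Provo/EyeLink interest-area report dialect.
PROVO_GAZE_COLUMNS = {
    "participant_id": "Participant_ID",
    "word_id": "Word_Unique_ID",
    "skipped": "IA_SKIP",
    "first_fixation_ms": "IA_FIRST_FIXATION_DURATION",
    "gaze_ms": "IA_FIRST_RUN_DWELL_TIME",
    "total_ms": "IA_DWELL_TIME",
    "regression_in": "IA_REGRESSION_IN",
}

GAZE_COLUMNS = list(PROVO_GAZE_COLUMNS)
DURATION_COLUMNS = ["first_fixation_ms", "gaze_ms", "total_ms"]


@dataclass
class PassageCorpus:
    """Ordered passages of word tokens with stable word identifiers.

    ``table`` has one row per word token with columns ``word_id`` (unique),
    ``text_id``, ``position`` (0-based within passage), ``surface``,
    ``word_number_in_sentence`` (1-based, resetting after each
    sentence-final word) and ``sentence_final``.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in CORPUS_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"corpus table lacks columns: {missing}")
        if self.table["word_id"].duplicated().any():
            dupes = self.table.loc[self.table["word_id"].duplicated(), "word_id"]
            raise ValueError(f"duplicate word_ids: {sorted(set(dupes))[:5]}")
        if (self.table["surface"].astype(str).str.len() == 0).any():
            raise ValueError("corpus contains empty surface forms")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_passages(
        cls,
        passages: Iterable[Sequence[str]],
        *,
        text_ids: Sequence | None = None,
    ) -> "PassageCorpus":
        """Build a corpus from lists of surface words.

        Sentence boundaries are detected from terminal punctuation
        (., ! or ?, allowing closing quotes); the last word of a passage
        is always sentence-final.
        """
        rows = []
        wid = 0
        passages = list(passages)
        if text_ids is None:
            text_ids = list(range(1, len(passages) + 1))
        for tid, words in zip(text_ids, passages):
            words = list(words)
            if not words:
                raise ValueError(f"passage {tid!r} is empty")
            wn = 1
            for pos, surface in enumerate(words):
                final = is_sentence_final(surface) or pos == len(words) - 1
                rows.append((wid, tid, pos, surface, wn, final))
                wid += 1
                wn = 1 if final else wn + 1
        return cls(pd.DataFrame(rows, columns=CORPUS_COLUMNS))

    @property
    def n_tokens(self) -> int:
        return len(self.table)

    def n_types(self, *, normalize: bool = True) -> int:
        """Distinct word forms; by default case-insensitive and
        punctuation-stripped (the normalization is configurable because
        published token/type counts rarely state theirs)."""
        surfaces = self.table["surface"].astype(str)
        if normalize:
            surfaces = surfaces.map(normalize_word)
        return surfaces.nunique()

    def passages(self):
        """Iterate (text_id, per-passage table ordered by position)."""
        for tid, grp in self.table.groupby("text_id", sort=False):
            yield tid, grp.sort_values("position")

    def initial_word_ids(self) -> set:
        """word_ids of passage-initial words (no preceding context, hence
        no predictability metrics)."""
        return set(
            self.table.loc[self.table["position"] == 0, "word_id"].tolist()
        )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _read_table(path, sep=None) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")


def _apply_map(df: pd.DataFrame, column_map: Mapping[str, str], required) -> pd.DataFrame:
    missing = [k for k in required if column_map.get(k, k) not in df.columns]
    if missing:
        raise ValueError(
            f"input table lacks required columns: "
            f"{[column_map.get(k, k) for k in missing]} (for {missing})"
        )
    out = pd.DataFrame()
    for canonical in column_map:
        src = column_map[canonical]
        if src in df.columns:
            out[canonical] = df[src]
    return out


def load_passages(path, column_map: Mapping[str, str] | None = None, *, sep=None) -> PassageCorpus:
    """Read a delimited word-list table into a :class:`PassageCorpus`.

    Needs word_id, text_id and word columns (default names ``word_id``,
    ``text_id``, ``word``); ``word_number_in_sentence`` is recomputed from
    sentence-final punctuation unless supplied.
    """
    cmap = {"word_id": "word_id", "text_id": "text_id", "surface": "word"}
    cmap.update(column_map or {})
    df = _read_table(path, sep)
    out = _apply_map(df, cmap, required=["word_id", "text_id", "surface"])
    rows = []
    for tid, grp in out.groupby("text_id", sort=False):
        words = grp["surface"].astype(str).tolist()
        ids = grp["word_id"].tolist()
        if not words:
            raise ValueError(f"passage {tid!r} is empty")
        wn = 1
        for pos, (wid, surface) in enumerate(zip(ids, words)):
            final = is_sentence_final(surface) or pos == len(words) - 1
            rows.append((wid, tid, pos, surface, wn, final))
            wn = 1 if final else wn + 1
    return PassageCorpus(pd.DataFrame(rows, columns=CORPUS_COLUMNS))


def load_eye_movement_report(
    path,
    column_map: Mapping[str, str] | None = None,
    *,
    sep=None,
) -> pd.DataFrame:
    """Read and validate a word-level eye-movement report.

    Returns one row per participant × word with canonical columns
    ``participant_id, word_id, skipped, first_fixation_ms, gaze_ms,
    total_ms, regression_in``. Non-positive durations are treated as absent;
    durations reported for skipped words are nulled (counted); rows whose
    present durations violate the ordering FFD ≤ gaze ≤ total are dropped
    with a logged count (kept in ``.attrs['n_dropped_invalid']``).
    """
    cmap = dict(PROVO_GAZE_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = _read_table(path, sep)
    out = _apply_map(df, cmap, required=list(PROVO_GAZE_COLUMNS))
    out["skipped"] = out["skipped"].astype(float).astype(bool)
    out["regression_in"] = out["regression_in"].fillna(0).astype(float).astype(bool)
    for c in DURATION_COLUMNS:
        out[c] = pd.to_numeric(out[c], errors="coerce")
        out.loc[out[c] <= 0, c] = np.nan

    nulled = int((out["skipped"] & out[DURATION_COLUMNS].notna().any(axis=1)).sum())
    if nulled:
        log.info("nulled durations on %d skipped rows", nulled)
        out.loc[out["skipped"], DURATION_COLUMNS] = np.nan

    ffd, gaze, total = (out[c] for c in DURATION_COLUMNS)
    bad = ((gaze < ffd) | (total < gaze) | (total < ffd)).fillna(False)
    # A fixated row without a first fixation duration is malformed too.
    bad |= ~out["skipped"] & ffd.isna()
    if bad.any():
        log.warning("dropping %d rows violating duration ordering", int(bad.sum()))
    out = out.loc[~bad].reset_index(drop=True)
    if out.duplicated(["participant_id", "word_id"]).any():
        raise ValueError("duplicate (participant_id, word_id) pairs in report")
    out.attrs["n_dropped_invalid"] = int(bad.sum())
    out.attrs["n_nulled_skipped_durations"] = nulled
    return out


def load_cloze_norms(path, column_map: Mapping[str, str] | None = None, *, sep=None) -> pd.Series:
    """Read word-by-word cloze norms: word_id → fraction of respondents
    producing the target. Exact zeros are preserved (they carry the cloze
    floor effect); values outside [0, 1] are an error."""
    cmap = {"word_id": "word_id", "cloze_probability": "cloze_probability"}
    cmap.update(column_map or {})
    df = _read_table(path, sep)
    out = _apply_map(df, cmap, required=["word_id", "cloze_probability"])
    vals = pd.to_numeric(out["cloze_probability"], errors="raise")
    bad = vals.dropna()
    if ((bad < 0) | (bad > 1)).any():
        offending = bad[(bad < 0) | (bad > 1)].iloc[0]
        raise ValueError(f"cloze probability {offending} outside [0, 1]")
    series = pd.Series(vals.values, index=out["word_id"].values, name="cloze_probability")
    n_missing = int(series.isna().sum())
    if n_missing:
        log.info("cloze norms missing for %d words", n_missing)
    return series


def load_frequency_table(path, column_map: Mapping[str, str] | None = None, *, sep=None) -> dict[str, float]:
    """Read a SUBTLEX-style frequency table into word → log10 per-million.

    Lookup is case-insensitive (keys are normalized forms); non-positive
    frequencies are an error.
    """
    cmap = {"word": "word", "per_million": "per_million"}
    cmap.update(column_map or {})
    df = _read_table(path, sep)
    out = _apply_map(df, cmap, required=["word", "per_million"])
    freqs = pd.to_numeric(out["per_million"], errors="raise")
    if (freqs <= 0).any():
        w = out.loc[freqs <= 0, "word"].iloc[0]
        raise ValueError(f"non-positive frequency for word {w!r}")
    return {
        normalize_word(str(w)): float(np.log10(f))
        for w, f in zip(out["word"], freqs)
    }


def merge_observations(
    corpus: PassageCorpus,
    gaze: pd.DataFrame,
    metrics: pd.DataFrame,
    cloze: pd.Series | None = None,
    frequency: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Assemble the one-row-per-participant × word analysis table.

    Passage-initial words have no metrics (the moving window starts at the
    second word) and their observations are excluded; a *fixated* word that
    is non-initial but lacks metrics is an error. Words absent from the
    frequency table are dropped from the result with a logged count
    (``.attrs['n_dropped_frequency']``) rather than imputed. Row
    conservation: output rows = gaze rows whose word has metrics (minus
    frequency drops), and the skipped/fixated partition is preserved.
    """
    words = corpus.table.set_index("word_id")
    unknown = set(gaze["word_id"]) - set(words.index)
    if unknown:
        raise ValueError(f"gaze rows reference unknown word_ids: {sorted(unknown)[:5]}")

    metrics = metrics.set_index("word_id") if "word_id" in metrics.columns else metrics
    initial = corpus.initial_word_ids()
    modelled = gaze.loc[~gaze["word_id"].isin(initial)].copy()
    lacking = set(modelled["word_id"]) - set(metrics.index)
    fixated_lacking = set(
        modelled.loc[~modelled["skipped"] & modelled["word_id"].isin(lacking), "word_id"]
    )
    if fixated_lacking:
        raise ValueError(
            f"metrics missing for fixated words: {sorted(fixated_lacking)[:10]}"
        )
    if lacking:
        log.info("dropping %d observations on metric-less (skipped-only) words", len(lacking))
        modelled = modelled.loc[~modelled["word_id"].isin(lacking)]

    out = modelled.merge(
        metrics[["entropy_bits", "surprisal_bits", "target_probability"]
                + (["top_prediction_similarity"] if "top_prediction_similarity" in metrics else [])],
        left_on="word_id",
        right_index=True,
        how="left",
    )
    out = out.merge(
        words[["text_id", "surface", "word_number_in_sentence"]],
        left_on="word_id",
        right_index=True,
        how="left",
    )
    out["length_letters"] = out["surface"].astype(str).map(letter_count)
    if cloze is not None:
        out["cloze_probability"] = out["word_id"].map(cloze)

    n_dropped_freq = 0
    if frequency is not None:
        out["log_frequency"] = out["surface"].astype(str).map(
            lambda s: frequency.get(normalize_word(s), np.nan)
        )
        missing = out["log_frequency"].isna()
        n_dropped_freq = int(missing.sum())
        if n_dropped_freq:
            log.info("dropping %d observations with no frequency entry", n_dropped_freq)
            out = out.loc[~missing]

    if out.duplicated(["participant_id", "word_id"]).any():
        raise ValueError("merge produced duplicate (participant_id, word_id) rows")
    out = out.reset_index(drop=True)
    out.attrs["n_dropped_frequency"] = n_dropped_freq
    out.attrs["n_skipped"] = int(out["skipped"].sum())
    out.attrs["n_fixated"] = int((~out["skipped"]).sum())
    return out
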