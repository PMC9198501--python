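"""Prediction-error-cost subset analysis.

When a context licenses a strong prediction (low entropy) that turns out
wrong (high surprisal), fixation durations show a prediction error cost;
whether that cost is softened when the wrong prediction is semantically
close to the target is tested on exactly that subset. Entropy and
surprisal are discretized word-by-word with equal-frequency (quantile)
binning, the lowest-entropy × highest-surprisal cell is selected, and the
duration/regression models are refitted there with target-prediction
similarity replacing the entropy and surprisal terms.

Binning is computed on the word-level metric values and broadcast to
observations, so on a complete design the subset factorizes as
participants × selected tokens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixedmodels import FitResult, fit_mixed_many, similarity_model

__all__ = [
    "BinAssignment",
    "equal_frequency_bins",
    "select_prediction_error_subset",
    "select_quadrant",
    "similarity_effect_fit",
]

SIMILARITY_OUTCOMES = ("first_fixation", "gaze", "total_time", "regression")


@dataclass
class BinAssignment:
    """Equal-frequency discretization of one variable.

    ``labels`` are ordered bin indices 0 (low) .. n_bins-1 (high), one per
    input value; ``boundaries`` are the interior quantiles. A value equal
    to a boundary goes to the higher bin (stable, documented tie policy),
    so heavy ties can make counts unequal.
    """

    variable: str
    n_bins: int
    labels: np.ndarray
    boundaries: np.ndarray

    def counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_bins)


def equal_frequency_bins(values, n_bins: int, *, variable: str = "value") -> BinAssignment:
    """Quantile-based cut into ``n_bins`` equally populated categories.

    Deterministic and permutation-invariant: assignments depend only on
    each value and the empirical quantiles, not on input order. Constant
    input or n_bins < 2 is an error.
    """
    x = np.asarray(values, dtype=float)
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if x.size < n_bins:
        raise ValueError(f"cannot cut {x.size} values into {n_bins} bins")
    if np.any(~np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0:
        raise ValueError("values are constant; equal-frequency bins undefined")
    qs = np.quantile(x, np.arange(1, n_bins) / n_bins)
    # side="right": a value equal to a boundary joins the higher bin.
    labels = np.searchsorted(qs, x, side="right")
    return BinAssignment(variable, n_bins, labels.astype(int), qs)


def select_quadrant(
    table: pd.DataFrame,
    word_metrics: pd.DataFrame,
    *,
    entropy_bin: int,
    surprisal_bin: int,
    n_bins: int = 3,
) -> pd.DataFrame:
    """Observations whose word falls in a given entropy × surprisal cell.

    Bins are computed on the word-level metric values in ``word_metrics``
    (columns word_id, entropy_bits, surprisal_bits) and broadcast to the
    observation table by word_id.
    """
    wm = word_metrics.drop_duplicates("word_id")
    h_bins = equal_frequency_bins(wm["entropy_bits"], n_bins, variable="entropy_bits")
    s_bins = equal_frequency_bins(wm["surprisal_bits"], n_bins, variable="surprisal_bits")
    chosen = wm.loc[
        (h_bins.labels == entropy_bin) & (s_bins.labels == surprisal_bin), "word_id"
    ]
    subset = table.loc[table["word_id"].isin(set(chosen))].copy()
    subset.attrs["n_selected_tokens"] = int(chosen.nunique())
    subset.attrs["n_participants"] = int(subset["participant_id"].nunique()) if not subset.empty else 0
    return subset


def select_prediction_error_subset(
    table: pd.DataFrame,
    word_metrics: pd.DataFrame,
    *,
    n_bins: int = 3,
) -> pd.DataFrame:
    """The low-entropy / high-surprisal cell: strong predictions that
    were wrong. Default tertile binning (n_bins configurable 2-5).

    Raises if the cell is empty.
    """
    if not 2 <= n_bins <= 5:
        raise ValueError("n_bins must be between 2 and 5")
    subset = select_quadrant(
        table,
        word_metrics,
        entropy_bin=0,
        surprisal_bin=n_bins - 1,
        n_bins=n_bins,
    )
    if subset.empty:
        raise ValueError("low-entropy/high-surprisal subset is empty")
    return subset


def similarity_effect_fit(
    subset: pd.DataFrame,
    *,
    outcomes=SIMILARITY_OUTCOMES,
    nagq: int = 1,
) -> dict[str, FitResult]:
    """Fit outcome ~ similarity + covariates (+ crossed intercepts) on the
    prediction-error subset, one fit per outcome, batched in one R session."""
    if "top_prediction_similarity" not in subset.columns:
        raise ValueError("subset lacks top_prediction_similarity")
    if subset["top_prediction_similarity"].isna().any():
        bad = subset.loc[subset["top_prediction_similarity"].isna(), "word_id"].unique()
        raise ValueError(f"similarity missing for words: {sorted(bad)[:10]}")
    requests = [(o, similarity_model(o), subset) for o in outcomes]
    return fit_mixed_many(requests, nagq=nagq)
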