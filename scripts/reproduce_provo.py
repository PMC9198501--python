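#!/usr/bin/env python
"""Recompute the real-data analyses from locally downloaded corpus files.

Works from the public Provo Corpus releases (https://osf.io/sjefs/) and a
SUBTLEX-style frequency table. Everything that needs only the corpus files
is deterministic: token/type totals, observation totals, the skipped /
fixated split, the zero-cloze fraction, and (given respondent-level cloze
responses) human next-word accuracy statistics. With the optional
transformer backend installed (``pip install 'gazelm[transformer]'``,
downloads the released 117M-parameter GPT-2 weights) the script also
recomputes the predictability metrics, the model top-k accuracy curve, the
five crossed random-intercept mixed models, and the low-entropy /
high-surprisal similarity analysis.

Tolerance notes: corpus-level counts should reproduce exactly once the
column mapping and word normalization match the release in hand (both are
configurable; token/type totals are sensitive to case and punctuation
handling). Model-derived quantities (top-k accuracies, effect sizes)
additionally depend on subword tokenization, the word-decoding convention
for top predictions, and the embedding layer used for similarity — expect
slack of a few percentage points on accuracies and agreement in sign and
approximate magnitude, rather than digit-for-digit equality, for the
mixed-model effects.

Usage:
    python scripts/reproduce_provo.py \
        --passages passages.csv --eyetracking provo_ia.csv \
        --cloze cloze_norms.csv --subtlex subtlex.csv \
        [--cloze-responses responses.csv] [--backend gpt2] [--out report.json]

This script never downloads anything itself; point it at local files.
"""

from __future__ import annotations

import argparse
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import pandas as pd  # noqa: E402

from gazelm import (  # noqa: E402
    duration_model,
    fit_mixed_many,
    human_accuracy_stats,
    incremental_metrics,
    load_cloze_norms,
    load_eye_movement_report,
    load_frequency_table,
    load_passages,
    merge_observations,
    model_accuracy_curve,
    regression_model,
    select_prediction_error_subset,
    similarity_effect_fit,
    skip_model,
    zero_probability_fraction,
)
from gazelm.pipeline import fit_result_summary, states_to_frame  # noqa: E402


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--passages", required=True, type=Path)
    parser.add_argument("--eyetracking", required=True, type=Path)
    parser.add_argument("--cloze", required=True, type=Path)
    parser.add_argument("--subtlex", type=Path)
    parser.add_argument("--cloze-responses", type=Path,
                        help="respondent-level cloze table (respondent_id, guess, target)")
    parser.add_argument("--backend", default=None,
                        help="transformer model name (e.g. gpt2); omit for counts only")
    parser.add_argument("--n-bins", type=int, default=3)
    parser.add_argument("--out", type=Path, default=Path("provo_report.json"))
    args = parser.parse_args()

    report: dict = {}

    corpus = load_passages(args.passages)
    report["corpus"] = {
        "n_tokens": corpus.n_tokens,
        "n_types_normalized": corpus.n_types(),
        "n_types_raw": corpus.n_types(normalize=False),
        "n_passages": int(corpus.table["text_id"].nunique()),
    }

    gaze = load_eye_movement_report(args.eyetracking)
    report["eye_movements"] = {
        "n_observations": len(gaze),
        "n_skipped": int(gaze["skipped"].sum()),
        "n_fixated": int((~gaze["skipped"]).sum()),
        "n_dropped_invalid": gaze.attrs["n_dropped_invalid"],
    }

    norms = load_cloze_norms(args.cloze)
    report["cloze"] = {
        "n_words": int(norms.notna().sum()),
        "zero_cloze_fraction": zero_probability_fraction(norms),
    }

    if args.cloze_responses:
        responses = pd.read_csv(args.cloze_responses)
        summary = human_accuracy_stats(responses)
        report["human_accuracy"] = {
            "mean": summary.mean, "sd": summary.sd, "max": summary.maximum,
            "n_respondents": int(len(summary.per_respondent)),
        }

    if args.backend:
        from gazelm.hf_backend import TransformerLM

        lm = TransformerLM(args.backend)
        states, targets, pids, word_ids = [], [], [], []
        for tid, passage in corpus.passages():
            words = passage["surface"].tolist()
            ws = incremental_metrics(lm, words, passage["word_id"].tolist()[1:])
            states += ws
            targets += words[1:]
            pids += [tid] * len(ws)
        curve = model_accuracy_curve(states, targets, pids)
        report["model_accuracy_topk"] = {
            str(k): {"accuracy": a, "sem": s} for k, (a, s) in curve.model_topk.items()
        }

        metrics = states_to_frame(states)
        freq = load_frequency_table(args.subtlex) if args.subtlex else None
        obs = merge_observations(corpus, gaze, metrics, cloze=norms, frequency=freq)
        fixated = obs.loc[~obs["skipped"]]
        fits = fit_mixed_many(
            [
                ("skip", skip_model(), obs),
                ("first_fixation", duration_model("first_fixation"), fixated),
                ("gaze", duration_model("gaze"), fixated),
                ("total_time", duration_model("total_time"), fixated),
                ("regression", regression_model(), obs),
            ]
        )
        report["mixed_models"] = {k: fit_result_summary(v) for k, v in fits.items()}

        subset = select_prediction_error_subset(obs, metrics, n_bins=args.n_bins)
        report["prederror_subset"] = {
            "n_observations": len(subset),
            "n_tokens": subset.attrs["n_selected_tokens"],
            "n_participants": subset.attrs["n_participants"],
        }
        sim_fits = similarity_effect_fit(subset)
        report["similarity_models"] = {
            k: fit_result_summary(v) for k, v in sim_fits.items()
        }

    args.out.write_text(json.dumps(report, indent=2))
    print(json.dumps(report, indent=2))
    return 0


if __name__ == "__main__":
    sys.exit(main())
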