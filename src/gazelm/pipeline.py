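"""End-to-end orchestration of the synthetic study.

Runs the stages in dependency order — toy LM → passages → predictability
metrics → cloze norms → gaze simulation → observation merge → cloze
validation → mixed models → prediction-error subset — writing every table
as delimited text plus a JSON run manifest with stage row counts, output
hashes, seeds and software versions. Re-running with the same config
reproduces identical outputs.

Configs load from YAML/JSON; the same entry points drive a real-data run
when the user swaps the simulated inputs for loaded ones (see
scripts/reproduce_provo.py for that route).
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cloze import human_accuracy_stats, model_accuracy_curve, zero_probability_fraction
from .corpus import merge_observations
from .mixedmodels import (
    FitResult,
    choose_transform,
    duration_model,
    fit_mixed_many,
    regression_model,
    skip_model,
    type3_wald,
    vif,
)
from .predictability import incremental_metrics
from .prederror import select_prediction_error_subset, similarity_effect_fit
from .synthetic import (
    GazeSimConfig,
    pseudo_vocabulary,
    sample_cloze_responses,
    sample_passages,
    simulate_cloze,
    simulate_gaze,
    toy_frequency_table,
)
from .toylm import random_lm

__all__ = ["PipelineConfig", "run_pipeline", "states_to_frame", "fit_result_summary"]

log = logging.getLogger(__name__)

STAGES = (
    "passages",
    "metrics",
    "cloze",
    "gaze",
    "merge",
    "validation",
    "models",
    "prederror",
)


@dataclass
class PipelineConfig:
    """Everything a synthetic end-to-end run needs.

    The defaults give a smoke-test-sized study (completes in well under a
    minute); scale n_participants / n_passages / passage_length up for
    simulation studies.
    """

    seed: int = 0
    outdir: str = "gazelm_run"
    vocab_size: int = 40
    lm_concentration: float = 0.1
    n_passages: int = 3
    passage_length: int = 60
    n_participants: int = 10
    n_cloze_respondents: int = 40
    k_max: int = 10
    n_bins: int = 3
    nagq: int = 1
    compute_similarity: bool = True
    gaze: GazeSimConfig | None = None
    stages: tuple[str, ...] = STAGES

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gaze_raw = raw.pop("gaze", None)
        cfg = cls(**raw)
        if gaze_raw:
            cfg.gaze = GazeSimConfig(**gaze_raw)
        return cfg

    def subseed(self, k: int) -> int:
        # Deterministic per-stage sub-seeds kept below 2**31.
        return (self.seed * 1000003 + k) % (2**31 - 1)


def states_to_frame(states) -> pd.DataFrame:
    """Flatten PredictionStates to the delimited metrics table: word_id,
    probability, entropy and surprisal in bits, top candidates, similarity."""
    rows = []
    for s in states:
        row = {
            "word_id": s.word_id,
            "target_probability": s.target_probability,
            "entropy_bits": s.entropy_bits,
            "surprisal_bits": s.surprisal_bits,
            "top_prediction_similarity": s.top_prediction_similarity,
        }
        for i, (w, p) in enumerate(s.top_candidates, start=1):
            row[f"top{i}_word"] = w
            row[f"top{i}_prob"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def fit_result_summary(fit: FitResult) -> dict:
    """JSON-ready summary of one mixed-model fit."""
    return {
        "outcome": fit.outcome,
        "family": fit.family,
        "formula": fit.formula,
        "n": fit.n,
        "converged": fit.converged,
        "singular": fit.singular,
        "loglik": fit.loglik,
        "re_sd": fit.re_sd,
        "sigma": fit.sigma,
        "terms": fit.terms.to_dict(orient="records"),
        "type3": type3_wald(fit).to_dict(orient="records") if fit.converged else None,
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    """A stage failed; carries a machine-readable record."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.record = {"stage": stage, "error": str(cause), "type": type(cause).__name__}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest.

    Stage failure halts the run with a :class:`StageError` naming the stage.
    Later stages require earlier ones in the same run; the ``stages`` tuple
    can only truncate the tail of the sequence.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = [s for s in STAGES if s in config.stages]
    manifest: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items() if k != "gaze"},
        "stages": {},
        "outputs": {},
    }

    lm = random_lm(
        pseudo_vocabulary(config.vocab_size),
        config.subseed(1),
        concentration=config.lm_concentration,
    )
    freq_pm = toy_frequency_table(lm.vocabulary)
    log_freq = {w: float(np.log10(f)) for w, f in freq_pm.items()}

    state: dict = {}

    def record(stage: str, files: dict[str, Path], counts: dict[str, int]) -> None:
        manifest["stages"][stage] = counts
        for label, path in files.items():
            manifest["outputs"][label] = {"path": str(path), "sha256": _sha256(path)}
        log.info("stage %s: %s", stage, counts)

    for stage in enabled:
        try:
            if stage == "passages":
                corpus = sample_passages(
                    lm, config.n_passages, config.passage_length, config.subseed(2)
                )
                path = outdir / "passages.csv"
                corpus.to_csv(path)
                state["corpus"] = corpus
                record(stage, {"passages": path}, {"n_tokens": corpus.n_tokens,
                                                   "n_types": corpus.n_types()})
            elif stage == "metrics":
                corpus = state["corpus"]
                states, passage_of = [], []
                for tid, passage in corpus.passages():
                    ws = incremental_metrics(
                        lm,
                        passage["surface"].tolist(),
                        passage["word_id"].tolist()[1:],
                        k_max=config.k_max,
                        compute_similarity=config.compute_similarity,
                    )
                    states.extend(ws)
                    passage_of.extend([tid] * len(ws))
                metrics = states_to_frame(states)
                path = outdir / "metrics.csv"
                metrics.to_csv(path, index=False)
                state.update(states=states, metrics=metrics, passage_of=passage_of)
                record(stage, {"metrics": path}, {"n_states": len(states)})
            elif stage == "cloze":
                corpus = state["corpus"]
                responses = sample_cloze_responses(
                    lm, corpus, config.n_cloze_respondents, config.subseed(3)
                )
                norms = simulate_cloze(
                    lm, corpus, config.n_cloze_respondents, config.subseed(3)
                )
                path = outdir / "cloze_norms.csv"
                norms.rename_axis("word_id").reset_index().to_csv(path, index=False)
                state.update(responses=responses, norms=norms)
                record(stage, {"cloze_norms": path}, {"n_words": len(norms),
                                                      "n_responses": len(responses)})
            elif stage == "gaze":
                sim = config.gaze or GazeSimConfig(
                    n_participants=config.n_participants, seed=config.subseed(4)
                )
                gaze = simulate_gaze(state["corpus"], state["metrics"], sim, log_freq)
                path = outdir / "gaze.csv"
                gaze.to_csv(path, index=False)
                state["gaze"] = gaze
                record(stage, {"gaze": path}, {
                    "n_observations": len(gaze),
                    "n_skipped": int(gaze["skipped"].sum()),
                    "n_fixated": int((~gaze["skipped"]).sum()),
                })
            elif stage == "merge":
                obs = merge_observations(
                    state["corpus"], state["gaze"], state["metrics"],
                    cloze=state.get("norms"), frequency=log_freq,
                )
                path = outdir / "observations.csv"
                obs.to_csv(path, index=False)
                state["obs"] = obs
                counts = {
                    "n_rows": len(obs),
                    "n_skipped": obs.attrs["n_skipped"],
                    "n_fixated": obs.attrs["n_fixated"],
                }
                assert counts["n_skipped"] + counts["n_fixated"] == counts["n_rows"]
                record(stage, {"observations": path}, counts)
            elif stage == "validation":
                human = human_accuracy_stats(state["responses"])
                curve = model_accuracy_curve(
                    state["states"],
                    [state["corpus"].table.set_index("word_id").loc[s.word_id, "surface"]
                     for s in state["states"]],
                    state["passage_of"],
                    k_max=config.k_max,
                )
                summary = {
                    "zero_cloze_fraction": zero_probability_fraction(state["norms"]),
                    "human_accuracy": {"mean": human.mean, "sd": human.sd,
                                       "max": human.maximum},
                    "model_topk": {str(k): {"accuracy": a, "sem": s}
                                   for k, (a, s) in curve.model_topk.items()},
                }
                path = outdir / "validation.json"
                path.write_text(json.dumps(summary, indent=2))
                state["validation"] = summary
                record(stage, {"validation": path},
                       {"n_respondents": int(state["responses"]["respondent_id"].nunique())})
            elif stage == "models":
                obs = state["obs"]
                fixated = obs.loc[~obs["skipped"]]
                bc = choose_transform(fixated["gaze_ms"])
                # Collinearity screen on the main-effect design (raw-scale
                # interaction products are collinear with their mains by
                # construction and are not part of the screen).
                vifs = vif(obs, skip_model().variables())
                fits = fit_mixed_many(
                    [
                        ("skip", skip_model(), obs),
                        ("first_fixation", duration_model("first_fixation"), fixated),
                        ("gaze", duration_model("gaze"), fixated),
                        ("total_time", duration_model("total_time"), fixated),
                        ("regression", regression_model(), obs),
                    ],
                    nagq=config.nagq,
                )
                payload = {
                    "boxcox_lambda": bc.lambda_,
                    "duration_transform": bc.transform,
                    "max_vif": float(vifs.max()),
                    "fits": {k: fit_result_summary(v) for k, v in fits.items()},
                }
                path = outdir / "models.json"
                path.write_text(json.dumps(payload, indent=2))
                state.update(fits=fits, models_summary=payload)
                record(stage, {"models": path},
                       {name: fit.n for name, fit in fits.items()})
            elif stage == "prederror":
                obs = state["obs"]
                subset = select_prediction_error_subset(
                    obs, state["metrics"], n_bins=config.n_bins
                )
                path = outdir / "prederror_subset.csv"
                subset.to_csv(path, index=False)
                sim_fits = similarity_effect_fit(subset, nagq=config.nagq)
                fits_path = outdir / "prederror_fits.json"
                fits_path.write_text(json.dumps(
                    {k: fit_result_summary(v) for k, v in sim_fits.items()}, indent=2
                ))
                state.update(subset=subset, similarity_fits=sim_fits)
                record(stage, {"prederror_subset": path, "prederror_fits": fits_path}, {
                    "n_rows": len(subset),
                    "n_tokens": subset.attrs["n_selected_tokens"],
                    "n_participants": subset.attrs["n_participants"],
                })
        except Exception as exc:  # halt with the stage name, machine-readable
            if isinstance(exc, StageError):
                raise
            err = StageError(stage, exc)
            (outdir / "error.json").write_text(json.dumps(err.record, indent=2))
            raise err from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    state["manifest"] = manifest
    state["manifest_path"] = manifest_path
    return state
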