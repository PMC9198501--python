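"""Subprocess bridge to lme4 (lmer/glmer) through Rscript.

Crossed random-intercept mixed models — Gaussian by maximum likelihood,
binomial by Laplace approximation — are fitted by lme4, the standard tool
for these models. Jobs are batched: one R session fits any number of
models, which matters when simulation studies fit dozens.

Each job ships a data frame to CSV, a model formula in lme4 syntax and a
family; results come back as JSON with fixed effects, the coefficient
covariance matrix, random-effect standard deviations, convergence
diagnostics and a car::Anova type-III Wald table (used as an independent
cross-check of the type-III statistics computed in Python).
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Lme4Job", "Lme4Error", "run_lme4_jobs", "rscript_available"]


class Lme4Error(RuntimeError):
    """Raised when the R bridge itself fails (not a model-fit warning)."""


@dataclass
class Lme4Job:
    """One mixed-model fit request."""

    name: str
    data: pd.DataFrame
    formula: str
    family: str = "gaussian"  # "gaussian" (ML) or "binomial" (Laplace/AGQ)
    nagq: int = 1

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.data.empty:
            raise ValueError(f"job {self.name!r} has no data")


def rscript_available() -> bool:
    return shutil.which("Rscript") is not None


def _runner_path() -> Path:
    with resources.as_file(resources.files("gazelm") / "r" / "fit_mixed.R") as p:
        return Path(p)


def run_lme4_jobs(jobs: list[Lme4Job], *, timeout: float = 3600.0) -> list[dict]:
    """Fit all jobs in one R session; returns one result dict per job.

    A result has ``ok=True`` with keys ``terms, beta, vcov, re_sd, sigma,
    n, loglik, singular, messages, anova_type3`` — or ``ok=False`` with an
    ``error`` message. Raises :class:`Lme4Error` if Rscript is missing or
    the session itself fails.
    """
    if not jobs:
        return []
    if not rscript_available():
        raise Lme4Error(
            "Rscript not found on PATH; the mixed-model stage needs R with lme4"
        )
    with tempfile.TemporaryDirectory(prefix="gazelm_lme4_") as tmp:
        tmpdir = Path(tmp)
        specs = []
        for i, job in enumerate(jobs):
            csv_path = tmpdir / f"job{i}.csv"
            job.data.to_csv(csv_path, index=False)
            specs.append(
                {
                    "name": job.name,
                    "data": str(csv_path),
                    "formula": job.formula,
                    "family": job.family,
                    "nagq": job.nagq,
                }
            )
        jobs_path = tmpdir / "jobs.json"
        out_path = tmpdir / "results.json"
        jobs_path.write_text(json.dumps(specs))
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(_runner_path()), str(jobs_path), str(out_path)],
            capture_output=True,
            text=True,
            timeout=timeout,
        )
        if proc.returncode != 0 or not out_path.exists():
            raise Lme4Error(
                f"R bridge failed (exit {proc.returncode}):\n{proc.stderr[-2000:]}"
            )
        results = json.loads(out_path.read_text())
    for res in results:
        if res.get("ok") and res.get("vcov") is not None:
            res["vcov"] = np.asarray(res["vcov"], dtype=float)
            res["beta"] = np.asarray(res["beta"], dtype=float)
    return results
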