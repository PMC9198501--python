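"""Crossed random-effects models of word-by-word gaze behaviour.

Four analyses share one structure: an outcome per participant × word
(skip yes/no, log first fixation duration, log gaze duration, log total
reading time, regression-in yes/no), fixed effects for entropy, surprisal
and their interaction plus log frequency, word length in letters and
word number in sentence, and crossed random intercepts for participant,
word item and text passage::

    outcome ~ entropy * surprisal + freq + length + word_number
              + (1|participant) + (1|word) + (1|text)

Binary outcomes use a logistic link (coefficients reported as odds ratios
per bit); duration outcomes are modelled on the natural-log scale, as
indicated by a Box-Cox check, and back-transformed by exponentiation for
presentation. Estimation is maximum likelihood (not REML) so fixed-effect
comparisons are coherent across models; fitting is delegated to lme4
(:mod:`gazelm.lme4`). Significance of each fixed factor comes from
type-III Wald chi-square tests computed here from the coefficient vector
and its covariance; collinearity is screened with variance inflation
factors (a maximum under 2 is taken as unproblematic).

Predictors enter unscaled: entropy and surprisal in bits, frequency as
log10 per million, so coefficient magnitudes are per-bit / per-decade.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import boxcox_normmax

from .lme4 import Lme4Job, run_lme4_jobs

__all__ = [
    "ModelSpec",
    "FitResult",
    "TransformDecision",
    "skip_model",
    "duration_model",
    "regression_model",
    "similarity_model",
    "choose_transform",
    "fit_mixed",
    "fit_mixed_many",
    "type3_wald",
    "vif",
]

log = logging.getLogger(__name__)

OUTCOMES = {
    # outcome name -> (source column, family)
    "skip": ("skipped", "binomial"),
    "first_fixation": ("first_fixation_ms", "gaussian"),
    "gaze": ("gaze_ms", "gaussian"),
    "total_time": ("total_ms", "gaussian"),
    "regression": ("regression_in", "binomial"),
}

DEFAULT_GROUPS = ("participant_id", "word_id", "text_id")

#: The shared covariate block of every analysis.
COVARIATES = ["log_frequency", "length_letters", "word_number_in_sentence"]


@dataclass
class ModelSpec:
    """One mixed-model analysis: outcome, fixed terms, grouping factors.

    Fixed terms use lme4/R syntax; ``a*b`` expands to both main effects and
    their interaction. Interactions are only allowed between declared main
    effects (``a:b`` requires ``a`` and ``b`` to appear, possibly via
    ``a*b``).
    """

    outcome: str
    fixed: list[str] = field(
        default_factory=lambda: ["entropy_bits*surprisal_bits"] + COVARIATES
    )
    groups: tuple[str, ...] = DEFAULT_GROUPS

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(
                f"unknown outcome {self.outcome!r}; expected one of {sorted(OUTCOMES)}"
            )
        mains = set()
        for term in self.fixed:
            mains.update(v for v in re.split(r"[*:]", term) if "*" in term or ":" not in term)
        for term in self.fixed:
            if ":" in term and "*" not in term:
                for v in term.split(":"):
                    if v not in mains:
                        raise ValueError(
                            f"interaction {term!r} involves {v!r}, which is not a main effect"
                        )

    @property
    def family(self) -> str:
        return OUTCOMES[self.outcome][1]

    @property
    def source_column(self) -> str:
        return OUTCOMES[self.outcome][0]

    def variables(self) -> list[str]:
        """Data columns the fixed terms reference."""
        seen: list[str] = []
        for term in self.fixed:
            for v in re.split(r"[*:]", term):
                if v not in seen:
                    seen.append(v)
        return seen

    def formula(self, response: str = "y") -> str:
        fixed = " + ".join(self.fixed)
        random = " + ".join(f"(1|{g})" for g in self.groups)
        return f"{response} ~ {fixed} + {random}"


def skip_model() -> ModelSpec:
    """Skipping ~ entropy × surprisal + covariates; all observations."""
    return ModelSpec("skip")


def duration_model(outcome: str) -> ModelSpec:
    """log-duration ~ surprisal × entropy + covariates; fixated rows only."""
    if outcome not in ("first_fixation", "gaze", "total_time"):
        raise ValueError(f"{outcome!r} is not a duration outcome")
    return ModelSpec(outcome)


def regression_model() -> ModelSpec:
    """Regression-in ~ surprisal × entropy + covariates; all observations."""
    return ModelSpec("regression")


def similarity_model(outcome: str) -> ModelSpec:
    """Outcome ~ target-prediction similarity + covariates (no entropy /
    surprisal terms; used on the low-entropy / high-surprisal subset)."""
    return ModelSpec(outcome, fixed=["top_prediction_similarity"] + COVARIATES)


@dataclass
class TransformDecision:
    """Box-Cox profile-ML check of the duration scale."""

    lambda_: float
    transform: str  # "log" or "identity"


def choose_transform(durations, *, log_band: float = 0.5) -> TransformDecision:
    """Estimate the Box-Cox λ̂ for positive durations and pick the scale.

    λ̂ within ``±log_band`` of zero indicates the log transform; λ̂ near 1
    leaves the data untransformed. Non-positive or constant input is an
    error.
    """
    x = np.asarray(pd.Series(durations).dropna(), dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 durations for a Box-Cox check")
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive durations")
    if np.ptp(x) == 0:
        raise ValueError("durations are constant; no transform is identifiable")
    lam = float(boxcox_normmax(x, method="mle"))
    return TransformDecision(lam, "log" if abs(lam) <= log_band else "identity")


@dataclass
class FitResult:
    """Coefficients, tests and diagnostics from one mixed-model fit.

    ``terms`` has one row per fixed-effect coefficient: beta, se, stat
    (z for binomial, t for Gaussian; p-values use the Wald normal
    approximation), and odds_ratio = exp(beta) for binary outcomes.
    ``anova_r`` carries the car::Anova type-III table returned by the R
    bridge, kept as an independent check on :func:`type3_wald`.
    """

    outcome: str
    family: str
    formula: str
    terms: pd.DataFrame
    vcov: np.ndarray
    re_sd: dict[str, float]
    sigma: float | None
    n: int
    loglik: float
    converged: bool
    singular: bool
    messages: list[str]
    anova_r: pd.DataFrame | None = None

    def coef(self, term: str) -> pd.Series:
        row = self.terms.loc[self.terms["term"] == term]
        if row.empty:
            raise KeyError(f"no term {term!r}; have {list(self.terms['term'])}")
        return row.iloc[0]

    def max_vif_data(self) -> None:  # placeholder for interface symmetry
        raise NotImplementedError("use gazelm.mixedmodels.vif on the data table")


def _prepare(spec: ModelSpec, table: pd.DataFrame) -> pd.DataFrame:
    """Build the modelling frame: response column y plus predictors/groups.

    Duration outcomes keep fixated rows only and take the natural log;
    binary outcomes are 0/1 over all observations. Rows with any missing
    predictor are dropped (count logged).
    """
    cols = spec.variables()
    missing_cols = [c for c in cols + [spec.source_column] if c not in table.columns]
    if missing_cols:
        raise ValueError(f"observation table lacks columns: {missing_cols}")
    d = table.copy()
    if spec.family == "binomial":
        d["y"] = d[spec.source_column].astype(bool).astype(int)
    else:
        d = d.loc[d[spec.source_column].notna()]
        if (d[spec.source_column] <= 0).any():
            raise ValueError("non-positive durations cannot be log-transformed")
        d["y"] = np.log(d[spec.source_column].astype(float))
    keep = ["y", *cols, *spec.groups]
    before = len(d)
    d = d[keep].dropna()
    if len(d) < before:
        log.info("dropped %d rows with missing predictors", before - len(d))
    if d.empty:
        raise ValueError("no rows left to fit")
    d = d.reset_index(drop=True)
    _check_design_rank(spec, d)
    return d


def _check_design_rank(spec: ModelSpec, d: pd.DataFrame) -> None:
    """Raise, naming the aliased terms, if the fixed-effect design is
    rank-deficient (rather than letting the backend drop columns)."""
    names = ["(Intercept)"]
    columns = [np.ones(len(d))]
    for term in spec.fixed:
        parts = re.split(r"[*:]", term)
        expansion = parts if "*" in term else ([term] if ":" not in term else [])
        for v in expansion:
            if v not in names:
                names.append(v)
                columns.append(d[v].to_numpy(dtype=float))
        if len(parts) > 1:
            names.append(":".join(parts))
            columns.append(np.prod([d[v].to_numpy(dtype=float) for v in parts], axis=0))
    X = np.column_stack(columns)
    aliased = []
    rank = 0
    for j in range(X.shape[1]):
        new_rank = np.linalg.matrix_rank(X[:, : j + 1])
        if new_rank == rank:
            aliased.append(names[j])
        rank = new_rank
    if aliased:
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")


def _to_fit_result(spec: ModelSpec, res: dict) -> FitResult:
    if not res.get("ok"):
        raise RuntimeError(f"mixed-model fit {res.get('name')!r} failed: {res.get('error')}")
    beta = np.asarray(res["beta"], dtype=float)
    vcov = np.asarray(res["vcov"], dtype=float)
    se = np.sqrt(np.diag(vcov))
    stat = beta / se
    p = 2.0 * stats.norm.sf(np.abs(stat))
    terms = pd.DataFrame(
        {
            "term": res["terms"],
            "beta": beta,
            "se": se,
            "stat": stat,
            "p": p,
        }
    )
    if res["family"] == "binomial":
        terms["odds_ratio"] = np.exp(beta)
    messages = [str(m) for m in (res.get("messages") or [])]
    converged = not any("failed to converge" in m.lower() for m in messages)
    anova_r = None
    if res.get("anova_type3"):
        at = res["anova_type3"]
        anova_r = pd.DataFrame(
            {"term": at["term"], "chisq": at["chisq"], "df": at["df"], "p": at["p"]}
        )
    sigma = res.get("sigma")
    return FitResult(
        outcome=spec.outcome,
        family=res["family"],
        formula=spec.formula(),
        terms=terms,
        vcov=vcov,
        re_sd={k: float(v) for k, v in (res.get("re_sd") or {}).items()},
        sigma=float(sigma) if sigma is not None else None,
        n=int(res["n"]),
        loglik=float(res["loglik"]),
        converged=converged,
        singular=bool(res.get("singular", False)),
        messages=messages,
        anova_r=anova_r,
    )


def fit_mixed(spec: ModelSpec, table: pd.DataFrame, *, nagq: int = 1) -> FitResult:
    """Fit one analysis. See :func:`fit_mixed_many` to batch several."""
    return fit_mixed_many([("fit", spec, table)], nagq=nagq)["fit"]


def fit_mixed_many(
    requests: list[tuple[str, ModelSpec, pd.DataFrame]],
    *,
    nagq: int = 1,
) -> dict[str, FitResult]:
    """Fit several analyses in a single R session.

    ``requests`` is a list of (name, spec, table); returns name → FitResult.
    Non-convergence or singular variance components are flagged on the
    result, never silently dropped; a hard R-side error raises.
    """
    jobs = []
    specs = {}
    for name, spec, table in requests:
        d = _prepare(spec, table)
        jobs.append(
            Lme4Job(
                name=name,
                data=d,
                formula=spec.formula(),
                family=spec.family,
                nagq=nagq,
            )
        )
        specs[name] = spec
    results = run_lme4_jobs(jobs)
    out = {}
    for res in results:
        out[res["name"]] = _to_fit_result(specs[res["name"]], res)
    return out


def type3_wald(fit: FitResult) -> pd.DataFrame:
    """Type-III Wald chi-square per fixed factor.

    Each factor's coefficients are tested marginally to every other term:
    χ² = β_f' V_f⁻¹ β_f with df = number of coefficients in the factor.
    With purely continuous predictors every coefficient is its own factor,
    so single-df factors satisfy χ² = z² exactly.
    """
    if not fit.converged:
        raise ValueError("type-III tests require a converged fit")
    names = list(fit.terms["term"])
    beta = fit.terms["beta"].to_numpy()
    rows = []
    for j, name in enumerate(names):
        idx = [j]
        b = beta[idx]
        V = fit.vcov[np.ix_(idx, idx)]
        try:
            chisq = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError as e:
            raise ValueError(f"aliased (rank-deficient) term {name!r}") from e
        df = len(idx)
        rows.append((name, chisq, df, float(stats.chi2.sf(chisq, df))))
    return pd.DataFrame(rows, columns=["term", "chisq", "df", "p"])


def vif(table: pd.DataFrame, terms: list[str]) -> pd.Series:
    """Variance inflation factors of the fixed-effect design.

    Terms name numeric columns of ``table``; ``a*b`` / ``a:b`` add the
    product column. Each predictor is regressed on the others (with
    intercept): VIF_j = 1 / (1 - R²_j). Perfectly collinear predictors
    yield ``inf`` rather than raising. The conventional screen flags a
    maximum at or above 2 (logged as a warning).
    """
    cols: dict[str, np.ndarray] = {}
    for term in terms:
        parts = re.split(r"[*:]", term)
        for v in parts:
            if v not in table.columns:
                raise ValueError(f"no column {v!r} in table")
            cols.setdefault(v, table[v].to_numpy(dtype=float))
        if len(parts) > 1:
            prod = np.prod([table[v].to_numpy(dtype=float) for v in parts], axis=0)
            cols.setdefault(":".join(parts), prod)
    if len(cols) < 2:
        raise ValueError("VIF needs at least two fixed terms")
    X = pd.DataFrame(cols).dropna()
    out = {}
    for name in X.columns:
        others = np.column_stack(
            [np.ones(len(X))] + [X[c].to_numpy() for c in X.columns if c != name]
        )
        y = X[name].to_numpy()
        coef, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
        out[name] = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    series = pd.Series(out, name="vif")
    if series.max() >= 2.0:
        log.warning("max VIF %.2f >= 2: possible excessive collinearity", series.max())
    return series
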