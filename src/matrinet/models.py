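"""Mixed-model fits (LMM / binomial GLMM) and printed effect-size summaries.

Every model shares the fixed effects age (months, uncentred), sex (male
indicator; females are the reference), their interaction, the mother's
offspring count, the mother's relative rank and troop, plus — for the
network-metric models — the mother's corresponding metric; random intercepts
are year and immature identity nested within mother identity. Models undergo
no simplification.

Estimation is delegated to lme4 (``lmer``/``glmer``) through a batched
Rscript bridge: the same fitting routine and settings are applied to
observed and permuted datasets, which keeps the permutation inference
internally consistent. The backend is declared in every result's metadata.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
import math
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

BACKEND = "lme4::(g)lmer via Rscript (REML for LMMs, Laplace for GLMMs)"

TERMS_OF_INTEREST = ("age", "sex", "age:sex")


@dataclass(frozen=True)
class ModelSpec:
    """One named model applied to one network kind/mode."""

    name: str  # MP1a ... MP2c.3
    family: str  # gaussian | binomial
    kind: str  # proximity | grooming
    mode: str | None  # grooming: given | received | total
    permutation: str | None  # datastream | node | None (no test)
    metric: str | None = None  # network metric responses (MP2a/MP2b)
    mother_metric: bool = False  # control for the mother's own metric

    @property
    def label(self) -> str:
        return f"{self.name} {self.kind}" + (f" {self.mode}" if self.mode else "")


def _groom_modes(name, family, modes, permutation="node", **kw):
    return [ModelSpec(name, family, "grooming", m, permutation, **kw) for m in modes]


#: the full model roster: each prediction applied to its networks
MODEL_SPECS: list[ModelSpec] = (
    [
        # P1a: time with mother (no permutation test: not a network metric)
        ModelSpec("MP1a", "binomial", "proximity", None, None),
        ModelSpec("MP1a", "binomial", "grooming", "total", None),
        # P1b: mother-offspring ego-network Pearson correlation
        ModelSpec("MP1b", "gaussian", "proximity", None, "datastream"),
    ]
    + _groom_modes("MP1b", "gaussian", ["given", "received", "total"])
    + [ModelSpec("MP1c.1", "binomial", "proximity", None, "datastream")]
    + _groom_modes("MP1c.1", "binomial", ["given", "received", "total"])
    + [ModelSpec("MP1c.2", "binomial", "proximity", None, "datastream")]
    + _groom_modes("MP1c.2", "binomial", ["given", "received", "total"])
    + [
        ModelSpec(
            "MP2a", "gaussian", "proximity", None, "datastream",
            metric="strength_prox", mother_metric=True,
        )
    ]
    + [
        ModelSpec(
            "MP2a", "gaussian", "grooming", m, "node",
            metric=f"strength_groom_{m}", mother_metric=True,
        )
        for m in ("given", "received", "total")
    ]
    + [
        ModelSpec(
            "MP2b.1", "gaussian", "proximity", None, "datastream",
            metric="eigencent_prox", mother_metric=True,
        ),
        ModelSpec(
            "MP2b.1", "gaussian", "grooming", "total", "node",
            metric="eigencent_groom_total", mother_metric=True,
        ),
        ModelSpec(
            "MP2b.2", "gaussian", "proximity", None, "datastream",
            metric="betweenness_prox", mother_metric=True,
        ),
        ModelSpec(
            "MP2b.2", "gaussian", "grooming", "total", "node",
            metric="betweenness_groom_total", mother_metric=True,
        ),
        # P2c: partner-category proportions; node permutations also for proximity
        ModelSpec("MP2c.1", "binomial", "proximity", None, "node"),
    ]
    + _groom_modes("MP2c.1", "binomial", ["given", "received", "total"])
    + [ModelSpec("MP2c.2", "binomial", "proximity", None, "node")]
    + _groom_modes("MP2c.2", "binomial", ["given", "received", "total"])
    + [ModelSpec("MP2c.3", "binomial", "proximity", None, "node")]
    + _groom_modes("MP2c.3", "binomial", ["given", "received", "total"])
)


def spec_by_label(label: str) -> ModelSpec:
    for s in MODEL_SPECS:
        if s.label == label:
            return s
    raise KeyError(label)


@dataclass
class FitResult:
    model: str
    terms: pd.DataFrame  # term, estimate, se [, odds_ratio]
    converged: bool
    singular: bool
    messages: str
    n_rows: int
    n_immatures: int
    n_mothers: int
    backend: str = BACKEND

    def estimate(self, term: str) -> float:
        row = self.terms.loc[self.terms.term == term]
        if row.empty:
            raise KeyError(f"term {term!r} not in fit {self.model}")
        return float(row.estimate.iloc[0])

    def se(self, term: str) -> float:
        row = self.terms.loc[self.terms.term == term]
        if row.empty:
            raise KeyError(f"term {term!r} not in fit {self.model}")
        return float(row.se.iloc[0])


# ---------------------------------------------------------------------------
# Model table assembly


REQUIRED_COVARIATES = ["age", "sex", "n_offspring", "mother_rank", "troop", "year", "immature", "mother"]


def build_model_table(rows: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Validate and clean an assembled (immature x troop-period) table.

    Rows with missing covariates (e.g. the mother lacks a rank that season)
    are dropped with a logged count; duplicate (immature, period) rows are an
    error.
    """
    df = rows.copy()
    dup = df.duplicated(subset=["immature", "troop", "period_index"])
    if dup.any():
        raise ValueError(f"duplicate (immature, period) rows: {df[dup].head()}")
    needed = list(REQUIRED_COVARIATES)
    if spec.mother_metric:
        needed.append("mother_metric")
    value_cols = ["k", "n"] if spec.family == "binomial" else ["y"]
    before = len(df)
    df = df.dropna(subset=needed + value_cols)
    dropped = before - len(df)
    if dropped:
        log.info("%s: dropped %d/%d rows with missing covariates", spec.label, dropped, before)
    return df.reset_index(drop=True)


def model_formula(spec: ModelSpec, table: pd.DataFrame) -> str:
    """lme4 formula; single-level factors are dropped (with a log note)."""
    lhs = "cbind(k, n - k)" if spec.family == "binomial" else "y"
    fixed = ["age", "sex", "age:sex", "n_offspring", "mother_rank"]
    if table.troop.nunique() > 1:
        fixed.append("troop")
    else:
        log.info("%s: single troop, dropping troop fixed factor", spec.label)
    if spec.mother_metric:
        fixed.append("mother_metric")
    random = ["(1 | mother / immature)"]
    if table.year.nunique() > 1:
        random.append("(1 | year)")
    else:
        log.info("%s: single year, dropping year random intercept", spec.label)
    return f"{lhs} ~ " + " + ".join(fixed + random)


# ---------------------------------------------------------------------------
# lme4 bridge


def _r_driver_path() -> Path:
    return Path(importlib.resources.files("matrinet") / "r" / "fit_lme4.R")


def fit_batch(
    table: pd.DataFrame, spec: ModelSpec, reml: bool = True, timeout: int = 3600
) -> dict[int, FitResult]:
    """Fit one model formula to every ``.replicate`` block of ``table``.

    Replicate 0 conventionally holds the observed data; 1..K the permuted
    datasets. Returns a FitResult per replicate that fitted successfully.
    """
    df = table.copy()
    if ".replicate" not in df.columns:
        df[".replicate"] = 0
    formula = model_formula(spec, df)
    with tempfile.TemporaryDirectory(prefix="matrinet_lme4_") as tmp:
        tmp = Path(tmp)
        df.to_csv(tmp / "data.csv", index=False)
        (tmp / "job.json").write_text(
            json.dumps({"formula": formula, "family": spec.family, "reml": reml})
        )
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(_r_driver_path()), str(tmp)],
            capture_output=True,
            text=True,
            timeout=timeout,
        )
        if proc.returncode != 0:
            raise RuntimeError(
                f"lme4 bridge failed for {spec.label}:\n{proc.stderr[-2000:]}"
            )
        coefs = pd.read_csv(tmp / "coefs.csv")
        status = pd.read_csv(tmp / "status.csv")

    out: dict[int, FitResult] = {}
    for st in status.itertuples(index=False):
        rep = int(st.replicate)
        sub = df[df[".replicate"] == rep]
        terms = coefs[coefs.replicate == rep][["term", "estimate", "se"]].reset_index(drop=True)
        if spec.family == "binomial" and not terms.empty:
            terms = terms.assign(odds_ratio=np.exp(terms.estimate))
        ok = bool(st.ok)
        messages = "" if pd.isna(st.messages) else str(st.messages)
        converged = ok and "failed to converge" not in messages
        if not ok:
            log.warning("%s replicate %d: fit failed: %s", spec.label, rep, messages)
        out[rep] = FitResult(
            model=spec.label,
            terms=terms,
            converged=converged,
            singular=bool(st.singular),
            messages=messages,
            n_rows=len(sub),
            n_immatures=sub.immature.nunique(),
            n_mothers=sub.mother.nunique(),
        )
    return out


def fit_lmm(table: pd.DataFrame, spec: ModelSpec, reml: bool = True) -> FitResult:
    """REML linear mixed model for a Gaussian response column ``y``."""
    if spec.family != "gaussian":
        raise ValueError("fit_lmm requires a gaussian spec")
    return fit_batch(table, spec, reml=reml)[0]


def fit_binomial_glmm(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Logit-link binomial mixed model on successes/trials columns (k, n)."""
    if spec.family != "binomial":
        raise ValueError("fit_binomial_glmm requires a binomial spec")
    if (table["k"] == table["n"]).all() or (table["k"] == 0).all():
        result = fit_batch(table, spec)[0]
        result.converged = False
        result.messages = (result.messages + " | degenerate response (all k==n or all k==0)").strip(" |")
        return result
    return fit_batch(table, spec)[0]


# ---------------------------------------------------------------------------
# Printed effect-size summaries


def odds_percent(beta: float) -> float:
    """Percent change in odds per unit of the predictor: (OR - 1) * 100."""
    return (math.exp(beta) - 1.0) * 100.0


def age_change_percent(
    beta_age: float, beta_age_sex: float = 0.0, male: bool = False, t0: float = 12.0, t1: float = 48.0
) -> float:
    """Percent change in odds between ages t0 and t1: [(OR_t1 - OR_t0)/OR_t0] * 100.

    The age slope for males includes the interaction term (conditional
    effects interpretation).
    """
    slope = beta_age + (beta_age_sex if male else 0.0)
    return (math.exp(slope * (t1 - t0)) - 1.0) * 100.0


def sex_effect_percent(beta_sex: float, beta_age_sex: float = 0.0, age: float = 30.0) -> float:
    """Percent difference in odds for males vs females at a given age."""
    return (math.exp(beta_sex + beta_age_sex * age) - 1.0) * 100.0


def lmm_range_percent(
    slope: float, observed_range: float, t0: float = 12.0, t1: float = 48.0
) -> float:
    """LMM age effect as a percentage of the response's observed range."""
    if observed_range <= 0:
        raise ValueError("observed range must be positive")
    return slope * (t1 - t0) / observed_range * 100.0


def fit_age_change_percent(fit: FitResult, male: bool, t0: float = 12.0, t1: float = 48.0) -> float:
    return age_change_percent(fit.estimate("age"), fit.estimate("age:sex"), male, t0, t1)


def fit_sex_effect_percent(fit: FitResult, age: float = 30.0) -> float:
    return sex_effect_percent(fit.estimate("sex"), fit.estimate("age:sex"), age)
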