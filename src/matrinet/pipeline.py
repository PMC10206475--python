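"""End-to-end orchestration: records -> periods -> filters -> ranks ->
networks -> metrics -> responses -> mixed models -> permutation p-values ->
report.

Permutation inference: each model with a permutation test is refitted on K
null datasets; null dataset k is assembled from chain state k of every
period's permutation chain. The two-tailed p-value for a term is
``2 * min(#(null >= obs), #(null <= obs)) / K`` capped at 1, reported
alongside the binary significance label ("0.05" when p <= 0.05, else "NS")
used in the field's reporting convention. With K = 100 the smallest
attainable p under this rule is 0.02.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .config import (
    IMMATURE_MAX_AGE_MONTHS,
    FilterConfig,
    PermutationSchedule,
    SimulationConfig,
)
from .models import (
    BACKEND,
    TERMS_OF_INTEREST,
    FitResult,
    ModelSpec,
    MODEL_SPECS,
    build_model_table,
    fit_batch,
    fit_age_change_percent,
    fit_sex_effect_percent,
    lmm_range_percent,
)
from .networks import (
    GroupByIndividualMatrix,
    gbi_matrix,
    grooming_matrices,
    sri_matrix,
)
from .periods import SamplingPeriod, assign_periods, filter_individuals, filter_periods
from .permute import PermutedSet, datastream_chain, node_chain
from .ranks import dominance_matrix, isi_order, rank_table
from .records import Individual, Season
from .responses import (
    compare_vs_mean,
    compare_vs_random,
    mother_offspring_similarity,
    partner_category_proportion,
    time_with_mother_grooming,
    time_with_mother_proximity,
)
from . import metrics as metrics_mod
from .simulate import SimulatedData

log = logging.getLogger(__name__)


@dataclass
class AnalysisContext:
    """Everything the response builders need, computed once per dataset."""

    individuals: list[Individual]
    seasons: list[Season]
    prox_periods: dict[tuple, SamplingPeriod]
    prox_records: dict[tuple, list]
    groom_periods: dict[tuple, SamplingPeriod]
    groom_records: dict[tuple, list]
    gbis: dict[tuple, GroupByIndividualMatrix]
    prox_weights: dict[tuple, tuple[list[str], np.ndarray]]  # key -> (ids, SRI)
    groom_given: dict[tuple, tuple[list[str], np.ndarray]]  # key -> (ids, counts i->j)
    ranks: dict[tuple[str, int], dict[str, float]]  # (troop, year) -> id -> relative rank
    mother_of: dict[str, str] = field(default_factory=dict)
    sex_of: dict[str, str] = field(default_factory=dict)
    n_offspring: dict[str, int] = field(default_factory=dict)
    filter_counts: dict[str, int] = field(default_factory=dict)

    def individual(self, iid: str) -> Individual:
        return self._index[iid]

    def __post_init__(self) -> None:
        self._index = {i.id: i for i in self.individuals}
        self.mother_of = {i.id: i.mother_id for i in self.individuals if i.mother_id}
        self.sex_of = {i.id: i.sex for i in self.individuals}
        counts: dict[str, int] = {}
        for i in self.individuals:
            if i.mother_id:
                counts[i.mother_id] = counts.get(i.mother_id, 0) + 1
        self.n_offspring = counts

    def ages_at(self, on: date) -> dict[str, float]:
        return {i.id: i.age_months(on) for i in self.individuals}

    def periods_for(self, kind: str) -> dict[tuple, SamplingPeriod]:
        return self.prox_periods if kind == "proximity" else self.groom_periods


def build_context(data: SimulatedData, filters: FilterConfig | None = None) -> AnalysisContext:
    """Assign periods, apply filters, rank females and build observed networks."""
    filters = filters or FilterConfig()

    prox_periods, prox_assign = assign_periods(data.scans, data.seasons, data.config.period_days)
    prox_periods, prox_assign = filter_periods(
        prox_periods, prox_assign, filters.min_observations_per_period
    )
    prox_keep = filter_individuals(prox_periods, prox_assign, filters.min_sightings_per_season)

    groom_periods, groom_assign = assign_periods(data.grooming, data.seasons, data.config.period_days)
    groom_periods, groom_assign = filter_periods(
        groom_periods, groom_assign, filters.min_observations_per_period
    )
    groom_keep = filter_individuals(groom_periods, groom_assign, filters.min_sightings_per_season)

    gbis, prox_weights = {}, {}
    for p in prox_periods:
        ids = sorted(
            {m for r in prox_assign[p.key()] for m in r.subgroup_ids}
            & prox_keep[(p.troop, p.year)]
        )
        if len(ids) < 3:
            continue
        gbi = gbi_matrix(prox_assign[p.key()], p, ids)
        gbis[p.key()] = gbi
        prox_weights[p.key()] = (ids, sri_matrix(gbi).weights)

    groom_given = {}
    for p in groom_periods:
        ids = sorted(
            {x for r in groom_assign[p.key()] for x in (r.giver_id, r.recipient_id)}
            & groom_keep[(p.troop, p.year)]
        )
        if len(ids) < 3:
            continue
        gm = grooming_matrices(groom_assign[p.key()], p, "given", ids)
        groom_given[p.key()] = (ids, gm.values)

    ranks: dict[tuple[str, int], dict[str, float]] = {}
    for season in data.seasons:
        recs = [
            r
            for r in data.dominance
            if r.troop == season.troop and season.start_date <= r.when.date() <= season.end_date
        ]
        if not recs:
            continue
        dom = dominance_matrix(recs)
        try:
            order, _ = isi_order(dom)
        except ValueError:
            continue
        table = rank_table(order, season.troop, season.year)
        ranks[(season.troop, season.year)] = dict(zip(table.id, table.relative_rank))

    return AnalysisContext(
        individuals=data.individuals,
        seasons=data.seasons,
        prox_periods={p.key(): p for p in prox_periods if p.key() in gbis},
        prox_records={k: prox_assign[k] for k in gbis},
        groom_periods={p.key(): p for p in groom_periods if p.key() in groom_given},
        groom_records={k: groom_assign[k] for k in groom_given},
        gbis=gbis,
        prox_weights=prox_weights,
        groom_given=groom_given,
        ranks=ranks,
    )


# ---------------------------------------------------------------------------
# Response assembly


def _matrix_for(spec: ModelSpec, ids: list[str], base: np.ndarray) -> np.ndarray:
    """Derive the matrix a spec consumes from the period's base matrix
    (SRI for proximity; given-counts for grooming).

    The returned matrix is always read row-wise: mode transposition happens
    here, so downstream consumers treat rows as the focal's out-edges. The
    network-metric models receive the raw given-counts matrix because the
    metric functions apply in/out/total semantics themselves.
    """
    if spec.kind == "proximity":
        return base
    if spec.name in ("MP2a", "MP2b.1", "MP2b.2"):
        return base
    given = base
    values = {"given": given, "received": given.T, "total": given + given.T}[spec.mode]
    if spec.name in ("MP1b", "MP1c.1", "MP1c.2"):  # similarity models use proportions
        sums = values.sum(axis=1, keepdims=True)
        values = np.divide(values, sums, out=np.zeros_like(values, dtype=float), where=sums > 0)
    return values


def _base_matrices(spec: ModelSpec, ctx: AnalysisContext) -> dict[tuple, tuple[list[str], np.ndarray]]:
    return ctx.prox_weights if spec.kind == "proximity" else ctx.groom_given


def _covariate_row(ctx: AnalysisContext, spec: ModelSpec, period: SamplingPeriod, imm: Individual) -> dict | None:
    mother = imm.mother_id
    rank = ctx.ranks.get((period.troop, period.year), {}).get(mother, np.nan)
    return dict(
        model=spec.label,
        troop=period.troop,
        period_index=period.index,
        year=period.year,
        immature=imm.id,
        mother=mother,
        age=imm.age_months(period.midpoint),
        sex=1 if imm.sex == "M" else 0,
        n_offspring=ctx.n_offspring.get(mother, np.nan),
        mother_rank=rank,
    )


def _immatures_in(ctx: AnalysisContext, period: SamplingPeriod, ids: list[str]) -> list[Individual]:
    out = []
    for iid in ids:
        ind = ctx.individual(iid)
        if ind.mother_id is None:
            continue
        if ind.age_months(period.midpoint) <= IMMATURE_MAX_AGE_MONTHS:
            out.append(ind)
    return out


def assemble_rows(
    spec: ModelSpec,
    ctx: AnalysisContext,
    rng: np.random.Generator,
    override: dict[tuple, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Build the (immature x period) response/covariate table for one spec.

    ``override`` substitutes permuted base matrices (keyed by period) for the
    observed ones; record-based responses (MP1a) take no override.
    """
    rows: list[dict] = []
    if spec.name == "MP1a":
        rows = _rows_time_with_mother(spec, ctx)
    else:
        base = _base_matrices(spec, ctx)
        for key in sorted(base):
            ids, observed = base[key]
            matrix = override[key] if override is not None and key in override else observed
            weights = _matrix_for(spec, ids, matrix)
            period = ctx.periods_for(spec.kind)[key]
            if spec.name == "MP1b":
                rows += _rows_similarity(spec, ctx, period, ids, weights)
            elif spec.name in ("MP1c.1", "MP1c.2"):
                rows += _rows_binary(spec, ctx, period, ids, weights, rng)
            elif spec.name in ("MP2a", "MP2b.1", "MP2b.2"):
                rows += _rows_metric(spec, ctx, period, ids, weights)
            elif spec.name in ("MP2c.1", "MP2c.2", "MP2c.3"):
                rows += _rows_partner(spec, ctx, period, ids, weights)
            else:
                raise ValueError(f"unknown model {spec.name}")
    return pd.DataFrame(rows)


def _rows_time_with_mother(spec: ModelSpec, ctx: AnalysisContext) -> list[dict]:
    rows = []
    records = ctx.prox_records if spec.kind == "proximity" else ctx.groom_records
    periods = ctx.periods_for(spec.kind)
    base = _base_matrices(spec, ctx)
    for key in sorted(records):
        period = periods[key]
        ids = base[key][0]
        for imm in _immatures_in(ctx, period, ids):
            if imm.mother_id not in ids:
                log.debug("MP1a: mother of %s absent in %s", imm.id, key)
                continue
            if spec.kind == "proximity":
                prop = time_with_mother_proximity(records[key], imm.id, imm.mother_id)
            else:
                prop = time_with_mother_grooming(records[key], imm.id, imm.mother_id)
            if prop.n == 0:
                continue
            row = _covariate_row(ctx, spec, period, imm)
            row.update(k=prop.k, n=prop.n)
            rows.append(row)
    return rows


def _rows_similarity(spec, ctx, period, ids, weights) -> list[dict]:
    rows = []
    for imm in _immatures_in(ctx, period, ids):
        if imm.mother_id not in ids or len(ids) < 5:
            continue
        r, cos = mother_offspring_similarity(ids, weights, imm.id, imm.mother_id)
        if np.isnan(r):
            continue
        row = _covariate_row(ctx, spec, period, imm)
        row.update(y=r, cosine=cos)
        rows.append(row)
    return rows


def _rows_binary(spec, ctx, period, ids, weights, rng) -> list[dict]:
    rows = []
    for imm in _immatures_in(ctx, period, ids):
        if imm.mother_id not in ids or len(ids) < 5:
            continue
        if spec.name == "MP1c.1":
            res = compare_vs_random(ids, weights, imm.id, imm.mother_id, rng)
        else:
            res = compare_vs_mean(ids, weights, imm.id, imm.mother_id)
        if res is None:
            continue
        score, comparator = res
        row = _covariate_row(ctx, spec, period, imm)
        row.update(k=score, n=1, comparator=str(comparator))
        rows.append(row)
    return rows


def _rows_metric(spec, ctx, period, ids, weights) -> list[dict]:
    try:
        table = metrics_mod.metric_table(spec.metric, ids, weights)
    except ValueError as err:
        log.warning("%s: skipping period %s: %s", spec.label, period.key(), err)
        return []
    std = dict(zip(table.id, table.standardized))
    rows = []
    for imm in _immatures_in(ctx, period, ids):
        if imm.mother_id not in std:
            continue
        row = _covariate_row(ctx, spec, period, imm)
        row.update(y=std[imm.id], mother_metric=std[imm.mother_id])
        rows.append(row)
    return rows


_CATEGORY = {"MP2c.1": "immature", "MP2c.2": "peer", "MP2c.3": "same_sex"}
# matrices arrive mode-transposed from _matrix_for, so rows are always the
# focal's out-edges in the requested sense
_DIRECTION = {"given": "out", "received": "out", "total": "either", None: "either"}


def _rows_partner(spec, ctx, period, ids, weights) -> list[dict]:
    ages = ctx.ages_at(period.midpoint)
    rows = []
    for imm in _immatures_in(ctx, period, ids):
        prop = partner_category_proportion(
            ids,
            weights,
            imm.id,
            _CATEGORY[spec.name],
            ages,
            ctx.sex_of,
            _DIRECTION[spec.mode],
        )
        if prop is None:
            continue
        row = _covariate_row(ctx, spec, period, imm)
        row.update(k=prop.k, n=prop.n)
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# Permutation machinery


def null_matrix_sets(
    ctx: AnalysisContext, method: str, kind: str, schedule: PermutationSchedule, seed: int
) -> dict[tuple, PermutedSet]:
    """Permutation chains for every period of a network kind.

    datastream chains run on the proximity GBIs and yield null SRI matrices;
    node chains relabel the period's base matrix (SRI or given-counts).
    """
    sched = PermutationSchedule(
        schedule.total, schedule.burn_in, schedule.swaps_per_step, method, schedule.rng_seed
    )
    root = np.random.SeedSequence(seed)
    out: dict[tuple, PermutedSet] = {}
    base = ctx.prox_weights if kind == "proximity" else ctx.groom_given
    periods = ctx.periods_for(kind)
    for key in sorted(base):
        child = np.random.default_rng(root.spawn(1)[0])
        if method == "datastream":
            out[key] = datastream_chain(ctx.gbis[key], sched, child)
        else:
            ids, weights = base[key]
            out[key] = node_chain(weights, periods[key], ids, sched, child)
    return out


@dataclass
class PermutationResult:
    model: str
    term: str
    observed: float
    null_betas: list[float]
    p_two_tailed: float
    label: str  # "0.05" or "NS"
    unreliable: bool = False


def two_tailed_p(observed: float, null_betas: list[float]) -> float:
    null = np.asarray(null_betas, dtype=float)
    k = len(null)
    if k == 0:
        return float("nan")
    ge = int(np.sum(null >= observed))
    le = int(np.sum(null <= observed))
    return min(1.0, 2.0 * min(ge, le) / k)


def significance_label(p: float) -> str:
    return "0.05" if p <= 0.05 else "NS"


def run_model_with_permutations(
    spec: ModelSpec,
    ctx: AnalysisContext,
    schedule: PermutationSchedule,
    seed: int,
    null_sets: dict[tuple, PermutedSet] | None = None,
    terms: tuple[str, ...] = TERMS_OF_INTEREST,
) -> tuple[FitResult, list[PermutationResult]]:
    """Observed fit plus permutation p-values for the requested terms.

    All K+1 datasets (observed and nulls) are fitted in a single batched
    backend call with identical settings.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0)))
    observed_rows = assemble_rows(spec, ctx, rng)
    if observed_rows.empty:
        raise ValueError(f"{spec.label}: no model rows")
    observed_table = build_model_table(observed_rows, spec)
    tables = [observed_table.assign(**{".replicate": 0})]

    if spec.permutation is not None:
        if null_sets is None:
            null_sets = null_matrix_sets(ctx, spec.permutation, spec.kind, schedule, seed)
        for k in range(schedule.keep):
            rng_k = np.random.default_rng(np.random.SeedSequence((seed, k + 1)))
            override = {key: ps.matrices[k] for key, ps in null_sets.items()}
            null_rows = assemble_rows(spec, ctx, rng_k, override)
            if null_rows.empty:
                continue
            tables.append(build_model_table(null_rows, spec).assign(**{".replicate": k + 1}))

    fits = fit_batch(pd.concat(tables, ignore_index=True), spec)
    observed_fit = fits[0]
    results: list[PermutationResult] = []
    if spec.permutation is not None:
        null_fits = [f for rep, f in sorted(fits.items()) if rep > 0]
        n_bad = sum(1 for f in null_fits if not f.converged)
        unreliable = len(null_fits) == 0 or n_bad / max(len(null_fits), 1) > 0.20
        for term in terms:
            try:
                obs = observed_fit.estimate(term)
            except KeyError:
                continue
            nulls = []
            for f in null_fits:
                try:
                    nulls.append(f.estimate(term))
                except KeyError:
                    pass
            p = two_tailed_p(obs, nulls)
            results.append(
                PermutationResult(
                    spec.label, term, obs, nulls, p, significance_label(p), unreliable
                )
            )
    return observed_fit, results


# ---------------------------------------------------------------------------
# Full analysis + report


@dataclass
class AnalysisReport:
    fits: dict[str, FitResult]
    permutations: list[PermutationResult]
    effects: pd.DataFrame
    metadata: dict

    def term_table(self) -> pd.DataFrame:
        """Tables-2/3-style layout: estimate, s.e., permutation p label.

        The values reported for sex refer to males (females are the
        reference level).
        """
        perm = {(r.model, r.term): r for r in self.permutations}
        rows = []
        for label, fit in self.fits.items():
            for term in TERMS_OF_INTEREST:
                try:
                    est, se = fit.estimate(term), fit.se(term)
                except KeyError:
                    continue
                pr = perm.get((label, term))
                rows.append(
                    dict(
                        model=label,
                        variable=term,
                        estimate=est,
                        se=se,
                        p_label=pr.label if pr else "",
                        p_value=pr.p_two_tailed if pr else np.nan,
                        converged=fit.converged,
                    )
                )
        return pd.DataFrame(rows)

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table = self.term_table()
        if table.empty:
            raise ValueError("empty results: nothing to report")
        table.to_csv(outdir / "fits.csv", index=False)
        self.effects.to_csv(outdir / "effects.csv", index=False)
        perm_rows = pd.DataFrame(
            [
                dict(
                    model=r.model,
                    term=r.term,
                    observed=r.observed,
                    p_two_tailed=r.p_two_tailed,
                    label=r.label,
                    n_null=len(r.null_betas),
                    unreliable=r.unreliable,
                )
                for r in self.permutations
            ]
        )
        perm_rows.to_csv(outdir / "permutations.csv", index=False)
        lines = [
            "Model term estimates (sex values refer to males; females are the reference)",
            "",
            table.to_string(index=False, float_format=lambda v: f"{v: .4f}"),
            "",
            "Effect-size summaries",
            "",
            self.effects.to_string(index=False, float_format=lambda v: f"{v: .2f}"),
            "",
            "Run metadata: " + ", ".join(f"{k}={v}" for k, v in self.metadata.items()),
        ]
        (outdir / "report.txt").write_text("\n".join(lines) + "\n")


def effect_summaries(fits: dict[str, FitResult], tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Printed effect sizes: odds changes between 12 and 48 months per sex,
    sex effect at 30 months (binomial); range percentages (gaussian)."""
    rows = []
    for label, fit in fits.items():
        try:
            fit.estimate("age"), fit.estimate("age:sex")
        except KeyError:
            continue
        spec_family = "binomial" if "odds_ratio" in fit.terms.columns else "gaussian"
        if spec_family == "binomial":
            for male in (False, True):
                rows.append(
                    dict(
                        model=label,
                        quantity="age_change_pct",
                        sex="M" if male else "F",
                        value_pct=fit_age_change_percent(fit, male),
                    )
                )
            rows.append(
                dict(
                    model=label,
                    quantity="sex_effect_pct_at_30mo",
                    sex="M_vs_F",
                    value_pct=fit_sex_effect_percent(fit),
                )
            )
        else:
            table = tables.get(label)
            if table is None or "y" not in table:
                continue
            rng_ = float(table.y.max() - table.y.min())
            if rng_ <= 0:
                continue
            for male in (False, True):
                slope = fit.estimate("age") + (fit.estimate("age:sex") if male else 0.0)
                rows.append(
                    dict(
                        model=label,
                        quantity="age_range_pct",
                        sex="M" if male else "F",
                        value_pct=lmm_range_percent(slope, rng_),
                    )
                )
    return pd.DataFrame(rows)


def run_full_analysis(
    data: SimulatedData,
    schedule: PermutationSchedule | None = None,
    filters: FilterConfig | None = None,
    seed: int = 0,
    specs: list[ModelSpec] | None = None,
    outdir=None,
) -> AnalysisReport:
    """Execute the complete pipeline on one dataset.

    ``specs`` restricts the model roster (default: every model). Stage
    failures abort with a stage-labelled error.
    """
    schedule = schedule or PermutationSchedule()
    specs = specs if specs is not None else MODEL_SPECS
    try:
        ctx = build_context(data, filters)
    except Exception as err:
        raise RuntimeError(f"stage build_context failed: {err}") from err

    # shared null chains per (method, kind)
    cache: dict[tuple[str, str], dict[tuple, PermutedSet]] = {}
    fits: dict[str, FitResult] = {}
    tables: dict[str, pd.DataFrame] = {}
    permutations: list[PermutationResult] = []
    for spec in specs:
        try:
            null_sets = None
            if spec.permutation is not None:
                ck = (spec.permutation, spec.kind)
                if ck not in cache:
                    cache[ck] = null_matrix_sets(ctx, spec.permutation, spec.kind, schedule, seed)
                null_sets = cache[ck]
            fit, perm = run_model_with_permutations(spec, ctx, schedule, seed, null_sets)
            fits[spec.label] = fit
            rng = np.random.default_rng(np.random.SeedSequence((seed, 0)))
            tables[spec.label] = build_model_table(assemble_rows(spec, ctx, rng), spec)
            permutations.extend(perm)
        except Exception as err:
            raise RuntimeError(f"stage model {spec.label} failed: {err}") from err

    effects = effect_summaries(fits, tables)
    report = AnalysisReport(
        fits,
        permutations,
        effects,
        metadata=dict(
            seed=seed,
            schedule=f"{schedule.total}/{schedule.burn_in}/{schedule.keep}x{schedule.swaps_per_step}",
            backend=BACKEND,
            n_prox_periods=len(ctx.prox_periods),
            n_groom_periods=len(ctx.groom_periods),
        ),
    )
    if outdir is not None:
        report.write(outdir)
    return report
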