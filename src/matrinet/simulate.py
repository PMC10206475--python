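"""Synthetic troop generator.

Produces multi-troop, multi-season observation streams (proximity scans,
grooming events, dominance interactions) with known ground truth, emulating
scan sampling of 10 m subgroups from randomized focal lists, ad libitum
grooming with half-hour dyad deduplication, and ad libitum dominance
interactions among adult females.

The generative social structure has three ingredients (see docs/methods.md):

* **Social inheritance** — an immature's association-propensity row is a
  mixture ``w * mother_row + (1 - w) * homophily``, with
  ``w = lambda0 * exp(-(delta + delta_male*[male]) * age_months)``.
* **Homophily** — a Gaussian kernel of age distance plus a same-sex affinity
  growing linearly with the focal's age.
* **Mother attachment** — the probability that an immature is recorded in the
  same subgroup as its mother follows a logit-linear model in age, sex and
  their interaction, applied at the record level so the time-with-mother
  response is binomial-logit by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimulationConfig
from .records import (
    DominanceRecord,
    GroomingRecord,
    Individual,
    ScanRecord,
    Season,
)

MONTH_DAYS = 30.4375

_SCAN_SPACING_MIN = 4  # minutes between successive focal scans within a sweep
_RESAMPLE_SUPPRESSION = timedelta(hours=1)
_GROOM_DEDUP = timedelta(minutes=30)


@dataclass
class Population:
    """Simulated individuals plus generator-internal structure."""

    individuals: list[Individual]
    matriline: dict[str, int]  # id -> matriline index within its troop
    latent_rank: dict[str, int]  # adult females: 1 = highest within troop

    def by_troop(self, troop: str) -> list[Individual]:
        return [i for i in self.individuals if i.troop == troop]

    def lookup(self, id_: str) -> Individual:
        return next(i for i in self.individuals if i.id == id_)

    @property
    def troops(self) -> list[str]:
        seen: dict[str, None] = {}
        for i in self.individuals:
            seen.setdefault(i.troop, None)
        return list(seen)


@dataclass
class PropensityModel:
    """Latent per-scan and grooming propensities for one troop at one date."""

    ids: list[str]
    association: np.ndarray  # symmetric, zero diagonal, per-scan join probabilities
    grooming: np.ndarray  # directed, zero diagonal, relative event weights
    attachment: dict[str, float]  # immature id -> P(recorded with mother | recorded)

    def __post_init__(self) -> None:
        a = self.association
        if not np.allclose(a, a.T) or np.any(np.diag(a) != 0):
            raise ValueError("association propensity must be symmetric with zero diagonal")
        if np.any(np.diag(self.grooming) != 0):
            raise ValueError("grooming propensity must have zero diagonal")


def _season_calendar(config: SimulationConfig) -> list[Season]:
    seasons = []
    for year, n_periods in config.seasons:
        start = date(year, 6, 1)
        end = start + timedelta(days=n_periods * config.period_days - 1)
        for t in range(config.n_troops):
            seasons.append(Season(_troop_name(t), year, start, end))
    return seasons


def _troop_name(idx: int) -> str:
    return f"T{idx + 1}"


def reference_date(config: SimulationConfig) -> date:
    """Simulation epoch: the first season's start; ages are specified here."""
    return date(min(y for y, _ in config.seasons), 6, 1)


def inheritance_weight(config: SimulationConfig, age_months: float, is_male: bool) -> float:
    rate = config.delta + (config.delta_male if is_male else 0.0)
    return config.lambda0 * float(np.exp(-rate * max(age_months, 0.0)))


def _default_immature_roster(config: SimulationConfig):
    ages = np.linspace(4.0, 56.0, config.immatures_per_troop)
    for k, age in enumerate(ages):
        yield age, ("F" if k % 2 == 0 else "M"), k % config.n_matrilines


def make_population(config: SimulationConfig) -> Population:
    """Create the troops: ranked adult females in matrilines, adult males,
    and immatures each with a living mother in their natal matriline."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    ref = reference_date(config)
    individuals: list[Individual] = []
    matriline: dict[str, int] = {}
    latent_rank: dict[str, int] = {}

    roster = list(config.immatures) if config.immatures is not None else None
    for t in range(config.n_troops):
        troop = _troop_name(t)
        females_by_matriline: dict[int, list[str]] = {}
        for m in range(config.n_matrilines):
            for a in range(config.adults_per_matriline):
                iid = f"{troop}.F{m}{a}"
                age = 84.0 + 18.0 * a + 6.0 * m
                birth = ref - timedelta(days=age * MONTH_DAYS)
                individuals.append(Individual(iid, "F", birth, None, troop))
                matriline[iid] = m
                females_by_matriline.setdefault(m, []).append(iid)
        for a in range(config.adult_males_per_troop):
            iid = f"{troop}.M{a}"
            age = 96.0 + 12.0 * a
            birth = ref - timedelta(days=age * MONTH_DAYS)
            individuals.append(Individual(iid, "M", birth, None, troop))
            matriline[iid] = -1  # males are immigrants: no natal matriline here

        if roster is not None:
            troop_roster = [(s.age_months, s.sex, s.matriline) for s in roster]
        else:
            troop_roster = list(_default_immature_roster(config))
        for k, (age, sex, m) in enumerate(troop_roster):
            mothers = females_by_matriline.get(m, [])
            if not mothers:
                raise ConfigurationError(f"matriline {m} has no adult female")
            # siblings share mothers: offspring counts vary between 1 and 3
            mother = mothers[(k // config.n_matrilines) % min(2, len(mothers))]
            iid = f"{troop}.I{k}"
            birth = ref - timedelta(days=age * MONTH_DAYS)
            individuals.append(Individual(iid, sex, birth, mother, troop))
            matriline[iid] = m

        # latent dominance order over this troop's adult females
        females = [i for i in individuals if i.troop == troop and i.sex == "F" and i.mother_id is None]
        order = rng.permutation(len(females))
        for pos, idx in enumerate(order):
            latent_rank[females[idx].id] = pos + 1

    return Population(individuals, matriline, latent_rank)


# ---------------------------------------------------------------------------
# Latent propensities


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def latent_propensities(
    population: Population, config: SimulationConfig, at_date: date, troop: str
) -> PropensityModel:
    """Propensity matrices for one troop evaluated at ``at_date``."""
    members = population.by_troop(troop)
    if not members:
        raise ValueError(f"no individuals in troop {troop}")
    ids = [m.id for m in members]
    index = {iid: k for k, iid in enumerate(ids)}
    n = len(ids)
    ages = np.array([m.age_months(at_date) for m in members])
    male = np.array([m.sex == "M" for m in members])
    mat = np.array([population.matriline[m.id] for m in members])
    is_imm = np.array([m.mother_id is not None for m in members])

    # matriline-classified base propensity (applies to any pair)
    base = np.where(
        (mat[:, None] == mat[None, :]) & (mat[:, None] >= 0),
        config.within_matriline,
        config.between_matriline,
    )
    adult_male = (~is_imm) & male
    base[adult_male, :] = config.adult_male_propensity
    base[:, adult_male] = config.adult_male_propensity
    np.fill_diagonal(base, 0.0)

    # homophily kernel (rows = focal)
    dage = ages[:, None] - ages[None, :]
    kernel = np.exp(-(dage**2) / (2.0 * config.age_bandwidth**2))
    same_sex = male[:, None] == male[None, :]
    homo = (
        config.baseline
        + config.peer_affinity * kernel
        + config.same_sex_slope * ages[:, None] * same_sex
    )

    directed = base.astype(float).copy()
    w = np.zeros(n)
    attachment: dict[str, float] = {}
    for k, m in enumerate(members):
        if m.mother_id is None:
            continue
        w[k] = inheritance_weight(config, ages[k], male[k])
        mi = index[m.mother_id]
        directed[k, :] = w[k] * base[mi, :] + (1.0 - w[k]) * homo[k, :]
        attachment[m.id] = _sigmoid(config.attachment.logit(ages[k], male[k]))

    # an immature's dyads are governed by its own mixture row (immature-
    # immature dyads average the two perspectives); adult-adult dyads keep
    # the base classification. This keeps lambda0 the single inheritance
    # dial: at lambda0 = 0 an immature's row is unrelated to its mother's.
    assoc = base.astype(float).copy()
    imm = np.flatnonzero(is_imm)
    assoc[imm, :] = directed[imm, :]
    assoc[:, imm] = directed[imm, :].T
    both = np.ix_(imm, imm)
    assoc[both] = (directed[both] + directed[both].T) / 2.0
    np.fill_diagonal(assoc, 0.0)
    assoc = np.clip(assoc, 0.0, 0.95)
    # the mother-offspring cell carries the record-level attachment probability
    for k, m in enumerate(members):
        if m.mother_id is not None:
            mi = index[m.mother_id]
            assoc[k, mi] = assoc[mi, k] = attachment[m.id]

    groom = assoc.copy()
    for k, m in enumerate(members):
        if m.mother_id is not None:
            mi = index[m.mother_id]
            # odds-scale weight: share of grooming with the mother stays
            # logit-linear in age, sex and their interaction
            groom[k, mi] = groom[mi, k] = config.grooming_mother_weight * np.exp(
                config.attachment.logit(ages[k], male[k])
            )
    # grooming weight classes among adults differ from proximity ones
    scale = np.where(
        (mat[:, None] == mat[None, :]) & (mat[:, None] >= 0),
        config.grooming_adult_within / max(config.within_matriline, 1e-12),
        config.grooming_adult_between / max(config.between_matriline, 1e-12),
    )
    both_adult = (~is_imm[:, None]) & (~is_imm[None, :])
    groom = np.where(both_adult, assoc * scale, groom)
    groom[adult_male, :] *= config.grooming_adult_male / max(config.grooming_adult_between, 1e-12)
    np.fill_diagonal(groom, 0.0)
    groom = np.clip(groom, 0.0, None)

    return PropensityModel(ids, assoc, groom, attachment)


# ---------------------------------------------------------------------------
# Observation streams


def _period_starts(config: SimulationConfig, year: int, n_periods: int) -> list[date]:
    start = date(year, 6, 1)
    return [start + timedelta(days=p * config.period_days) for p in range(n_periods)]


def simulate_scans(
    population: Population,
    config: SimulationConfig,
    rng: np.random.Generator,
    propensities=None,
) -> list[ScanRecord]:
    """Scan sampling: one randomized focal-list sweep per observation day.

    Each troop member is focal at most once per sweep; a member recorded
    (as focal or neighbour) within the past hour is skipped. Neighbour j
    joins focal i's subgroup with probability ``association[i, j]``; an
    immature's mother is additionally pulled into the subgroup with the
    attachment probability (mother-offspring spatial cohesion).

    ``propensities`` optionally overrides the latent model: a callable
    ``(troop, date) -> PropensityModel``.
    """
    out: list[ScanRecord] = []
    sweeps = config.scans_per_individual_per_month
    for troop in population.troops:
        members = population.by_troop(troop)
        mother_of = {m.id: m.mother_id for m in members if m.mother_id is not None}
        for year, n_periods in config.seasons:
            for pstart in _period_starts(config, year, n_periods):
                mid = pstart + timedelta(days=config.period_days // 2)
                if propensities is not None:
                    prop = propensities(troop, mid)
                else:
                    prop = latent_propensities(population, config, mid, troop)
                index = {iid: k for k, iid in enumerate(prop.ids)}
                day_offsets = np.linspace(0, config.period_days - 1, sweeps).astype(int)
                for d in day_offsets:
                    day = pstart + timedelta(days=int(d))
                    order = rng.permutation(len(prop.ids))
                    t = datetime.combine(day, datetime.min.time()) + timedelta(hours=8)
                    last_seen: dict[str, datetime] = {}
                    for oi in order:
                        focal = prop.ids[oi]
                        if focal in last_seen and t - last_seen[focal] < _RESAMPLE_SUPPRESSION:
                            t += timedelta(minutes=_SCAN_SPACING_MIN)
                            continue
                        joins = rng.random(len(prop.ids)) < prop.association[oi]
                        joins[oi] = True
                        subgroup = {prop.ids[j] for j in np.flatnonzero(joins)}
                        # mother-offspring cohesion for immature neighbours
                        # (sorted: rng consumption independent of set order)
                        for iid in sorted(subgroup):
                            mom = mother_of.get(iid)
                            if iid != focal and mom is not None and mom not in subgroup:
                                if rng.random() < prop.attachment[iid]:
                                    subgroup.add(mom)
                        out.append(ScanRecord(t, troop, focal, frozenset(subgroup)))
                        for iid in subgroup:
                            last_seen[iid] = t
                        t += timedelta(minutes=_SCAN_SPACING_MIN)
    out.sort(key=lambda r: (r.troop, r.when, r.focal_id))
    return out


def simulate_grooming(
    population: Population,
    config: SimulationConfig,
    rng: np.random.Generator,
    propensities=None,
) -> list[GroomingRecord]:
    """Ad libitum grooming: each member initiates a Poisson number of events
    per 30-day period, recipients drawn proportionally to the directed
    grooming propensity row; a dyad is recorded at most once per half hour."""
    out: list[GroomingRecord] = []
    rate = config.grooming_events_per_individual_per_month
    for troop in population.troops:
        for year, n_periods in config.seasons:
            for pstart in _period_starts(config, year, n_periods):
                mid = pstart + timedelta(days=config.period_days // 2)
                if propensities is not None:
                    prop = propensities(troop, mid)
                else:
                    prop = latent_propensities(population, config, mid, troop)
                n = len(prop.ids)
                events = []
                for i in range(n):
                    row = prop.grooming[i]
                    total = row.sum()
                    if total <= 0:
                        continue
                    for _ in range(rng.poisson(rate)):
                        j = rng.choice(n, p=row / total)
                        day = int(rng.integers(0, config.period_days))
                        minute = int(rng.integers(0, 11 * 60))  # 07:00-18:00
                        when = datetime.combine(
                            pstart + timedelta(days=day), datetime.min.time()
                        ) + timedelta(hours=7, minutes=minute)
                        events.append((when, prop.ids[i], prop.ids[j]))
                events.sort()
                last: dict[frozenset, datetime] = {}
                for when, giver, recipient in events:
                    dyad = frozenset((giver, recipient))
                    if dyad in last and when - last[dyad] < _GROOM_DEDUP:
                        continue
                    last[dyad] = when
                    out.append(GroomingRecord(when, troop, giver, recipient))
    out.sort(key=lambda r: (r.troop, r.when, r.giver_id))
    return out


def simulate_dominance(
    population: Population, config: SimulationConfig, rng: np.random.Generator
) -> list[DominanceRecord]:
    """Ad libitum dominance interactions among adult females; the probability
    that the latently higher-ranking female wins grows with the rank gap."""
    out: list[DominanceRecord] = []
    for troop in population.troops:
        females = [
            m for m in population.by_troop(troop) if m.sex == "F" and m.mother_id is None
        ]
        if len(females) < 2:
            continue
        nf = len(females)
        # relative latent rank in [0, 1], 1 = highest
        rel = {
            f.id: 1.0 - (population.latent_rank[f.id] - 1) / (nf - 1) for f in females
        }
        n_dyads = nf * (nf - 1) // 2
        for year, n_periods in config.seasons:
            start = date(year, 6, 1)
            days = n_periods * config.period_days
            n_int = config.interactions_per_dyad * n_dyads
            for _ in range(n_int):
                i, j = rng.choice(nf, size=2, replace=False)
                a, b = females[i], females[j]
                gap = rel[a.id] - rel[b.id]
                p_a_wins = _sigmoid(config.dominance_steepness * gap) if np.isfinite(
                    config.dominance_steepness
                ) else (1.0 if gap > 0 else 0.0)
                winner, loser = (a, b) if rng.random() < p_a_wins else (b, a)
                day = int(rng.integers(0, days))
                minute = int(rng.integers(0, 11 * 60))
                when = datetime.combine(
                    start + timedelta(days=day), datetime.min.time()
                ) + timedelta(hours=7, minutes=minute)
                out.append(DominanceRecord(when, troop, winner.id, loser.id))
    out.sort(key=lambda r: (r.troop, r.when, r.giver_id))
    return out


# ---------------------------------------------------------------------------
# Full dataset


@dataclass
class SimulatedData:
    config: SimulationConfig
    population: Population
    seasons: list[Season]
    scans: list[ScanRecord]
    grooming: list[GroomingRecord]
    dominance: list[DominanceRecord]

    @property
    def individuals(self) -> list[Individual]:
        return self.population.individuals

    def ground_truth(self) -> pd.DataFrame:
        """Per-individual generator internals for recovery tests."""
        ref = reference_date(self.config)
        rows = []
        for m in self.individuals:
            age = m.age_months(ref)
            rows.append(
                dict(
                    id=m.id,
                    troop=m.troop,
                    sex=m.sex,
                    age_months=round(age, 3),
                    mother_id=m.mother_id or "",
                    matriline=self.population.matriline[m.id],
                    w=round(inheritance_weight(self.config, age, m.sex == "M"), 6)
                    if m.mother_id is not None
                    else float("nan"),
                    latent_rank=self.population.latent_rank.get(m.id, float("nan")),
                )
            )
        return pd.DataFrame(rows)


def simulate_dataset(config: SimulationConfig) -> SimulatedData:
    """Deterministically generate the full observation dataset for a config."""
    population = make_population(config)
    rng = np.random.default_rng(config.rng_seed + 1)
    scans = simulate_scans(population, config, rng)
    grooming = simulate_grooming(population, config, rng)
    dominance = simulate_dominance(population, config, rng)
    return SimulatedData(
        config, population, _season_calendar(config), scans, grooming, dominance
    )


def write_dataset(data: SimulatedData, outdir) -> None:
    from pathlib import Path

    from . import records as rec

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rec.write_scans(data.scans, outdir / "scans.csv")
    rec.write_grooming(data.grooming, outdir / "grooming.csv")
    rec.write_dominance(data.dominance, outdir / "dominance.csv")
    rec.write_individuals(data.individuals, outdir / "individuals.csv")
    rec.write_seasons(data.seasons, outdir / "seasons.csv")
    data.ground_truth().to_csv(outdir / "ground_truth.csv", index=False)
    data.config.to_yaml(outdir / "config.yaml")
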