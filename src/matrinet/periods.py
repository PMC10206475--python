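"""Sampling-period assignment and observation-count filters.

Records are aggregated into consecutive, non-overlapping 30-day windows per
(troop, network kind), anchored at the first observation date of each field
season — proximity and grooming streams therefore get different window
boundaries when their first dates differ. Periods with fewer than 95
observations are dropped, as are individuals seen fewer than five times in a
season.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, timedelta

from .config import FilterConfig
from .records import GroomingRecord, InputError, ScanRecord, Season

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamplingPeriod:
    troop: str
    network_kind: str  # "proximity" or "grooming"
    index: int  # running index within (troop, kind), over all seasons
    year: int  # season the period belongs to
    start_date: date
    end_date: date  # inclusive
    n_observations: int

    @property
    def midpoint(self) -> date:
        return self.start_date + (self.end_date - self.start_date) / 2

    def key(self) -> tuple:
        return (self.troop, self.network_kind, self.index)


def _record_kind(record) -> str:
    return "proximity" if isinstance(record, ScanRecord) else "grooming"


def assign_periods(
    records: list, seasons: list[Season], period_days: int = 30
) -> tuple[list[SamplingPeriod], dict[tuple, list]]:
    """Tag records with 30-day sampling periods.

    Returns the period list and a mapping ``period.key() -> records``. A
    record whose date falls outside every declared season for its troop is an
    input error.
    """
    if not records:
        return [], {}
    kind = _record_kind(records[0])
    by_troop_season: dict[tuple, list] = {}
    for r in records:
        day = r.when.date()
        season = next(
            (
                s
                for s in seasons
                if s.troop == r.troop and s.start_date <= day <= s.end_date
            ),
            None,
        )
        if season is None:
            raise InputError(
                f"record on {day} for troop {r.troop} falls outside all declared seasons"
            )
        by_troop_season.setdefault((r.troop, season.year), []).append(r)

    periods: list[SamplingPeriod] = []
    assignment: dict[tuple, list] = {}
    for troop in sorted({t for t, _ in by_troop_season}):
        index = 0
        for year in sorted(y for t, y in by_troop_season if t == troop):
            recs = sorted(by_troop_season[(troop, year)], key=lambda r: r.when)
            anchor = recs[0].when.date()
            buckets: dict[int, list] = {}
            for r in recs:
                k = (r.when.date() - anchor).days // period_days
                buckets.setdefault(k, []).append(r)
            for k in sorted(buckets):
                start = anchor + timedelta(days=k * period_days)
                period = SamplingPeriod(
                    troop,
                    kind,
                    index,
                    year,
                    start,
                    start + timedelta(days=period_days - 1),
                    len(buckets[k]),
                )
                periods.append(period)
                assignment[period.key()] = buckets[k]
                index += 1
    return periods, assignment


def filter_periods(
    periods: list[SamplingPeriod],
    assignment: dict[tuple, list],
    min_obs: int = FilterConfig.min_observations_per_period,
) -> tuple[list[SamplingPeriod], dict[tuple, list]]:
    """Drop periods with fewer than ``min_obs`` observations (logged)."""
    kept, kept_assignment = [], {}
    for p in periods:
        if p.n_observations >= min_obs:
            kept.append(p)
            kept_assignment[p.key()] = assignment[p.key()]
        else:
            log.info(
                "dropping period %s/%s #%d: %d < %d observations",
                p.troop,
                p.network_kind,
                p.index,
                p.n_observations,
                min_obs,
            )
    return kept, kept_assignment


def _sightings(record) -> list[str]:
    if isinstance(record, ScanRecord):
        return list(record.subgroup_ids)
    return [record.giver_id, record.recipient_id]


def filter_individuals(
    periods: list[SamplingPeriod],
    assignment: dict[tuple, list],
    min_sightings: int = FilterConfig.min_sightings_per_season,
) -> dict[tuple[str, int], set[str]]:
    """Individuals retained per (troop, season year): seen >= min_sightings
    times in that season's records. Exclusions are logged."""
    counts: dict[tuple[str, int], dict[str, int]] = {}
    for p in periods:
        season_key = (p.troop, p.year)
        tally = counts.setdefault(season_key, {})
        for r in assignment[p.key()]:
            for iid in _sightings(r):
                tally[iid] = tally.get(iid, 0) + 1
    retained: dict[tuple[str, int], set[str]] = {}
    for season_key, tally in counts.items():
        keep = {iid for iid, c in tally.items() if c >= min_sightings}
        dropped = sorted(set(tally) - keep)
        if dropped:
            log.info(
                "season %s/%s: excluding %d individuals with < %d sightings: %s",
                season_key[0],
                season_key[1],
                len(dropped),
                min_sightings,
                ", ".join(dropped),
            )
        retained[season_key] = keep
    return retained
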