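"""Typed field-observation records and their CSV schemas.

Schemas (all plain CSV, ISO timestamps):

* ``scans.csv``       — datetime, troop, focal_id, subgroup_ids (semicolon-joined,
  includes the focal; a singleton subgroup means the focal was alone)
* ``grooming.csv``    — datetime, troop, giver_id, recipient_id
* ``dominance.csv``   — datetime, troop, giver_id, recipient_id
* ``individuals.csv`` — id, sex, birth_date, mother_id, troop
* ``seasons.csv``     — troop, year, start_date, end_date
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)


class InputError(ValueError):
    """Malformed observation input (bad schema, bad rows)."""


@dataclass(frozen=True)
class ScanRecord:
    """One instantaneous proximity scan: the focal and everyone within 10 m."""

    when: datetime
    troop: str
    focal_id: str
    subgroup_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.focal_id not in self.subgroup_ids:
            raise InputError(f"focal {self.focal_id} not in its own subgroup")


@dataclass(frozen=True)
class GroomingRecord:
    """One directed grooming event (giver to recipient)."""

    when: datetime
    troop: str
    giver_id: str
    recipient_id: str

    def __post_init__(self) -> None:
        if self.giver_id == self.recipient_id:
            raise InputError(f"grooming giver == recipient ({self.giver_id})")


@dataclass(frozen=True)
class DominanceRecord:
    """One decided dominance interaction (giver displaced/supplanted recipient)."""

    when: datetime
    troop: str
    giver_id: str
    recipient_id: str

    def __post_init__(self) -> None:
        if self.giver_id == self.recipient_id:
            raise InputError(f"dominance giver == recipient ({self.giver_id})")


@dataclass(frozen=True)
class Individual:
    """Census entry for one animal."""

    id: str
    sex: str  # "F" or "M"
    birth_date: date
    mother_id: str | None
    troop: str

    def age_months(self, on: date | datetime) -> float:
        if isinstance(on, datetime):
            on = on.date()
        return (on - self.birth_date).days / 30.4375

    def is_immature(self, on: date | datetime, max_age: float = 60.0) -> bool:
        return self.age_months(on) <= max_age


@dataclass(frozen=True)
class Season:
    """One field season for one troop."""

    troop: str
    year: int
    start_date: date
    end_date: date


# ---------------------------------------------------------------------------
# CSV parsing


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")


def _parse_when(value, path, line: int) -> datetime:
    ts = pd.to_datetime(value, errors="coerce")
    if pd.isna(ts):
        raise InputError(f"{path}: line {line}: unparsable timestamp {value!r}")
    return ts.to_pydatetime()


def read_records(path: str | Path, kind: str):
    """Read observation records of one *kind* from a CSV file.

    kind is one of ``scan``, ``grooming``, ``dominance``. Malformed rows raise
    :class:`InputError` carrying the 1-based data line number.
    """
    path = Path(path)
    readers = {"scan": _read_scans, "grooming": _read_grooming, "dominance": _read_dominance}
    if kind not in readers:
        raise InputError(f"unknown record kind {kind!r}")
    return readers[kind](path)


def _read_scans(path: Path) -> list[ScanRecord]:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["datetime", "troop", "focal_id", "subgroup_ids"], path)
    if df.empty:
        log.warning("%s: no scan records", path)
        return []
    out = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        when = _parse_when(row.datetime, path, line)
        members = [m for m in str(row.subgroup_ids).split(";") if m]
        if len(set(members)) != len(members):
            members = list(dict.fromkeys(members))  # set semantics, keep order
        try:
            out.append(ScanRecord(when, str(row.troop), str(row.focal_id), frozenset(members)))
        except InputError as err:
            raise InputError(f"{path}: line {line}: {err}") from None
    return out


def _read_dyadic(path: Path, cls) -> list:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["datetime", "troop", "giver_id", "recipient_id"], path)
    if df.empty:
        log.warning("%s: no records", path)
        return []
    out = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        when = _parse_when(row.datetime, path, line)
        try:
            out.append(cls(when, str(row.troop), str(row.giver_id), str(row.recipient_id)))
        except InputError as err:
            raise InputError(f"{path}: line {line}: {err}") from None
    return out


def _read_grooming(path: Path) -> list[GroomingRecord]:
    return _read_dyadic(path, GroomingRecord)


def _read_dominance(path: Path) -> list[DominanceRecord]:
    return _read_dyadic(path, DominanceRecord)


def read_individuals(path: str | Path) -> list[Individual]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["id", "sex", "birth_date", "mother_id", "troop"], path)
    out = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        birth = pd.to_datetime(row.birth_date, errors="coerce")
        if pd.isna(birth):
            raise InputError(f"{path}: line {line}: unparsable birth_date {row.birth_date!r}")
        mother = None if pd.isna(row.mother_id) or row.mother_id in ("", "NA") else str(row.mother_id)
        out.append(Individual(str(row.id), str(row.sex), birth.date(), mother, str(row.troop)))
    return out


def read_seasons(path: str | Path) -> list[Season]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["troop", "year", "start_date", "end_date"], path)
    out = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        start = pd.to_datetime(row.start_date, errors="coerce")
        end = pd.to_datetime(row.end_date, errors="coerce")
        if pd.isna(start) or pd.isna(end):
            raise InputError(f"{path}: line {line}: unparsable season dates")
        out.append(Season(str(row.troop), int(row.year), start.date(), end.date()))
    return out


# ---------------------------------------------------------------------------
# CSV writing


def write_scans(records: list[ScanRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "datetime": [r.when.isoformat(sep=" ") for r in records],
            "troop": [r.troop for r in records],
            "focal_id": [r.focal_id for r in records],
            "subgroup_ids": [";".join(sorted(r.subgroup_ids)) for r in records],
        }
    ).to_csv(path, index=False)


def _write_dyadic(records, path) -> None:
    pd.DataFrame(
        {
            "datetime": [r.when.isoformat(sep=" ") for r in records],
            "troop": [r.troop for r in records],
            "giver_id": [r.giver_id for r in records],
            "recipient_id": [r.recipient_id for r in records],
        }
    ).to_csv(path, index=False)


write_grooming = _write_dyadic
write_dominance = _write_dyadic


def write_individuals(individuals: list[Individual], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [i.id for i in individuals],
            "sex": [i.sex for i in individuals],
            "birth_date": [i.birth_date.isoformat() for i in individuals],
            "mother_id": [i.mother_id or "" for i in individuals],
            "troop": [i.troop for i in individuals],
        }
    ).to_csv(path, index=False)


def write_seasons(seasons: list[Season], path: str | Path) -> None:
    pd.DataFrame(
        {
            "troop": [s.troop for s in seasons],
            "year": [s.year for s in seasons],
            "start_date": [s.start_date.isoformat() for s in seasons],
            "end_date": [s.end_date.isoformat() for s in seasons],
        }
    ).to_csv(path, index=False)
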