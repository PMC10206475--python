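"""Dependent variables of the ontogeny models, computed per immature and
sampling period.

* time with mother — proportion of an immature's observation records that
  include its mother (proximity: joint subgroup membership; grooming: events
  in either direction with the mother over all events involving the
  immature);
* ego-network similarity — Pearson r and cosine similarity between the
  mother's and the immature's ego vectors, aligned on identical column
  order with both dyad members' columns dropped;
* binary comparisons — 1 if the mother-immature r strictly exceeds a
  comparator's r (a random non-mother individual, or the mean over all
  non-mother individuals);
* partner-category proportions — fraction of a category (immature, peer,
  same-sex) of the troop the focal is connected to.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .config import IMMATURE_MAX_AGE_MONTHS, PEER_WINDOW_MONTHS
from .networks import ego_vector
from .records import GroomingRecord, ScanRecord

log = logging.getLogger(__name__)


@dataclass
class Proportion:
    """A k-out-of-n response."""

    k: int
    n: int

    @property
    def value(self) -> float:
        return self.k / self.n if self.n else math.nan


def time_with_mother_proximity(
    records: list[ScanRecord], immature: str, mother: str
) -> Proportion:
    """k = records whose subgroup holds both; n = records holding the immature."""
    n = k = 0
    for r in records:
        if immature in r.subgroup_ids:
            n += 1
            if mother in r.subgroup_ids:
                k += 1
    return Proportion(k, n)


def time_with_mother_grooming(
    records: list[GroomingRecord], immature: str, mother: str
) -> Proportion:
    """k = events between immature and mother (either direction);
    n = events involving the immature."""
    n = k = 0
    for r in records:
        pair = {r.giver_id, r.recipient_id}
        if immature in pair:
            n += 1
            if mother in pair:
                k += 1
    return Proportion(k, n)


def pearson_cosine(u: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """(Pearson r, cosine similarity) of two aligned ego vectors.

    Pearson is undefined (NaN) for a zero-variance vector; cosine is
    undefined only for an all-zero vector.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("ego vectors are not aligned")
    if len(u) < 3:
        raise ValueError("ego vectors must have length >= 3")
    r = math.nan
    if u.std() > 0 and v.std() > 0:
        r = float(np.corrcoef(u, v)[0, 1])
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    cos = float(u @ v / (nu * nv)) if nu > 0 and nv > 0 else math.nan
    return r, cos


def ego_similarity(
    ids: list[str], weights: np.ndarray, immature: str, other: str
) -> tuple[float, float]:
    """Similarity between two individuals' ego vectors with both members'
    columns dropped (the self column is structurally zero and the dyad edge
    sits at different positions in the two rows)."""
    drop = {immature, other}
    u, cols_u = ego_vector(weights, ids, immature, drop)
    v, cols_v = ego_vector(weights, ids, other, drop)
    assert cols_u == cols_v
    return pearson_cosine(u, v)


def mother_offspring_similarity(
    ids: list[str], weights: np.ndarray, immature: str, mother: str
) -> tuple[float, float]:
    return ego_similarity(ids, weights, immature, mother)


def _eligible_comparators(ids: list[str], immature: str, mother: str) -> list[str]:
    return [i for i in ids if i not in (immature, mother)]


def compare_vs_random(
    ids: list[str],
    weights: np.ndarray,
    immature: str,
    mother: str,
    rng: np.random.Generator,
) -> tuple[int, str] | None:
    """1 if r(mother) strictly exceeds r(random non-mother comparator).

    Ties score 0. Returns (score, comparator id); None when no eligible
    comparator exists or a correlation is undefined.
    """
    pool = _eligible_comparators(ids, immature, mother)
    if not pool:
        return None
    comparator = pool[int(rng.integers(len(pool)))]
    r_mother, _ = ego_similarity(ids, weights, immature, mother)
    r_comp, _ = ego_similarity(ids, weights, immature, comparator)
    if math.isnan(r_mother) or math.isnan(r_comp):
        return None
    return int(r_mother > r_comp), comparator


def compare_vs_mean(
    ids: list[str], weights: np.ndarray, immature: str, mother: str
) -> tuple[int, float] | None:
    """1 if r(mother) strictly exceeds the mean r over all non-mother
    individuals. Returns (score, mean r)."""
    pool = _eligible_comparators(ids, immature, mother)
    r_mother, _ = ego_similarity(ids, weights, immature, mother)
    if math.isnan(r_mother) or not pool:
        return None
    rs = []
    for comparator in pool:
        r, _ = ego_similarity(ids, weights, immature, comparator)
        if not math.isnan(r):
            rs.append(r)
    if not rs:
        return None
    mean_r = float(np.mean(rs))
    return int(r_mother > mean_r), mean_r


# ---------------------------------------------------------------------------
# Partner-category proportions


def in_category(
    category: str,
    partner_age: float,
    partner_sex: str,
    focal_age: float,
    focal_sex: str,
) -> bool:
    if category == "immature":
        return partner_age <= IMMATURE_MAX_AGE_MONTHS
    if category == "peer":
        return abs(partner_age - focal_age) <= PEER_WINDOW_MONTHS  # inclusive bound
    if category == "same_sex":
        return partner_sex == focal_sex
    raise ValueError(f"unknown partner category {category!r}")


def partner_category_proportion(
    ids: list[str],
    weights: np.ndarray,
    focal: str,
    category: str,
    ages: dict[str, float],
    sexes: dict[str, str],
    direction: str = "either",
) -> Proportion | None:
    """k = distinct category members with a nonzero edge to the focal,
    n = category members in the troop-period (focal excluded). ``direction``
    is out / in / either for directed grooming matrices. None when n = 0."""
    if focal not in ids:
        raise KeyError(f"{focal} not in matrix")
    w = np.asarray(weights, dtype=float)
    fi = ids.index(focal)
    if direction == "out":
        edges = w[fi, :]
    elif direction == "in":
        edges = w[:, fi]
    elif direction == "either":
        edges = w[fi, :] + w[:, fi]
    else:
        raise ValueError(f"unknown direction {direction!r}")
    k = n = 0
    for j, iid in enumerate(ids):
        if iid == focal:
            continue
        if in_category(category, ages[iid], sexes[iid], ages[focal], sexes[focal]):
            n += 1
            if edges[j] > 0:
                k += 1
    if n == 0:
        log.debug("category %s empty for %s", category, focal)
        return None
    return Proportion(k, n)
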