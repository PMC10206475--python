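"""Group-by-individual matrices, simple-ratio-index association networks and
directed grooming networks, built per troop-period.

The simple ratio index for a dyad (A, B) is ``x / (x + yA + yB)`` where x is
the number of sampled subgroups containing both and yA (yB) the number
containing only A (only B): the fraction of sampled subgroups containing
either member in which both were present. "Alone" records are genuine
observations of non-association and contribute to the y terms. A dyad whose
denominator is zero carries no information; its index is stored as 0 with a
mask flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .periods import SamplingPeriod
from .records import GroomingRecord, ScanRecord


class LookupError_(KeyError):
    pass


@dataclass
class GroupByIndividualMatrix:
    """Binary subgroups x individuals matrix for one troop-period."""

    period: SamplingPeriod
    ids: list[str]  # fixed column order
    matrix: np.ndarray  # (n_subgroups, n_individuals) of 0/1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.ids):
            raise ValueError("GBI shape does not match id list")
        if self.matrix.size and self.matrix.sum(axis=1).min() < 1:
            raise ValueError("every subgroup row must contain at least one individual")


@dataclass
class AssociationMatrix:
    """Symmetric SRI weights in [0, 1]; mask marks never-observed dyads."""

    period: SamplingPeriod
    ids: list[str]
    weights: np.ndarray
    undefined: np.ndarray = field(default=None)  # boolean mask, True = no information

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.allclose(w, w.T):
            raise ValueError("association matrix must be symmetric")
        if w.size and (w.min() < 0 or w.max() > 1 + 1e-12):
            raise ValueError("SRI weights must lie in [0, 1]")
        self.weights = w
        if self.undefined is None:
            self.undefined = np.zeros_like(w, dtype=bool)


@dataclass
class GroomingMatrix:
    """Directed grooming network: counts or row proportions.

    ``mode`` is given / received / total; ``values`` holds counts unless
    ``proportion`` is set, in which case rows are normalized (all-zero rows
    stay zero rather than becoming NaN).
    """

    period: SamplingPeriod
    ids: list[str]
    mode: str
    values: np.ndarray
    proportion: bool = False


def gbi_matrix(records: list[ScanRecord], period: SamplingPeriod, ids: list[str] | None = None) -> GroupByIndividualMatrix:
    """One row per recorded subgroup (singletons included), restricted to
    ``ids`` when given (rows emptied by the restriction are dropped)."""
    if not records:
        raise ValueError(f"no scan records in period {period.key()}")
    if ids is None:
        ids = sorted({m for r in records for m in r.subgroup_ids})
    col = {iid: k for k, iid in enumerate(ids)}
    rows = []
    for r in records:
        row = np.zeros(len(ids), dtype=np.int8)
        hit = False
        for m in r.subgroup_ids:
            if m in col:
                row[col[m]] = 1
                hit = True
        if hit:
            rows.append(row)
    if not rows:
        raise ValueError(f"period {period.key()}: no subgroups left after id restriction")
    return GroupByIndividualMatrix(period, list(ids), np.array(rows))


def sri_matrix(gbi: GroupByIndividualMatrix) -> AssociationMatrix:
    """Simple ratio index for every dyad of the GBI."""
    b = gbi.matrix.astype(np.int64)
    x = b.T @ b  # co-occurrence counts; diagonal = per-individual sightings
    n = np.diag(x)
    denom = n[:, None] + n[None, :] - x
    undefined = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        sri = np.where(undefined, 0.0, x / np.where(undefined, 1, denom))
    np.fill_diagonal(sri, 0.0)
    np.fill_diagonal(undefined, False)
    return AssociationMatrix(gbi.period, gbi.ids, sri, undefined)


def grooming_matrices(
    records: list[GroomingRecord],
    period: SamplingPeriod,
    mode: str = "given",
    ids: list[str] | None = None,
    proportion: bool = False,
) -> GroomingMatrix:
    """Directed grooming count matrix for one troop-period.

    given:    entry (i, j) = number of events i -> j
    received: transpose of given
    total:    given + given^T (symmetric counts)
    """
    if mode not in ("given", "received", "total"):
        raise ValueError(f"unknown grooming mode {mode!r}")
    if ids is None:
        ids = sorted({x for r in records for x in (r.giver_id, r.recipient_id)})
    col = {iid: k for k, iid in enumerate(ids)}
    given = np.zeros((len(ids), len(ids)), dtype=float)
    for r in records:
        if r.giver_id in col and r.recipient_id in col:
            given[col[r.giver_id], col[r.recipient_id]] += 1
    values = {"given": given, "received": given.T.copy(), "total": given + given.T}[mode]
    if proportion:
        sums = values.sum(axis=1, keepdims=True)
        values = np.divide(values, sums, out=np.zeros_like(values), where=sums > 0)
    return GroomingMatrix(period, list(ids), mode, values, proportion)


def ego_vector(
    weights: np.ndarray, ids: list[str], ego: str, drop_ids: set[str] | list[str] = ()
) -> tuple[np.ndarray, list[str]]:
    """The ego's row with the columns in ``drop_ids`` removed, plus the kept
    column order (so two ego vectors built with the same drops align)."""
    if ego not in ids:
        raise LookupError_(f"{ego} not in matrix")
    drop = set(drop_ids)
    keep = [k for k, iid in enumerate(ids) if iid not in drop]
    row = np.asarray(weights)[ids.index(ego), keep]
    return row, [ids[k] for k in keep]


# ---------------------------------------------------------------------------
# Export


def to_edge_list(ids: list[str], weights: np.ndarray, kind: str, mode: str = "") -> pd.DataFrame:
    """Edge-list with nonzero weights; undirected half for symmetric input."""
    w = np.asarray(weights)
    symmetric = np.allclose(w, w.T)
    rows = []
    for i in range(len(ids)):
        for j in range(len(ids)):
            if i == j or w[i, j] == 0:
                continue
            if symmetric and j < i:
                continue
            rows.append((ids[i], ids[j], w[i, j], kind, mode))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "weight", "kind", "mode"])


def to_graph(ids: list[str], weights: np.ndarray) -> nx.Graph:
    w = np.asarray(weights)
    directed = not np.allclose(w, w.T)
    g = nx.DiGraph() if directed else nx.Graph()
    g.add_nodes_from(ids)
    for i in range(len(ids)):
        for j in range(len(ids)):
            if i == j or w[i, j] == 0 or (not directed and j < i):
                continue
            g.add_edge(ids[i], ids[j], weight=float(w[i, j]))
    return g


def write_graphml(ids: list[str], weights: np.ndarray, path) -> None:
    nx.write_graphml(to_graph(ids, weights), path)
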