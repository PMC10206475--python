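"""Adult-female dominance ranking by the I&SI method.

The I&SI criterion seeks the linear order minimizing first the number of
inconsistencies I — dyads in which the individual ranked lower won more
interactions — and then their total strength SI, the summed rank distances of
the inconsistent dyads (de Vries 1998). Tied dyads (equal nonzero wins both
ways) and unknown dyads (no interactions) contribute to neither I nor SI.

Exact search is infeasible beyond ~10 individuals, so the optimum is found by
seed-controlled random-restart hill climbing over pairwise position swaps;
exhaustive-search tests pin correctness at small n.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import DominanceRecord


@dataclass
class DominanceMatrix:
    ids: list[str]
    wins: np.ndarray  # wins[i, j] = interactions i won over j

    def __post_init__(self) -> None:
        w = np.asarray(self.wins)
        if w.shape != (len(self.ids), len(self.ids)):
            raise ValueError("wins matrix shape does not match ids")
        if np.any(np.diag(w) != 0) or np.any(w < 0):
            raise ValueError("wins must be non-negative with zero diagonal")
        self.wins = w.astype(np.int64)


def dominance_matrix(records: list[DominanceRecord], ids: list[str] | None = None) -> DominanceMatrix:
    if ids is None:
        ids = sorted({x for r in records for x in (r.giver_id, r.recipient_id)})
    col = {iid: k for k, iid in enumerate(ids)}
    wins = np.zeros((len(ids), len(ids)), dtype=np.int64)
    for r in records:
        if r.giver_id in col and r.recipient_id in col:
            wins[col[r.giver_id], col[r.recipient_id]] += 1
    return DominanceMatrix(list(ids), wins)


def _objective(wins: np.ndarray, order: np.ndarray) -> tuple[int, int]:
    """(I, SI) of an ordering given as an array of matrix indices, best first."""
    return _objective_dom(wins > wins.T, order)


def _objective_dom(dom: np.ndarray, order: np.ndarray) -> tuple[int, int]:
    # dom[a, b] True iff a won strictly more than b; ties and 0-0 are neutral
    pos = np.empty(len(order), dtype=np.int64)
    pos[order] = np.arange(len(order))
    dist = pos[:, None] - pos[None, :]
    incon = dom & (dist > 0)  # dominant placed below its subordinate
    return int(incon.sum()), int(dist[incon].sum())


def isi_order(
    dom: DominanceMatrix, max_restarts: int = 50, seed: int = 0
) -> tuple[list[str], tuple[int, int]]:
    """Best ordering (ids, best first) and its (I, SI).

    Random-restart local search: from each shuffled start, repeatedly apply
    the best-improving pairwise position swap until none improves.
    """
    n = len(dom.ids)
    if n < 2:
        raise ValueError("need at least 2 individuals to rank")
    if dom.wins.sum() == 0:
        raise ValueError("all-zero dominance matrix: ordering undefined")
    rng = np.random.default_rng(seed)
    wins = dom.wins
    dominance = wins > wins.T
    best_order, best_score = None, None
    for restart in range(max_restarts):
        order = rng.permutation(n) if restart else _initial_order(wins)
        score = _objective_dom(dominance, order)
        improved = True
        while improved:
            improved = False
            cand_best, cand_score = None, score
            for a in range(n):
                for b in range(a + 1, n):
                    trial = order.copy()
                    trial[a], trial[b] = trial[b], trial[a]
                    s = _objective_dom(dominance, trial)
                    if s < cand_score:
                        cand_best, cand_score = trial, s
            if cand_best is not None:
                order, score = cand_best, cand_score
                improved = True
        if best_score is None or score < best_score:
            best_order, best_score = order, score
        if best_score == (0, 0):
            break
    return [dom.ids[k] for k in best_order], best_score


def _initial_order(wins: np.ndarray) -> np.ndarray:
    """Start from David's-score order: a good linear seed for the search."""
    totals = wins + wins.T
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(totals > 0, wins / np.where(totals > 0, totals, 1), 0.0)
    w1 = p.sum(axis=1)
    l1 = p.sum(axis=0)
    ds = w1 + p @ w1 - l1 - p.T @ l1
    return np.argsort(-ds, kind="stable")


def isi_exhaustive(dom: DominanceMatrix) -> tuple[list[str], tuple[int, int]]:
    """Exact minimum over all orderings; oracle for small n only."""
    n = len(dom.ids)
    best, best_score = None, None
    for perm in itertools.permutations(range(n)):
        s = _objective(dom.wins, np.array(perm))
        if best_score is None or s < best_score:
            best, best_score = perm, s
    return [dom.ids[k] for k in best], best_score


def standardize_rank(r: int, n: int) -> float:
    """Relative rank 1 - [(1 - r) / (1 - n)]: 1 = highest, 0 = lowest."""
    if n < 2:
        raise ValueError("group size must be >= 2")
    if not 1 <= r <= n:
        raise ValueError(f"ordinal rank {r} outside 1..{n}")
    return 1.0 - (1.0 - r) / (1.0 - n)


def rank_table(ordered_ids: list[str], troop: str = "", season: int | None = None) -> pd.DataFrame:
    """Ordinal and relative ranks for an I&SI ordering (best first)."""
    n = len(ordered_ids)
    return pd.DataFrame(
        {
            "troop": troop,
            "season": season,
            "id": ordered_ids,
            "ordinal_rank": np.arange(1, n + 1),
            "relative_rank": [standardize_rank(r, n) for r in range(1, n + 1)],
        }
    )
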