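"""Null-model network permutations.

Two procedures, following the standard animal-social-network practice:

* **datastream** — chained checkerboard swaps of the group-by-individual
  matrix: find rows (g, h) and columns (i, j) with pattern [[1,0],[0,1]] and
  flip it to [[0,1],[1,0]]. Subgroup sizes (row sums) and individual sighting
  counts (column sums) are conserved exactly. Each chain step performs a
  fixed number of successful swaps; the chain runs for ``total`` steps, the
  first ``burn_in`` states are discarded and the remaining states are
  converted to SRI matrices.

* **node** — joint random relabeling of a network's rows and columns,
  composed sequentially along the chain. Entry multisets are conserved; the
  association between node attributes (which stay with matrix positions) and
  network structure is broken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PermutationSchedule
from .networks import AssociationMatrix, GroupByIndividualMatrix, sri_matrix
from .periods import SamplingPeriod


class SwapExhaustedError(RuntimeError):
    """No swappable checkerboard submatrix found within the attempt budget."""


@dataclass
class PermutedSet:
    period: SamplingPeriod
    method: str
    matrices: list[np.ndarray]  # kept null weight matrices
    chain_indices: list[int]  # position of each kept state along the chain
    ids: list[str]


def datastream_swap_step(
    gbi: np.ndarray, n_swaps: int, rng: np.random.Generator, max_attempts: int = 200_000
) -> np.ndarray:
    """Perform ``n_swaps`` successful checkerboard flips on a copy of ``gbi``."""
    b = np.asarray(gbi)
    if b.ndim != 2 or b.shape[0] < 2 or b.shape[1] < 2:
        raise ValueError("GBI must have at least 2 rows and 2 columns")
    b = b.copy()
    n_rows, _ = b.shape
    done = 0
    attempts = 0
    while done < n_swaps:
        if attempts >= max_attempts:
            raise SwapExhaustedError(
                f"only {done}/{n_swaps} swaps found after {attempts} attempts"
            )
        attempts += 1
        g, h = rng.integers(0, n_rows, size=2)
        if g == h:
            continue
        rg, rh = b[g], b[h]
        c10 = np.flatnonzero((rg == 1) & (rh == 0))
        c01 = np.flatnonzero((rg == 0) & (rh == 1))
        if len(c10) == 0 or len(c01) == 0:
            continue
        i = c10[rng.integers(len(c10))]
        j = c01[rng.integers(len(c01))]
        b[g, i], b[g, j] = 0, 1
        b[h, i], b[h, j] = 1, 0
        done += 1
    return b


def datastream_chain(
    gbi: GroupByIndividualMatrix, schedule: PermutationSchedule, rng: np.random.Generator
) -> PermutedSet:
    """Chained datastream permutation: each step re-permutes the previous
    state; kept states are returned as SRI matrices."""
    if schedule.method != "datastream":
        raise ValueError("schedule method must be 'datastream'")
    state = gbi.matrix
    kept: list[np.ndarray] = []
    indices: list[int] = []
    for step in range(1, schedule.total + 1):
        state = datastream_swap_step(state, schedule.swaps_per_step, rng)
        if step > schedule.burn_in:
            null_gbi = GroupByIndividualMatrix(gbi.period, gbi.ids, state)
            kept.append(sri_matrix(null_gbi).weights)
            indices.append(step)
    return PermutedSet(gbi.period, "datastream", kept, indices, gbi.ids)


def node_permute(
    matrix: np.ndarray, rng: np.random.Generator | None = None, pi: np.ndarray | None = None
) -> np.ndarray:
    """One joint row+column relabeling: entry (i, j) moves to (pi(i), pi(j)).

    ``pi`` fixes the permutation explicitly; otherwise it is drawn from rng.
    """
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("node permutation requires a square matrix")
    if pi is None:
        if rng is None:
            raise ValueError("either rng or pi must be given")
        pi = rng.permutation(m.shape[0])
    pi = np.asarray(pi)
    out = np.empty_like(m)
    out[np.ix_(pi, pi)] = m
    return out


def node_chain(
    matrix: np.ndarray,
    period: SamplingPeriod,
    ids: list[str],
    schedule: PermutationSchedule,
    rng: np.random.Generator,
) -> PermutedSet:
    """Sequentially composed relabelings; the last ``keep`` states are kept.

    Composition of uniform permutations is itself uniform; the chain layout
    is retained for procedural fidelity with the datastream variant.
    """
    if schedule.method != "node":
        raise ValueError("schedule method must be 'node'")
    state = np.asarray(matrix)
    kept: list[np.ndarray] = []
    indices: list[int] = []
    for step in range(1, schedule.total + 1):
        state = node_permute(state, rng)
        if step > schedule.burn_in:
            kept.append(state.copy())
            indices.append(step)
    return PermutedSet(period, "node", kept, indices, list(ids))


def permuted_sets_for_periods(
    observed: dict[tuple, tuple[list[str], np.ndarray]],
    gbis: dict[tuple, GroupByIndividualMatrix],
    periods: dict[tuple, SamplingPeriod],
    schedule: PermutationSchedule,
    seed: int,
) -> dict[tuple, PermutedSet]:
    """One permutation chain per period, with per-period child seeds.

    ``observed`` maps period key -> (ids, weight matrix); for the datastream
    method ``gbis`` must hold the period's group-by-individual matrix.
    Chain state k across all periods assembles whole-dataset null replicate k.
    """
    out: dict[tuple, PermutedSet] = {}
    root = np.random.SeedSequence(seed)
    for key in sorted(observed):
        child = np.random.default_rng(root.spawn(1)[0])
        if schedule.method == "datastream":
            out[key] = datastream_chain(gbis[key], schedule, child)
        else:
            ids, weights = observed[key]
            out[key] = node_chain(weights, periods[key], ids, schedule, child)
    return out
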