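"""Brute-force oracles, deliberately independent of the implementation paths
they check."""

from __future__ import annotations

import itertools

import numpy as np


def sri_recount(subgroups: list[set[str]], a: str, b: str) -> float | None:
    """SRI by direct recount over subgroup lists; None when undefined."""
    x = sum(1 for s in subgroups if a in s and b in s)
    ya = sum(1 for s in subgroups if a in s and b not in s)
    yb = sum(1 for s in subgroups if b in s and a not in s)
    denom = x + ya + yb
    return None if denom == 0 else x / denom


def leading_eigenvector(weights: np.ndarray) -> np.ndarray:
    """Dense symmetric eigendecomposition, rescaled to max = 1."""
    vals, vecs = np.linalg.eigh(weights)
    v = np.abs(vecs[:, np.argmax(vals)])
    return v / v.max()


def betweenness_enumeration(weights: np.ndarray) -> np.ndarray:
    """Betweenness by exhaustive enumeration of simple paths (weights as
    costs, fractional split over equal-cost shortest paths)."""
    n = weights.shape[0]
    out = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        best_cost, best_paths = None, []
        stack = [([s], 0.0)]
        while stack:
            path, cost = stack.pop()
            u = path[-1]
            if best_cost is not None and cost > best_cost + 1e-12:
                continue
            if u == t:
                if best_cost is None or cost < best_cost - 1e-12:
                    best_cost, best_paths = cost, [path]
                elif abs(cost - best_cost) <= 1e-12:
                    best_paths.append(path)
                continue
            for v in range(n):
                if weights[u, v] > 0 and v not in path:
                    stack.append((path + [v], cost + weights[u, v]))
        if not best_paths:
            continue
        for path in best_paths:
            for v in path[1:-1]:
                out[v] += 1.0 / len(best_paths)
    return out


def isi_objective(wins: np.ndarray, order: tuple[int, ...]) -> tuple[int, int]:
    """(I, SI) of one ordering, computed pair by pair."""
    pos = {idx: p for p, idx in enumerate(order)}
    n = len(order)
    i_count = si = 0
    for a in range(n):
        for b in range(a + 1, n):
            if wins[a, b] == wins[b, a]:
                continue
            dom, sub = (a, b) if wins[a, b] > wins[b, a] else (b, a)
            if pos[dom] > pos[sub]:
                i_count += 1
                si += pos[dom] - pos[sub]
    return i_count, si


def isi_exhaustive_min(wins: np.ndarray) -> tuple[int, int]:
    return min(
        isi_objective(wins, perm)
        for perm in itertools.permutations(range(wins.shape[0]))
    )


def random_gbi(rng: np.random.Generator, n_rows: int, n_cols: int, density: float = 0.25) -> np.ndarray:
    """Random 0/1 GBI with every row non-empty."""
    b = (rng.random((n_rows, n_cols)) < density).astype(np.int8)
    for i in range(n_rows):
        if b[i].sum() == 0:
            b[i, rng.integers(n_cols)] = 1
    return b
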