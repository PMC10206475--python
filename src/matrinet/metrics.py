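"""Node-level network metrics, their variance-stabilizing transforms and
within-period standardization.

Metric naming: ``strength_prox``, ``strength_groom_given`` / ``_received`` /
``_total``, ``eigencent_prox``, ``eigencent_groom_total``,
``betweenness_prox``, ``betweenness_groom_total``. Directed grooming is
collapsed to symmetric totals for eigenvector and betweenness centrality
(the in/out components cannot be separated for these metrics).

Betweenness follows the Brandes algorithm with edge weights treated as path
*costs* by default — the convention of the graph library this replicates —
with an ``inverse_weights`` option for the biologically intuitive reading
(strong edges = short paths). Masked (undefined-SRI) edges are weight 0
throughout.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

EIGEN_TOL = 1e-10

#: metric name -> elementwise transform applied before standardization
TRANSFORMS: dict[str, str] = {
    "strength_prox": "identity",
    "strength_groom_given": "log1p",
    "strength_groom_received": "identity",
    "strength_groom_total": "identity",
    "eigencent_prox": "identity",
    "eigencent_groom_total": "sqrt",
    "betweenness_prox": "log1p",
    "betweenness_groom_total": "sqrt",
}


def strength(weights: np.ndarray, mode: str = "undirected") -> np.ndarray:
    """Sum of incident edge weights: undirected / out / in / total."""
    w = np.asarray(weights, dtype=float)
    if mode == "undirected":
        return w.sum(axis=1)
    if mode == "out":
        return w.sum(axis=1)
    if mode == "in":
        return w.sum(axis=0)
    if mode == "total":
        return w.sum(axis=1) + w.sum(axis=0)
    raise ValueError(f"unknown strength mode {mode!r}")


def eigenvector_centrality(weights: np.ndarray, tol: float = EIGEN_TOL, max_iter: int = 10_000) -> np.ndarray:
    """Leading eigenvector by power iteration, rescaled to max = 1.

    Directed input is symmetrized first. On a disconnected graph the result
    concentrates on the dominant component (others decay towards 0); this is
    logged rather than treated as an error.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0 or not np.any(w):
        raise ValueError("eigenvector centrality undefined for an all-zero matrix")
    if not np.allclose(w, w.T):
        w = w + w.T
    n_components = _n_components(w)
    if n_components > 1:
        log.info("eigenvector centrality on a graph with %d components", n_components)
    # diagonal shift: breaks the +/-lambda tie on bipartite graphs without
    # changing eigenvectors
    shift = w.sum(axis=1).max()
    ws = w + shift * np.eye(w.shape[0])
    v = np.full(w.shape[0], 1.0 / np.sqrt(w.shape[0]))
    for _ in range(max_iter):
        nxt = ws @ v
        norm = np.linalg.norm(nxt)
        if norm == 0:
            break
        nxt /= norm
        if np.linalg.norm(nxt - v) < tol:
            v = nxt
            break
        v = nxt
    v = np.abs(v)
    return v / v.max()


def _n_components(w: np.ndarray) -> int:
    from scipy.sparse.csgraph import connected_components

    n, _ = connected_components((w != 0).astype(np.int8), directed=False)
    return n


def betweenness(weights: np.ndarray, weight_handling: str = "weights_as_costs") -> np.ndarray:
    """Fractional count of weighted shortest paths through each node."""
    w = np.asarray(weights, dtype=float)
    if not np.allclose(w, w.T):
        w = w + w.T
    if weight_handling == "weights_as_costs":
        cost = w
    elif weight_handling == "inverse_weights":
        with np.errstate(divide="ignore"):
            cost = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    else:
        raise ValueError(f"unknown weight handling {weight_handling!r}")
    g = nx.Graph()
    n = w.shape[0]
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if cost[i, j] > 0:
                g.add_edge(i, j, weight=float(cost[i, j]))
    bc = nx.betweenness_centrality(g, weight="weight", normalized=False)
    return np.array([bc[i] for i in range(n)])


def transform(values: np.ndarray, kind: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if kind == "identity":
        return values.copy()
    if kind == "log1p":
        return np.log1p(values)
    if kind == "sqrt":
        if np.any(values < 0):
            raise ValueError("sqrt transform requires non-negative values")
        return np.sqrt(values)
    raise ValueError(f"unknown transform {kind!r}")


def transform_for(metric: str) -> str:
    try:
        return TRANSFORMS[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}") from None


def standardize_within_period(values: np.ndarray) -> np.ndarray:
    """Z-scores (sample sd) within one period; constant input -> zeros."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return np.zeros_like(values)
    sd = values.std(ddof=1)
    if sd == 0:
        log.warning("zero variance within period: standardized values set to 0")
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def metric_values(metric: str, weights: np.ndarray) -> np.ndarray:
    """Raw value of a named metric on one period's weight matrix."""
    if metric.startswith("strength_groom_"):
        mode = {"given": "out", "received": "in", "total": "total"}[metric.rsplit("_", 1)[1]]
        return strength(weights, mode)
    if metric == "strength_prox":
        return strength(weights, "undirected")
    if metric.startswith("eigencent"):
        return eigenvector_centrality(weights)
    if metric.startswith("betweenness"):
        return betweenness(weights)
    raise ValueError(f"unknown metric {metric!r}")


def metric_table(metric: str, ids: list[str], weights: np.ndarray) -> pd.DataFrame:
    """raw -> transformed -> standardized values for one troop-period."""
    raw = metric_values(metric, weights)
    trans = transform(raw, transform_for(metric))
    std = standardize_within_period(trans)
    return pd.DataFrame(
        {"id": ids, "metric": metric, "raw": raw, "transformed": trans, "standardized": std}
    )
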