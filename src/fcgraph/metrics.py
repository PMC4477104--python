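"""Weighted global and nodal graph metrics, null normalisation, AUC.

All metrics operate on :class:`~fcgraph.connectivity.ThresholdedNetwork`
objects whose weights lie in (0, 1]. Distances between nodes use edge
lengths ``1/weight`` (the dominant convention for functional connectomes).

Global metrics: clustering coefficient C_p, characteristic path length L_p,
their null-normalised ratios gamma and lambda (against degree-preserving
rewired networks), small-worldness sigma = gamma/lambda, and global/local
efficiency. Nodal metrics: binary degree, nodal efficiency, betweenness.
A trapezoid AUC over the sparsity grid condenses each metric curve into a
threshold-independent scalar per subject.

Conventions recorded here once:

* Weighted clustering is the geometric-mean (Onnela) formulation by
  default; the arithmetic (Barrat) variant is available via ``variant``.
* L_p on a disconnected graph is the mean over *reachable* pairs only;
  the efficiency metrics handle disconnection natively via 1/inf = 0.
* Degree is the binary edge count, not strength.
* Betweenness uses fractional counting over tied shortest paths, endpoints
  excluded, unnormalised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import networkx as nx
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .connectivity import ThresholdedNetwork
from ._seeds import child_rng

__all__ = [
    "clustering_coefficient",
    "shortest_path_lengths",
    "characteristic_path_length",
    "global_efficiency",
    "nodal_efficiency",
    "local_efficiency",
    "betweenness",
    "degree",
    "rewire_null",
    "small_world_indices",
    "SmallWorldIndices",
    "auc",
    "GLOBAL_METRICS",
    "NODAL_METRICS",
    "global_metrics_record",
    "nodal_metrics_record",
]

GLOBAL_METRICS = ("c_p", "l_p", "gamma", "lambda", "sigma", "e_glob", "e_loc")
NODAL_METRICS = ("degree", "efficiency", "betweenness")


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def clustering_coefficient(net: ThresholdedNetwork, variant: str = "onnela"
                           ) -> tuple[np.ndarray, float]:
    """Weighted per-node clustering and its mean C_p.

    Onnela variant: C_i = (W_hat^{1/3})^3_{ii} / (k_i (k_i - 1)) with
    W_hat = W / max(W); nodes with binary degree < 2 get 0. The Barrat
    variant averages arithmetic-mean edge weights over closed triangles.
    """
    w = net.weights
    n = w.shape[0]
    a = (w > 0)
    k = a.sum(axis=1)
    denom = k * (k - 1)
    valid = denom > 0
    out = np.zeros(n)
    if not np.any(a):
        return out, 0.0
    if variant == "onnela":
        w_hat = w / w.max()
        cube = np.linalg.matrix_power(np.cbrt(w_hat), 3)
        out[valid] = np.diag(cube)[valid] / denom[valid]
    elif variant == "barrat":
        s = w.sum(axis=1)
        af = a.astype(float)
        # Barrat: C_i = 1/(s_i (k_i-1)) * sum_{j,h} (w_ij + w_ih)/2 a_ij a_ih a_jh
        num = np.einsum("ij,ih,jh->i", w, af, af) + \
            np.einsum("ij,ih,jh->i", af, w, af)
        valid_b = (s > 0) & (k > 1)
        out[valid_b] = num[valid_b] / (2 * s[valid_b] * (k[valid_b] - 1))
    else:
        raise ValueError(f"unknown clustering variant {variant!r}")
    return out, float(out.mean())


# ---------------------------------------------------------------------------
# distances and efficiencies
# ---------------------------------------------------------------------------

def shortest_path_lengths(net: ThresholdedNetwork) -> np.ndarray:
    """All-pairs shortest-path distances with edge length 1/weight.

    Unreachable pairs get +inf; the diagonal is 0.
    """
    w = net.weights
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    return dijkstra(csr_matrix(lengths), directed=False)


def characteristic_path_length(net: ThresholdedNetwork,
                               dist: np.ndarray | None = None) -> float:
    """Mean shortest-path distance over reachable off-diagonal pairs."""
    d = shortest_path_lengths(net) if dist is None else dist
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        return float("inf")
    return float(d[finite].mean())


def global_efficiency(net: ThresholdedNetwork,
                      dist: np.ndarray | None = None) -> float:
    """Mean inverse distance over all off-diagonal pairs (1/inf = 0)."""
    d = shortest_path_lengths(net) if dist is None else dist
    n = d.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiency(net: ThresholdedNetwork,
                     dist: np.ndarray | None = None) -> np.ndarray:
    """Per-node mean inverse distance to every other node."""
    d = shortest_path_lengths(net) if dist is None else dist
    n = d.shape[0]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return inv.sum(axis=1) / (n - 1)


def local_efficiency(net: ThresholdedNetwork) -> float:
    """Mean over nodes of the global efficiency of each neighbourhood.

    The neighbourhood subgraph of node i contains i's neighbours (i itself
    removed) with their mutual edges; nodes with fewer than two neighbours
    contribute 0.
    """
    w = net.weights
    n = w.shape[0]
    vals = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(w[i] > 0)
        if nb.size < 2:
            continue
        sub = ThresholdedNetwork(w[np.ix_(nb, nb)], net.sparsity, 0)
        vals[i] = global_efficiency(sub)
    return float(vals.mean())


def betweenness(net: ThresholdedNetwork) -> np.ndarray:
    """Weighted shortest-path betweenness (unnormalised, endpoints excluded).

    Shortest paths use edge length 1/weight; tied shortest paths are counted
    fractionally (Brandes accumulation).
    """
    g = nx.Graph()
    n = net.n_nodes
    g.add_nodes_from(range(n))
    for i, j, w in net.edges():
        g.add_edge(i, j, length=1.0 / w)
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return np.array([bc[i] for i in range(n)])


def degree(net: ThresholdedNetwork) -> np.ndarray:
    """Binary degree: number of incident edges per node."""
    return (net.weights > 0).sum(axis=1).astype(int)


# ---------------------------------------------------------------------------
# degree-preserving null model
# ---------------------------------------------------------------------------

@njit(cache=True)
def _swap_kernel(eu, ev, adj, n_target, max_attempts, seed):  # pragma: no cover
    np.random.seed(seed)
    m = eu.shape[0]
    successes = 0
    attempts = 0
    while successes < n_target and attempts < max_attempts:
        attempts += 1
        e1 = np.random.randint(m)
        e2 = np.random.randint(m)
        if e1 == e2:
            continue
        a, b = eu[e1], ev[e1]
        c, d = eu[e2], ev[e2]
        if np.random.randint(2) == 1:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        eu[e1], ev[e1] = a, d
        eu[e2], ev[e2] = c, b
        successes += 1
    return successes


def rewire_null(net: ThresholdedNetwork, n_swaps_per_edge: int = 10,
                seed: int = 0) -> ThresholdedNetwork:
    """Degree-preserving randomised copy of ``net``.

    Topology is randomised by double-edge swaps (each swap preserves every
    node's binary degree), then the original weight multiset is reassigned
    to the randomised edges in random order. Warns when fewer than
    ``n_swaps_per_edge * K`` swaps succeed within the attempt budget (e.g.
    for rigid graphs like complete graphs).
    """
    edges = net.edges()
    k = len(edges)
    if k < 2:
        return ThresholdedNetwork(net.weights.copy(), net.sparsity,
                                  net.edge_count, list(net.region_labels))
    rng = child_rng(seed, "rewire")
    eu = np.array([e[0] for e in edges], dtype=np.int64)
    ev = np.array([e[1] for e in edges], dtype=np.int64)
    wts = np.array([e[2] for e in edges])
    adj = net.weights > 0
    target = n_swaps_per_edge * k
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    achieved = _swap_kernel(eu, ev, adj.copy(), target, 100 * target,
                            kernel_seed)
    if achieved < target:
        warnings.warn(
            f"rewiring achieved {achieved}/{target} swaps within budget",
            RuntimeWarning, stacklevel=2)
    n = net.n_nodes
    out = np.zeros((n, n))
    out[eu, ev] = rng.permutation(wts)
    out = np.maximum(out, out.T)
    return ThresholdedNetwork(out, net.sparsity, net.edge_count,
                              list(net.region_labels))


@dataclass
class SmallWorldIndices:
    """Null-normalised small-world summary of one network."""

    gamma: float
    lambda_: float
    sigma: float
    null_c_p_mean: float
    null_c_p_sd: float
    null_l_p_mean: float
    null_l_p_sd: float
    n_random: int


def small_world_indices(net: ThresholdedNetwork, n_random: int = 100,
                        n_swaps_per_edge: int = 10, seed: int = 0,
                        clustering_variant: str = "onnela"
                        ) -> SmallWorldIndices:
    """gamma, lambda and sigma against degree-preserving rewired nulls.

    gamma = C_p / <C_p^rand>, lambda = L_p / <L_p^rand>, sigma = gamma /
    lambda, with ensemble means over ``n_random`` rewired networks. A null
    whose L_p is undefined (no reachable pair) is resampled, up to five
    times the ensemble budget.
    """
    _, c_p = clustering_coefficient(net, clustering_variant)
    l_p = characteristic_path_length(net)
    c_rand, l_rand = [], []
    draws = 0
    budget = 5 * n_random
    while len(c_rand) < n_random and draws < budget:
        null = rewire_null(net, n_swaps_per_edge,
                           seed=child_seed_for_null(seed, draws))
        draws += 1
        l_null = characteristic_path_length(null)
        if not np.isfinite(l_null):
            continue
        _, c_null = clustering_coefficient(null, clustering_variant)
        c_rand.append(c_null)
        l_rand.append(l_null)
    if len(c_rand) < n_random:
        raise RuntimeError("could not draw enough valid null networks")
    c_rand = np.asarray(c_rand)
    l_rand = np.asarray(l_rand)
    c_mean, l_mean = float(c_rand.mean()), float(l_rand.mean())
    gamma = c_p / c_mean if c_mean > 0 else float("inf")
    lam = l_p / l_mean if l_mean > 0 else float("inf")
    return SmallWorldIndices(gamma, lam, gamma / lam,
                             c_mean, float(c_rand.std()),
                             l_mean, float(l_rand.std()), n_random)


def child_seed_for_null(seed: int, index: int) -> int:
    from ._seeds import child_seed
    return child_seed(seed, "null-ensemble", index)


# ---------------------------------------------------------------------------
# AUC summary
# ---------------------------------------------------------------------------

def auc(curve: np.ndarray, grid_values: np.ndarray) -> float:
    """Trapezoid area under a metric-vs-sparsity curve.

    ``sum_k (Y(S_k) + Y(S_{k+1})) * (S_{k+1} - S_k) / 2``; for a constant
    curve c this equals c * (S_n - S_1).
    """
    y = np.asarray(curve, dtype=float)
    s = np.asarray(grid_values, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("curve and grid must be 1-D with equal length")
    if len(y) < 2:
        raise ValueError("need at least two grid points")
    if not np.all(np.isfinite(y)):
        raise ValueError("curve contains missing values")
    return float(np.sum((y[:-1] + y[1:]) * np.diff(s) / 2.0))


# ---------------------------------------------------------------------------
# per-network records (pipeline convenience)
# ---------------------------------------------------------------------------

def global_metrics_record(net: ThresholdedNetwork, n_random: int = 100,
                          n_swaps_per_edge: int = 10, seed: int = 0,
                          clustering_variant: str = "onnela") -> dict:
    """All seven global metrics of one thresholded network as a dict."""
    dist = shortest_path_lengths(net)
    _, c_p = clustering_coefficient(net, clustering_variant)
    sw = small_world_indices(net, n_random, n_swaps_per_edge, seed,
                             clustering_variant)
    return {
        "c_p": c_p,
        "l_p": characteristic_path_length(net, dist),
        "gamma": sw.gamma,
        "lambda": sw.lambda_,
        "sigma": sw.sigma,
        "e_glob": global_efficiency(net, dist),
        "e_loc": local_efficiency(net),
    }


def nodal_metrics_record(net: ThresholdedNetwork) -> dict[str, np.ndarray]:
    """The three nodal centralities of one thresholded network."""
    dist = shortest_path_lengths(net)
    return {
        "degree": degree(net).astype(float),
        "efficiency": nodal_efficiency(net, dist),
        "betweenness": betweenness(net),
    }


def nodal_auc_table(conns, groups, grid_values, subject_ids=None):
    """Nodal centrality curves and AUCs for a cohort of connectivity matrices.

    Returns ``(curves, aucs)`` as long-format DataFrames with columns
    (subject, group, sparsity, metric, node, value) and
    (subject, group, metric, node, auc).
    """
    import pandas as pd
    from .connectivity import threshold_at_sparsity

    grid_values = np.asarray(grid_values, dtype=float)
    rows = []
    for s_idx, (conn, group) in enumerate(zip(conns, groups)):
        sid = subject_ids[s_idx] if subject_ids else f"sub-{s_idx + 1:03d}"
        for s in grid_values:
            net = threshold_at_sparsity(conn, float(s))
            for metric, values in nodal_metrics_record(net).items():
                rows += [(sid, group, float(s), metric, node, float(v))
                         for node, v in zip(conn.region_labels, values)]
    curves = pd.DataFrame(rows, columns=["subject", "group", "sparsity",
                                         "metric", "node", "value"])
    aucs = (curves.sort_values("sparsity")
            .groupby(["subject", "group", "metric", "node"], sort=True)["value"]
            .apply(lambda v: auc(v.to_numpy(), grid_values))
            .rename("auc").reset_index())
    return curves, aucs
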