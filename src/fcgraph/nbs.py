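"""Network-based statistic (NBS): component-level inference on edges.

Edge-wise two-sample t statistics are computed on the raw signed
connectivity values of a node subset (typically the FDR-selected altered
regions, optionally the whole parcellation). Edges whose |t| exceeds a
primary threshold (default T = 1.6) form a graph; each connected component
is a candidate subnetwork, its size measured in edges (the extent measure).
Family-wise-error-corrected component p-values come from a permutation null
of the *maximum* component size under group-label reallocation (default
10,000 permutations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from .connectivity import ConnectivityMatrix
from ._seeds import child_rng

__all__ = [
    "EdgeStatMatrix",
    "NbsComponent",
    "NbsResult",
    "edgewise_tstats",
    "suprathreshold_components",
    "nbs_test",
]


@dataclass
class EdgeStatMatrix:
    """Signed two-sample t per edge over a node subset."""

    t_values: np.ndarray
    node_subset: list[str]
    df: int


@dataclass
class NbsComponent:
    """One supra-threshold connected component."""

    nodes: list[str]
    edges: list[dict]          # region1, region2, t, direction
    size: int                  # number of edges
    p_value: float = float("nan")


@dataclass
class NbsResult:
    """Observed components with FWE-corrected p-values."""

    components: list[NbsComponent]
    threshold_t: float
    n_permutations: int
    seed: int
    null_max_sizes: np.ndarray = field(default_factory=lambda: np.zeros(0))
    node_subset: list[str] = field(default_factory=list)

    def significant(self, alpha: float = 0.05) -> list[NbsComponent]:
        return [c for c in self.components if c.p_value < alpha]


def _edge_values(conns: list[ConnectivityMatrix],
                 subset_idx: np.ndarray) -> np.ndarray:
    """Stack upper-triangle signed connectivity values: (n_subjects, n_edges)."""
    m = subset_idx.size
    iu, ju = np.triu_indices(m, k=1)
    rows = [c.weights[np.ix_(subset_idx, subset_idx)][iu, ju] for c in conns]
    return np.vstack(rows)


def _tstats(values: np.ndarray, n_a: int) -> np.ndarray:
    """Pooled-variance two-sample t per column; zero-variance columns get 0."""
    a, b = values[:n_a], values[n_a:]
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    return t


def _resolve_subset(conns: list[ConnectivityMatrix],
                    node_subset: list[str] | list[int] | None
                    ) -> tuple[np.ndarray, list[str]]:
    labels = conns[0].region_labels
    if node_subset is None:
        idx = np.arange(len(labels))
    elif all(isinstance(x, (int, np.integer)) for x in node_subset):
        idx = np.asarray(node_subset, dtype=int)
    else:
        lookup = {lab: i for i, lab in enumerate(labels)}
        missing = [x for x in node_subset if x not in lookup]
        if missing:
            raise ValueError(f"unknown region labels: {missing[:5]}")
        idx = np.asarray([lookup[x] for x in node_subset], dtype=int)
    if idx.size < 2:
        raise ValueError("node subset must contain at least 2 regions")
    return idx, [labels[i] for i in idx]


def edgewise_tstats(conn_a: list[ConnectivityMatrix],
                    conn_b: list[ConnectivityMatrix],
                    node_subset: list[str] | list[int] | None = None
                    ) -> EdgeStatMatrix:
    """Signed two-sample t per edge on raw connectivity values.

    Positive t means group A exceeds group B on that edge. Computed on the
    signed (pre-thresholding) connectivity, pooled-variance formula.
    """
    if len(conn_a) < 2 or len(conn_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    idx, sub_labels = _resolve_subset(conn_a + conn_b, node_subset)
    values = _edge_values(list(conn_a) + list(conn_b), idx)
    t = _tstats(values, len(conn_a))
    if np.any(t == 0) and np.any(values.std(axis=0) == 0):
        warnings.warn("zero pooled variance on some edge(s); t set to 0",
                      RuntimeWarning, stacklevel=2)
    m = idx.size
    tm = np.zeros((m, m))
    iu, ju = np.triu_indices(m, k=1)
    tm[iu, ju] = t
    tm = tm + tm.T
    return EdgeStatMatrix(tm, sub_labels, len(conn_a) + len(conn_b) - 2)


def suprathreshold_components(stats: EdgeStatMatrix, t_threshold: float,
                              sided: str = "two") -> list[NbsComponent]:
    """Connected components of edges with |t| >= threshold.

    ``sided`` is "two" (screen on |t|), "greater" (t >= threshold) or
    "less" (t <= -threshold). Each edge carries its signed t and a
    direction label ("increase" when group A > group B). Components are
    sorted by edge count, descending.
    """
    if t_threshold <= 0:
        raise ValueError("t_threshold must be positive")
    t = stats.t_values
    if sided == "two":
        keep = np.abs(t) >= t_threshold
    elif sided == "greater":
        keep = t >= t_threshold
    elif sided == "less":
        keep = t <= -t_threshold
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    g = nx.Graph()
    iu, ju = np.triu_indices(t.shape[0], k=1)
    for i, j in zip(iu[keep[iu, ju]], ju[keep[iu, ju]]):
        g.add_edge(int(i), int(j))
    comps = []
    for nodes in nx.connected_components(g):
        sub = g.subgraph(nodes)
        edges = [{
            "region1": stats.node_subset[i],
            "region2": stats.node_subset[j],
            "t": float(t[i, j]),
            "direction": "increase" if t[i, j] > 0 else "decrease",
        } for i, j in sorted(sub.edges())]
        comps.append(NbsComponent(
            nodes=[stats.node_subset[i] for i in sorted(nodes)],
            edges=edges, size=sub.number_of_edges()))
    comps.sort(key=lambda c: c.size, reverse=True)
    return comps


def _max_component_edges(keep_iu: np.ndarray, iu: np.ndarray, ju: np.ndarray,
                         n_nodes: int) -> int:
    """Edge count of the largest connected component (union-find)."""
    parent = np.arange(n_nodes)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    edge_count = np.zeros(n_nodes, dtype=np.int64)
    for i, j in zip(iu[keep_iu], ju[keep_iu]):
        ri, rj = find(int(i)), find(int(j))
        if ri == rj:
            edge_count[ri] += 1
        else:
            parent[rj] = ri
            edge_count[ri] += edge_count[rj] + 1
            edge_count[rj] = 0
    return int(edge_count.max()) if keep_iu.any() else 0


def nbs_test(conn_a: list[ConnectivityMatrix],
             conn_b: list[ConnectivityMatrix],
             node_subset: list[str] | list[int] | None = None,
             t_threshold: float = 1.6, n_perm: int = 10_000,
             seed: int = 0, sided: str = "two") -> NbsResult:
    """Full NBS: observed components + max-component-size permutation null.

    The null permutes group labels (group sizes preserved), recomputes every
    edge t, thresholds, and records the maximum component size in edges.
    A component of observed size s gets the FWE-corrected p-value
    ``(1 + #{null max >= s}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    stats = edgewise_tstats(conn_a, conn_b, node_subset)
    comps = suprathreshold_components(stats, t_threshold, sided)
    m = len(stats.node_subset)
    iu, ju = np.triu_indices(m, k=1)
    idx, _ = _resolve_subset(list(conn_a) + list(conn_b), node_subset)
    values = _edge_values(list(conn_a) + list(conn_b), idx)
    n_a = len(conn_a)
    rng = child_rng(seed, "nbs-null")
    n_subj = values.shape[0]
    null_max = np.zeros(n_perm, dtype=np.int64)
    for p_idx in range(n_perm):
        order = rng.permutation(n_subj)
        t_null = _tstats(values[order], n_a)
        if sided == "two":
            keep = np.abs(t_null) >= t_threshold
        elif sided == "greater":
            keep = t_null >= t_threshold
        else:
            keep = t_null <= -t_threshold
        null_max[p_idx] = _max_component_edges(keep, iu, ju, m)
    for c in comps:
        c.p_value = float((1 + np.sum(null_max >= c.size)) / (1 + n_perm))
    return NbsResult(comps, float(t_threshold), n_perm, seed, null_max,
                     stats.node_subset)
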