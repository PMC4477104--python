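"""Nonparametric group comparison of AUC metrics.

Between-group differences in every AUC-summarised network metric are tested
by label permutation: the observed difference in group means is compared to
the distribution obtained by randomly reallocating subjects to two groups of
the original sizes (default 10,000 reallocations, two-tailed). Nodal
centralities are additionally corrected across regions by Benjamini-Hochberg
FDR, and a region counts as "altered" when at least one of its three
centralities survives FDR.

p-values use the permutation-inclusive (add-one) formula
``p = (1 + #{|null| >= |observed|}) / (1 + n_perm)`` so they are never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._seeds import child_rng, child_seed

__all__ = [
    "PermutationResult",
    "permutation_test",
    "fdr_bh",
    "compare_global",
    "select_altered_nodes",
]


@dataclass
class PermutationResult:
    """One permutation test: observed mean difference A - B and its null."""

    metric_name: str
    observed_diff: float
    null_diffs: np.ndarray
    p_value: float
    critical_value: float   # 95th percentile of |null|
    n_permutations: int
    seed: int
    node: str | None = None


def _null_diffs(pooled: np.ndarray, n_a: int, n_perm: int,
                rng: np.random.Generator) -> np.ndarray:
    """Permutation null of mean(first n_a) - mean(rest), vectorised.

    ``pooled`` may be 1-D (one test) or 2-D (n_subjects, n_tests) with the
    same label permutations shared across tests.
    """
    n = pooled.shape[0]
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    perm = pooled[order]  # (n_perm, n) or (n_perm, n, n_tests)
    return perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1)


def permutation_test(values_a: np.ndarray, values_b: np.ndarray,
                     n_perm: int = 10_000, seed: int = 0,
                     metric_name: str = "") -> PermutationResult:
    """Two-tailed permutation test on the difference of group means."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    pooled = np.concatenate([a, b])
    observed = float(a.mean() - b.mean())
    if np.ptp(pooled) == 0:
        warnings.warn("zero variance in pooled values; p = 1",
                      RuntimeWarning, stacklevel=2)
        null = np.zeros(n_perm)
        return PermutationResult(metric_name, observed, null, 1.0, 0.0,
                                 n_perm, seed)
    rng = child_rng(seed, "permutation-test")
    null = _null_diffs(pooled, a.size, n_perm, rng)
    p = float((1 + np.sum(np.abs(null) >= abs(observed) - 1e-15))
              / (1 + n_perm))
    crit = float(np.quantile(np.abs(null), 0.95))
    return PermutationResult(metric_name, observed, null, p, crit,
                             n_perm, seed)


def fdr_bh(p_values: np.ndarray, q: float = 0.05
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def compare_global(auc_table: pd.DataFrame, n_perm: int = 10_000,
                   seed: int = 0) -> pd.DataFrame:
    """Permutation tests on every global metric's AUC.

    ``auc_table`` is long format with columns (subject, group, metric, auc);
    groups are labelled "A"/"B". Returns one row per metric with the
    observed difference A - B, the two-tailed permutation p, and the
    95th-percentile critical value. No correction is applied across the
    global metrics (each is reported raw).
    """
    required = {"subject", "group", "metric", "auc"}
    if not required.issubset(auc_table.columns):
        raise ValueError(f"auc_table needs columns {sorted(required)}")
    rows = []
    for m_idx, (metric, sub) in enumerate(sorted(auc_table.groupby("metric"))):
        a = sub.loc[sub.group == "A", "auc"].to_numpy()
        b = sub.loc[sub.group == "B", "auc"].to_numpy()
        res = permutation_test(a, b, n_perm,
                               seed=child_seed(seed, "global", m_idx),
                               metric_name=metric)
        rows.append({"metric": metric, "mean_A": a.mean(), "mean_B": b.mean(),
                     "observed_diff": res.observed_diff,
                     "critical_value": res.critical_value,
                     "p_value": res.p_value})
    return pd.DataFrame(rows)


def select_altered_nodes(nodal_auc_table: pd.DataFrame, n_perm: int = 10_000,
                         q: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Permutation + FDR screen for regions with altered centrality.

    ``nodal_auc_table`` is long format with columns
    (subject, group, metric, node, auc) covering the three centralities
    (degree, efficiency, betweenness) on one common node set. Per metric,
    each node gets a two-tailed permutation p (one shared set of label
    permutations across nodes, for speed and exchangeability); BH-FDR is
    then applied per metric across nodes, and a node is selected when any
    of its three centralities survives.

    Returns one row per node with raw p's, adjusted p's, and the selected
    flag — the machine-readable analogue of an "altered regions" table.
    """
    required = {"subject", "group", "metric", "node", "auc"}
    if not required.issubset(nodal_auc_table.columns):
        raise ValueError(f"nodal_auc_table needs columns {sorted(required)}")
    metrics = sorted(nodal_auc_table.metric.unique())
    nodes = None
    out: dict[str, dict] = {}
    for m_idx, metric in enumerate(metrics):
        sub = nodal_auc_table[nodal_auc_table.metric == metric]
        wide = sub.pivot_table(index="subject", columns="node", values="auc",
                               sort=True)
        groups = sub.drop_duplicates("subject").set_index("subject")["group"]
        groups = groups.loc[wide.index]
        if nodes is None:
            nodes = list(wide.columns)
        elif list(wide.columns) != nodes:
            raise ValueError("metrics cover different node sets")
        a = wide.loc[groups == "A"].to_numpy()
        b = wide.loc[groups == "B"].to_numpy()
        if a.shape[0] < 2 or b.shape[0] < 2:
            raise ValueError("each group needs at least 2 subjects")
        pooled = np.vstack([a, b])
        observed = a.mean(axis=0) - b.mean(axis=0)
        rng = child_rng(seed, "nodal", m_idx)
        null = _null_diffs(pooled, a.shape[0], n_perm, rng)  # (n_perm, N)
        exceed = (np.abs(null) >= np.abs(observed)[None, :] - 1e-15).sum(axis=0)
        p_raw = (1 + exceed) / (1 + n_perm)
        # degenerate nodes (zero spread) get p = 1
        flat = np.ptp(pooled, axis=0) == 0
        p_raw[flat] = 1.0
        reject, p_adj = fdr_bh(p_raw, q)
        for i, node in enumerate(nodes):
            rec = out.setdefault(node, {"node": node})
            rec[f"diff_{metric}"] = observed[i]
            rec[f"p_{metric}"] = p_raw[i]
            rec[f"p_fdr_{metric}"] = p_adj[i]
            rec[f"reject_{metric}"] = bool(reject[i])
    table = pd.DataFrame([out[n] for n in nodes])
    reject_cols = [c for c in table.columns if c.startswith("reject_")]
    table["selected"] = table[reject_cols].any(axis=1)
    return table
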