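"""The fitted-analysis layer: a model object over a two-group cohort.

:class:`ConnectomeGroupAnalysis` is constructed from per-subject regional
time series plus group labels (and optional per-subject nuisance
regressors); :meth:`ConnectomeGroupAnalysis.fit` runs the whole analysis —
band-pass filtering, nuisance regression, partial-correlation estimation,
sparsity-grid determination, weighted graph metrics with null-model
normalisation, AUC summaries, permutation group comparison with FDR-screened
nodal centralities, and the network-based statistic — and returns a
:class:`ConnectomeGroupResults` carrying every table, a ``summary()`` and a
``save()`` that writes the plain-text outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn_mod
from . import metrics as met
from . import inference as inf
from . import nbs as nbs_mod
from .config import PipelineConfig
from .connectivity import (ConnectivityMatrix, SparsityGrid, TimeSeriesMatrix,
                           threshold_at_sparsity)
from .io import FLOAT_FORMAT, read_timeseries_dir, write_json
from .synthetic import Cohort
from ._seeds import child_seed

__all__ = ["ConnectomeGroupAnalysis", "ConnectomeGroupResults"]

logger = logging.getLogger("fcgraph")


class ConnectomeGroupAnalysis:
    """Two-group functional-connectome comparison.

    Parameters
    ----------
    subjects : list of TimeSeriesMatrix
        One regional time-series matrix per subject.
    groups : list of str
        "A" (patients) or "B" (controls), one per subject.
    covariates : list of arrays, optional
        Per-subject (T, M) nuisance regressors (e.g. motion profiles).
    config : PipelineConfig, optional
        All analysis settings; defaults follow the modelled study.

    Examples
    --------
    >>> from fcgraph import synthetic, config
    >>> model_a = synthetic.make_precision_model(20, 4, seed=0)
    >>> cohort = synthetic.simulate_cohort(
    ...     model_a, model_a, synthetic.CohortSpec(n_per_group=8, seed=1))
    >>> analysis = ConnectomeGroupAnalysis.from_cohort(
    ...     cohort, config.demo_config(seed=1))
    >>> results = analysis.fit()          # doctest: +SKIP
    >>> print(results.summary())          # doctest: +SKIP
    """

    def __init__(self, subjects: list[TimeSeriesMatrix], groups: list[str],
                 covariates: list[np.ndarray] | None = None,
                 config: PipelineConfig | None = None):
        if len(subjects) != len(groups):
            raise ValueError("one group label per subject required")
        bad = sorted(set(groups) - {"A", "B"})
        if bad:
            raise ValueError(f"group labels must be 'A'/'B', got {bad}")
        if sum(g == "A" for g in groups) < 2 or sum(g == "B" for g in groups) < 2:
            raise ValueError("need at least 2 subjects per group")
        labels = subjects[0].region_labels
        for s in subjects:
            if s.region_labels != labels:
                raise ValueError(f"subject {s.subject_id}: region labels differ")
        if covariates is not None and len(covariates) != len(subjects):
            raise ValueError("one covariate matrix per subject required")
        self.subjects = list(subjects)
        self.groups = list(groups)
        self.covariates = covariates
        self.config = config or PipelineConfig()
        self.region_labels = list(labels)

    @classmethod
    def from_cohort(cls, cohort: Cohort,
                    config: PipelineConfig | None = None
                    ) -> "ConnectomeGroupAnalysis":
        """Build from a simulated cohort, using its motion as covariates."""
        return cls(cohort.subjects, cohort.groups, cohort.motion, config)

    @classmethod
    def from_directory(cls, path: str | Path, label_file: str | Path,
                       groups_file: str | Path,
                       config: PipelineConfig | None = None
                       ) -> "ConnectomeGroupAnalysis":
        """Build from a directory of per-subject TSV time series.

        Motion files ``<subject_id>_motion.tsv`` are used as nuisance
        covariates when present.
        """
        config = config or PipelineConfig()
        subjects, groups = read_timeseries_dir(path, label_file, groups_file,
                                               config.tr_seconds)
        covs = []
        any_cov = False
        for s in subjects:
            f = Path(path) / f"{s.subject_id}_motion.tsv"
            if f.exists():
                covs.append(pd.read_csv(f, sep="\t").to_numpy(float))
                any_cov = True
            else:
                covs.append(np.zeros((s.n_timepoints, 0)))
        return cls(subjects, groups, covs if any_cov else None, config)

    # -- stages -------------------------------------------------------------

    def preprocess(self) -> list[TimeSeriesMatrix]:
        """Band-pass filter, then regress nuisance covariates per subject."""
        cfg = self.config
        out = []
        for i, ts in enumerate(self.subjects):
            f = conn_mod.bandpass_filter(ts, cfg.band.low_hz, cfg.band.high_hz)
            cov = None if self.covariates is None else self.covariates[i]
            out.append(conn_mod.regress_nuisance(f, cov))
        return out

    def estimate_connectivity(self, preprocessed: list[TimeSeriesMatrix]
                              ) -> list[ConnectivityMatrix]:
        cfg = self.config.estimator
        return [conn_mod.connectivity_matrix(ts, cfg.method, cfg.shrinkage)
                for ts in preprocessed]

    def determine_grid(self, conns: list[ConnectivityMatrix]) -> SparsityGrid:
        g = self.config.grid
        if g.mode == "fixed":
            return SparsityGrid(g.s_min, g.s_max, g.step)
        candidates = SparsityGrid(g.s_min, g.s_max, g.step).values
        return conn_mod.determine_threshold_range(
            conns, candidates, sigma_floor=g.sigma_floor,
            degree_log_base=g.degree_log_base, n_random=g.n_random,
            n_swaps_per_edge=self.config.nulls.n_swaps_per_edge,
            seed=child_seed(self.config.seed, "grid"))

    def fit(self) -> "ConnectomeGroupResults":
        """Run every stage and return the fitted results object."""
        cfg = self.config
        timings: dict[str, float] = {}

        def stage(name):
            logger.info("stage %s", name)
            timings[name] = time.perf_counter()

        def done(name):
            timings[name] = time.perf_counter() - timings[name]

        stage("preprocess")
        pre = self.preprocess()
        done("preprocess")

        stage("connectivity")
        conns = self.estimate_connectivity(pre)
        done("connectivity")

        stage("grid")
        grid = self.determine_grid(conns)
        done("grid")

        stage("metrics")
        gl_rows, nd_rows = [], []
        svals = grid.values
        for s_idx, (conn, group) in enumerate(zip(conns, self.groups)):
            sid = self.subjects[s_idx].subject_id or f"sub-{s_idx + 1:03d}"
            for t_idx, s in enumerate(svals):
                net = threshold_at_sparsity(conn, float(s))
                rec = met.global_metrics_record(
                    net, n_random=cfg.nulls.n_random,
                    n_swaps_per_edge=cfg.nulls.n_swaps_per_edge,
                    seed=child_seed(cfg.seed, "metrics", s_idx, t_idx),
                    clustering_variant=cfg.clustering_variant)
                for metric, value in rec.items():
                    gl_rows.append((sid, group, float(s), metric, value))
                nodal = met.nodal_metrics_record(net)
                for metric, values in nodal.items():
                    for node, value in zip(self.region_labels, values):
                        nd_rows.append((sid, group, float(s), metric, node,
                                        float(value)))
        global_curves = pd.DataFrame(
            gl_rows, columns=["subject", "group", "sparsity", "metric", "value"])
        nodal_curves = pd.DataFrame(
            nd_rows, columns=["subject", "group", "sparsity", "metric", "node",
                              "value"])
        done("metrics")

        stage("auc")
        auc_global = (
            global_curves.sort_values("sparsity")
            .groupby(["subject", "group", "metric"], sort=True)["value"]
            .apply(lambda v: met.auc(v.to_numpy(), svals))
            .rename("auc").reset_index())
        auc_nodal = (
            nodal_curves.sort_values("sparsity")
            .groupby(["subject", "group", "metric", "node"], sort=True)["value"]
            .apply(lambda v: met.auc(v.to_numpy(), svals))
            .rename("auc").reset_index())
        done("auc")

        stage("global_inference")
        global_comparison = inf.compare_global(
            auc_global, cfg.inference.n_perm,
            seed=child_seed(cfg.seed, "global-inference"))
        done("global_inference")

        stage("nodal_inference")
        altered = inf.select_altered_nodes(
            auc_nodal, cfg.inference.n_perm, cfg.inference.q,
            seed=child_seed(cfg.seed, "nodal-inference"))
        done("nodal_inference")

        stage("nbs")
        selected = altered.loc[altered.selected, "node"].tolist()
        if cfg.nbs.scope == "altered" and len(selected) >= 2:
            subset, nbs_scope = selected, "altered"
        else:
            subset, nbs_scope = None, "whole"
        idx_a = [i for i, g in enumerate(self.groups) if g == "A"]
        idx_b = [i for i, g in enumerate(self.groups) if g == "B"]
        nbs_result = nbs_mod.nbs_test(
            [conns[i] for i in idx_a], [conns[i] for i in idx_b],
            node_subset=subset, t_threshold=cfg.nbs.t_threshold,
            n_perm=cfg.nbs.n_perm, seed=child_seed(cfg.seed, "nbs"),
            sided=cfg.nbs.sided)
        done("nbs")

        return ConnectomeGroupResults(
            model=self, config=cfg, connectivity=conns, grid=grid,
            global_curves=global_curves, nodal_curves=nodal_curves,
            auc_global=auc_global, auc_nodal=auc_nodal,
            global_comparison=global_comparison, altered_nodes=altered,
            nbs_result=nbs_result, nbs_scope=nbs_scope, timings=timings)


@dataclass
class ConnectomeGroupResults:
    """Everything the fitted analysis produced."""

    model: ConnectomeGroupAnalysis
    config: PipelineConfig
    connectivity: list[ConnectivityMatrix]
    grid: SparsityGrid
    global_curves: pd.DataFrame
    nodal_curves: pd.DataFrame
    auc_global: pd.DataFrame
    auc_nodal: pd.DataFrame
    global_comparison: pd.DataFrame
    altered_nodes: pd.DataFrame
    nbs_result: nbs_mod.NbsResult
    nbs_scope: str = "altered"
    timings: dict = field(default_factory=dict)

    @property
    def selected_nodes(self) -> list[str]:
        return self.altered_nodes.loc[self.altered_nodes.selected,
                                      "node"].tolist()

    def summary(self) -> str:
        """Human-readable report of the fitted analysis."""
        cfg = self.config
        n_a = sum(g == "A" for g in self.model.groups)
        n_b = sum(g == "B" for g in self.model.groups)
        lines = [
            "Functional connectome group analysis",
            "=" * 68,
            f"subjects: {n_a} (group A) vs {n_b} (group B); "
            f"regions: {len(self.model.region_labels)}",
            f"estimator: {cfg.estimator.method} "
            f"(shrinkage={cfg.estimator.shrinkage}); "
            f"band: {cfg.band.low_hz}-{cfg.band.high_hz} Hz",
            f"sparsity grid: {self.grid.s_min:.2f}..{self.grid.s_max:.2f} "
            f"step {self.grid.step:.2f} ({len(self.grid)} thresholds)",
            f"permutations: {cfg.inference.n_perm}; FDR q={cfg.inference.q}; "
            f"NBS T={cfg.nbs.t_threshold} ({self.nbs_scope} scope)",
            "",
            "Global metric AUCs (group mean, permutation p, two-tailed)",
            "-" * 68,
        ]
        for _, r in self.global_comparison.iterrows():
            star = " *" if r.p_value < cfg.inference.alpha else ""
            lines.append(f"  {r.metric:<8s} A={r.mean_A:9.5f}  "
                         f"B={r.mean_B:9.5f}  diff={r.observed_diff:+9.5f}  "
                         f"p={r.p_value:.4f}{star}")
        lines += ["", f"Altered regions (FDR q={cfg.inference.q}, any of "
                      f"degree/efficiency/betweenness): "
                      f"{len(self.selected_nodes)}"]
        if self.selected_nodes:
            lines.append("  " + ", ".join(self.selected_nodes))
        lines += ["", f"NBS components (T={cfg.nbs.t_threshold}, "
                      f"{self.nbs_result.n_permutations} permutations):"]
        if not self.nbs_result.components:
            lines.append("  none above threshold")
        for k, c in enumerate(self.nbs_result.components):
            star = " *" if c.p_value < cfg.inference.alpha else ""
            lines.append(f"  component {k + 1}: {len(c.nodes)} nodes, "
                         f"{c.size} edges, p={c.p_value:.4f}{star}")
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------------

    def save(self, outdir: str | Path) -> None:
        """Write all result tables and reports as TSV/JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tag = f"{self.config.config_hash()}:{self.config.seed}"

        def tsv(df: pd.DataFrame, name: str) -> None:
            path = outdir / name
            with open(path, "w") as fh:
                fh.write(f"# fcgraph config={tag.split(':')[0]} "
                         f"seed={self.config.seed}\n")
                df.to_csv(fh, sep="\t", index=False,
                          float_format=FLOAT_FORMAT)

        tsv(self.global_curves, "metrics_global.tsv")
        tsv(self.nodal_curves, "metrics_nodal.tsv")
        auc_nodal = self.auc_nodal.copy()
        auc_all = pd.concat(
            [self.auc_global.assign(node=""), auc_nodal],
            ignore_index=True)[["subject", "group", "metric", "node", "auc"]]
        tsv(auc_all, "metrics_auc.tsv")
        tsv(self.global_comparison, "global_comparison.tsv")
        nodal_long = []
        for _, r in self.altered_nodes.iterrows():
            for metric in ("degree", "efficiency", "betweenness"):
                nodal_long.append({
                    "node": r.node, "metric": metric,
                    "observed_diff": r[f"diff_{metric}"],
                    "p_raw": r[f"p_{metric}"],
                    "p_fdr": r[f"p_fdr_{metric}"],
                    "selected": bool(r.selected)})
        tsv(pd.DataFrame(nodal_long), "nodal_comparison.tsv")
        comp_rows = []
        for k, c in enumerate(self.nbs_result.components):
            for e in c.edges:
                comp_rows.append({"component": k + 1, "region1": e["region1"],
                                  "region2": e["region2"], "t": e["t"],
                                  "direction": e["direction"],
                                  "component_p": c.p_value})
        comp_df = pd.DataFrame(
            comp_rows, columns=["component", "region1", "region2", "t",
                                "direction", "component_p"])
        tsv(comp_df, "nbs_components.tsv")
        write_json({"config": tag.split(":")[0], "seed": self.config.seed,
                    "grid": {"s_min": self.grid.s_min,
                             "s_max": self.grid.s_max,
                             "step": self.grid.step,
                             "bounded_by": self.grid.bounded_by}},
                   outdir / "grid_report.json")
        write_json({"config_hash": tag.split(":")[0],
                    "seed": self.config.seed,
                    "nbs_scope": self.nbs_scope,
                    "n_selected_nodes": len(self.selected_nodes),
                    "stage_seconds": {k: round(v, 3)
                                      for k, v in self.timings.items()}},
                   outdir / "run_report.json")
        self.config.to_yaml(outdir / "config_echo.yaml")
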