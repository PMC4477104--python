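"""Plain-text I/O: TSV time series and matrices, JSON reports, label lists.

All interchange formats are diff-able text. Time-series files are TSV with
one header row of region labels and T numeric rows; connectivity matrices
are TSV with header and index labels; reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import TimeSeriesMatrix, ConnectivityMatrix
from .synthetic import Cohort

__all__ = [
    "read_labels",
    "write_labels",
    "read_timeseries",
    "write_timeseries",
    "read_timeseries_dir",
    "write_cohort",
    "read_connectivity",
    "write_connectivity",
    "write_json",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.10g"


def read_labels(path: str | Path) -> list[str]:
    """One region label per line, blank lines ignored."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def write_labels(labels: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(labels) + "\n")


def write_timeseries(ts: TimeSeriesMatrix, path: str | Path) -> None:
    df = pd.DataFrame(ts.values, columns=ts.region_labels)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_timeseries(path: str | Path, tr_seconds: float = 2.0,
                    subject_id: str = "") -> TimeSeriesMatrix:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse as TSV ({exc})") from exc
    bad = df.columns[~df.dtypes.map(lambda d: np.issubdtype(d, np.number))]
    if len(bad):
        col = bad[0]
        row = int(pd.to_numeric(df[col], errors="coerce").isna().idxmax()) + 2
        raise ValueError(f"{path}: non-numeric cell in column {col!r} "
                         f"near line {row}")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = int(df[col].isna().idxmax()) + 2
        raise ValueError(f"{path}: missing/ragged value in column {col!r} "
                         f"at line {row}")
    sid = subject_id or path.stem
    return TimeSeriesMatrix(df.to_numpy(float), list(df.columns),
                            tr_seconds, sid)


def read_timeseries_dir(path: str | Path, label_file: str | Path,
                        groups_file: str | Path, tr_seconds: float = 2.0
                        ) -> tuple[list[TimeSeriesMatrix], list[str]]:
    """Read every subject listed in the groups table, validating labels.

    The groups table is TSV with columns (subject_id, group); each subject
    ``<subject_id>.tsv`` must exist under ``path`` and carry exactly the
    labels of ``label_file`` in order. Returns (subjects, group labels)
    ordered by subject id.
    """
    path = Path(path)
    labels = read_labels(label_file)
    gtab = pd.read_csv(groups_file, sep="\t")
    if not {"subject_id", "group"}.issubset(gtab.columns):
        raise ValueError(f"{groups_file}: needs columns subject_id, group")
    gtab = gtab.sort_values("subject_id")
    subjects, groups = [], []
    for _, row in gtab.iterrows():
        f = path / f"{row.subject_id}.tsv"
        if not f.exists():
            raise FileNotFoundError(f"missing time-series file {f}")
        ts = read_timeseries(f, tr_seconds, str(row.subject_id))
        if ts.region_labels != labels:
            mism = next(i for i, (a, b)
                        in enumerate(zip(ts.region_labels, labels)) if a != b)
            raise ValueError(
                f"{f}: header label {ts.region_labels[mism]!r} at column "
                f"{mism + 1} does not match expected {labels[mism]!r}")
        subjects.append(ts)
        groups.append(str(row.group))
    return subjects, groups


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write per-subject TSVs, motion regressors, groups.tsv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ts, motion in zip(cohort.subjects, cohort.motion):
        write_timeseries(ts, outdir / f"{ts.subject_id}.tsv")
        pd.DataFrame(motion, columns=[f"motion{i + 1}" for i in range(6)]) \
            .to_csv(outdir / f"{ts.subject_id}_motion.tsv", sep="\t",
                    index=False, float_format=FLOAT_FORMAT)
    pd.DataFrame({"subject_id": cohort.subject_ids, "group": cohort.groups}) \
        .to_csv(outdir / "groups.tsv", sep="\t", index=False)
    write_labels(cohort.subjects[0].region_labels, outdir / "labels.txt")
    spec = cohort.spec
    truth = {
        "planted_edges": [[int(i), int(j), float(d)]
                          for i, j, d in cohort.model_b.planted_edges],
        "seed": spec.seed,
        "spec": {
            "n_per_group": spec.n_per_group,
            "n_timepoints": spec.n_timepoints,
            "tr_seconds": spec.tr_seconds,
            "drift_amplitude": spec.drift_amplitude,
            "highfreq_noise_sd": spec.highfreq_noise_sd,
            "motion_leak_sd": spec.motion_leak_sd,
        },
    }
    write_json(truth, outdir / "truth.json")


def write_connectivity(conn: ConnectivityMatrix, path: str | Path) -> None:
    pd.DataFrame(conn.weights, index=conn.region_labels,
                 columns=conn.region_labels) \
        .to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_connectivity(path: str | Path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(df.to_numpy(float), list(df.columns))


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
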