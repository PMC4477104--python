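"""From regional time series to weighted partial-correlation networks.

The pipeline stage implemented here mirrors standard resting-state
connectome construction: band-pass filtering of regional mean signals,
nuisance (motion) regression, partial-correlation estimation with shrinkage
regularisation, conversion to weighted adjacency matrices by sparsity
thresholding, and determination of the admissible sparsity range from
small-world estimability criteria.

Conventions
-----------
* Partial correlation of regions i and j is ``-P_ij / sqrt(P_ii * P_jj)``
  where ``P`` is the (shrinkage-regularised) precision matrix.
* Thresholding ranks edges by absolute connectivity and stores the absolute
  value as the edge weight, so retained weights lie in (0, 1] and distances
  1/weight are well defined.
* The estimability criteria are (a) group-mean small-worldness sigma above a
  floor (default 1.1) and (b) mean binary degree above ``2 * ln(N)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import LedoitWolf

__all__ = [
    "TimeSeriesMatrix",
    "ConnectivityMatrix",
    "ThresholdedNetwork",
    "SparsityGrid",
    "bandpass_filter",
    "regress_nuisance",
    "partial_correlation_matrix",
    "pearson_correlation_matrix",
    "connectivity_matrix",
    "edge_count_at_sparsity",
    "threshold_at_sparsity",
    "determine_threshold_range",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TimeSeriesMatrix:
    """One subject's regional signals: T timepoints x N regions.

    Parameters
    ----------
    values : (T, N) float array
        Regional mean signals, arbitrary units.
    region_labels : list of str
        Column labels, length N.
    tr_seconds : float
        Sampling interval (repetition time) in seconds.
    subject_id : str, optional
        Identifier carried through the pipeline.
    """

    values: np.ndarray
    region_labels: list[str]
    tr_seconds: float = 2.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (T x N) array")
        t, n = self.values.shape
        if t < 30:
            raise ValueError(f"need at least 30 timepoints, got {t}")
        if n < 3:
            raise ValueError(f"need at least 3 regions, got {n}")
        if len(self.region_labels) != n:
            raise ValueError(
                f"{len(self.region_labels)} labels for {n} regions"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def _replace_values(self, values: np.ndarray) -> "TimeSeriesMatrix":
        return TimeSeriesMatrix(values, list(self.region_labels),
                                self.tr_seconds, self.subject_id)


@dataclass
class ConnectivityMatrix:
    """N x N symmetric connectivity weights with zero diagonal."""

    weights: np.ndarray
    region_labels: list[str]
    estimator_note: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = w.shape[0]
        if w.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        if len(self.region_labels) != n:
            raise ValueError("label count does not match matrix size")
        if not np.all(np.isfinite(w)):
            raise ValueError("connectivity matrix contains non-finite values")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.max(np.abs(w)) > 1 + 1e-9:
            raise ValueError("connectivity entries must lie in [-1, 1]")
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass
class ThresholdedNetwork:
    """Weighted undirected graph keeping the top-K edges at sparsity S.

    ``weights`` is a symmetric non-negative matrix; zero means no edge.
    """

    weights: np.ndarray
    sparsity: float
    edge_count: int
    region_labels: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def edges(self) -> list[tuple[int, int, float]]:
        """Upper-triangle edge list as (i, j, weight)."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        keep = self.weights[iu, ju] > 0
        return list(zip(iu[keep].tolist(), ju[keep].tolist(),
                        self.weights[iu, ju][keep].tolist()))


@dataclass
class SparsityGrid:
    """Ordered sparsity thresholds s_min, s_min+step, ..., s_max."""

    s_min: float
    s_max: float
    step: float
    bounded_by: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.s_min < self.s_max < 1):
            raise ValueError("need 0 < s_min < s_max < 1")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.s_max - self.s_min) / self.step)) + 1
        return self.s_min + self.step * np.arange(n)

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def bandpass_filter(ts: TimeSeriesMatrix, low_hz: float = 0.0,
                    high_hz: float = 0.08) -> TimeSeriesMatrix:
    """Band-pass each regional signal with a hard FFT mask.

    Frequencies inside [low_hz, high_hz] pass unchanged, everything else is
    zeroed; the DC bin is always removed so the output is mean-centred.
    The mask gives a bit-exact, parameter-free frequency response, which is
    all the method requires (only the band itself is specified).
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not (0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz > nyquist + 1e-12:
        raise ValueError(
            f"high_hz={high_hz} exceeds Nyquist {nyquist:.4g} Hz for "
            f"TR={ts.tr_seconds}s"
        )
    t = ts.n_timepoints
    freqs = np.fft.rfftfreq(t, d=ts.tr_seconds)
    mask = (freqs >= low_hz - 1e-12) & (freqs <= high_hz + 1e-12)
    mask[0] = False  # mean removal
    spec = np.fft.rfft(ts.values, axis=0)
    spec[~mask, :] = 0.0
    out = np.fft.irfft(spec, n=t, axis=0)
    return ts._replace_values(out)


def regress_nuisance(ts: TimeSeriesMatrix,
                     covariates: np.ndarray | None) -> TimeSeriesMatrix:
    """Remove nuisance covariates (e.g. motion profiles) by least squares.

    An intercept column is always included, so with no covariates the output
    is simply the mean-centred input. Residuals are orthogonal to every
    covariate column.
    """
    t = ts.n_timepoints
    if covariates is None or np.size(covariates) == 0:
        design = np.ones((t, 1))
    else:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        if covariates.shape[0] != t:
            raise ValueError(
                f"covariates have {covariates.shape[0]} rows, series has {t}"
            )
        if covariates.shape[1] >= t:
            raise ValueError("more covariates than timepoints")
        design = np.column_stack([np.ones(t), covariates])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            warnings.warn("rank-deficient nuisance design; using pseudo-inverse",
                          RuntimeWarning, stacklevel=2)
    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    resid = ts.values - design @ beta
    return ts._replace_values(resid)


# ---------------------------------------------------------------------------
# connectivity estimation
# ---------------------------------------------------------------------------

def _check_columns(ts: TimeSeriesMatrix) -> np.ndarray:
    x = ts.values
    if ts.n_timepoints < 30 or ts.n_regions < 3:
        raise ValueError("need T >= 30 and N >= 3 for connectivity estimation")
    bad = np.flatnonzero(np.ptp(x, axis=0) == 0)
    if bad.size:
        names = ", ".join(ts.region_labels[i] for i in bad[:5])
        raise ValueError(f"zero-variance region(s): {names}")
    return x


def partial_correlation_matrix(ts: TimeSeriesMatrix,
                               shrinkage: str | float = "auto"
                               ) -> ConnectivityMatrix:
    """Partial-correlation matrix from a shrinkage-regularised precision.

    With N regions and T ~ 2N timepoints the sample covariance is
    near-singular, so estimation works on the correlation scale (signals are
    standardised per region, making the estimator invariant to affine
    rescaling of any region) and the correlation matrix is shrunk toward the
    identity before inversion: Ledoit-Wolf analytic intensity for
    ``shrinkage="auto"`` or a fixed intensity in [0, 1]. The partial
    correlation is ``rho_ij = -P_ij / sqrt(P_ii P_jj)`` for the precision
    ``P``.
    """
    x = _check_columns(ts)
    xc = x - x.mean(axis=0)
    xc = xc / xc.std(axis=0)
    n = ts.n_regions
    sample = (xc.T @ xc) / xc.shape[0]
    # near-collinear data: warn, shrinkage keeps the inverse finite
    eigmin = float(np.linalg.eigvalsh(sample)[0])
    if eigmin < 1e-10 * float(np.trace(sample)) / n:
        warnings.warn(
            "sample covariance is (near-)singular; relying on shrinkage",
            RuntimeWarning, stacklevel=2,
        )
    if shrinkage == "auto":
        lw = LedoitWolf(assume_centered=True).fit(xc)
        cov = lw.covariance_
        intensity = float(lw.shrinkage_)
    else:
        intensity = float(shrinkage)
        if not 0 <= intensity <= 1:
            raise ValueError("shrinkage intensity must be in [0, 1]")
        mu = float(np.trace(sample)) / n
        cov = (1 - intensity) * sample + intensity * mu * np.eye(n)
    prec = np.linalg.inv(cov)
    d = np.sqrt(np.diag(prec))
    rho = -prec / np.outer(d, d)
    rho = 0.5 * (rho + rho.T)
    np.fill_diagonal(rho, 0.0)
    rho = np.clip(rho, -1.0, 1.0)
    if not np.all(np.isfinite(rho)):
        raise ValueError("partial-correlation estimate is non-finite")
    note = f"partial correlation, Ledoit-Wolf shrinkage={intensity:.6f}" \
        if shrinkage == "auto" else \
        f"partial correlation, fixed shrinkage={intensity:.6f}"
    return ConnectivityMatrix(rho, list(ts.region_labels), note)


def pearson_correlation_matrix(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Plain Pearson correlation matrix (alternative estimator)."""
    x = _check_columns(ts)
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(r, list(ts.region_labels), "pearson correlation")


def connectivity_matrix(ts: TimeSeriesMatrix, estimator: str = "partial",
                        shrinkage: str | float = "auto") -> ConnectivityMatrix:
    """Dispatch on estimator name ("partial" or "pearson")."""
    if estimator == "partial":
        return partial_correlation_matrix(ts, shrinkage)
    if estimator == "pearson":
        return pearson_correlation_matrix(ts)
    raise ValueError(f"unknown estimator {estimator!r}")


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def edge_count_at_sparsity(s: float, n: int) -> int:
    """K = round(S * N(N-1)/2), half-up rounding."""
    return int(np.floor(s * n * (n - 1) / 2 + 0.5))


def threshold_at_sparsity(conn: ConnectivityMatrix, s: float
                          ) -> ThresholdedNetwork:
    """Keep the K strongest |connectivity| entries as positive edge weights.

    Edges are ranked by absolute connectivity, descending; ties at the cut
    are broken by (i, j) lexicographic order so results are deterministic.
    Retained weights are the absolute connectivity values.
    """
    if not 0 < s < 1:
        raise ValueError("sparsity must lie in (0, 1)")
    n = conn.n_regions
    k = edge_count_at_sparsity(s, n)
    if k == 0:
        raise ValueError(f"sparsity {s} keeps zero edges at N={n}")
    iu, ju = np.triu_indices(n, k=1)
    absw = np.abs(conn.weights[iu, ju])
    # stable sort on (-|w|, i, j): lexsort keys are last-key-primary
    order = np.lexsort((ju, iu, -absw))
    keep = order[:k]
    out = np.zeros((n, n))
    out[iu[keep], ju[keep]] = absw[keep]
    out = out + out.T
    return ThresholdedNetwork(out, float(s), k, list(conn.region_labels))


def determine_threshold_range(conns: list[ConnectivityMatrix],
                              candidates: np.ndarray,
                              sigma_floor: float = 1.1,
                              degree_log_base: float = np.e,
                              n_random: int = 20,
                              n_swaps_per_edge: int = 10,
                              seed: int = 0) -> SparsityGrid:
    """Maximal contiguous sparsity range satisfying both estimability criteria.

    (a) the group-mean small-worldness sigma exceeds ``sigma_floor``;
    (b) every subject's mean binary degree exceeds ``2 * log(N)`` (natural
        log by default, base configurable).

    Returns the grid together with which criterion bound each end. Raises
    with a per-threshold diagnostic table when no threshold is admissible.
    """
    from .metrics import small_world_indices
    from ._seeds import child_seed

    candidates = np.asarray(candidates, dtype=float)
    if candidates[0] > 0.05 + 1e-9 or candidates[-1] < 0.50 - 1e-9:
        raise ValueError("candidate grid must cover at least (0.05, 0.50)")
    n = conns[0].n_regions
    deg_bound = 2.0 * np.log(n) / np.log(degree_log_base)
    step = float(np.median(np.diff(candidates)))

    ok = np.zeros(len(candidates), dtype=bool)
    diag_rows = []
    for t_idx, s in enumerate(candidates):
        k = edge_count_at_sparsity(s, n)
        mean_degree = 2.0 * k / n
        deg_ok = mean_degree > deg_bound
        sigma_mean = np.nan
        sig_ok = False
        if deg_ok:  # sigma is the expensive criterion; skip when degree fails
            sigmas = []
            for s_idx, conn in enumerate(conns):
                net = threshold_at_sparsity(conn, s)
                sw = small_world_indices(
                    net, n_random=n_random,
                    n_swaps_per_edge=n_swaps_per_edge,
                    seed=child_seed(seed, "grid-sigma", t_idx, s_idx))
                sigmas.append(sw.sigma)
            sigma_mean = float(np.mean(sigmas))
            sig_ok = sigma_mean > sigma_floor
        ok[t_idx] = deg_ok and sig_ok
        diag_rows.append((float(s), mean_degree, deg_ok, sigma_mean, sig_ok))

    if not ok.any():
        table = "\n".join(
            f"  S={s:.3f} mean_degree={d:7.2f} deg_ok={dok} "
            f"sigma={g if np.isnan(g) else round(g, 3)} sigma_ok={gok}"
            for s, d, dok, g, gok in diag_rows)
        raise ValueError(
            "no admissible sparsity threshold; per-threshold diagnostics:\n"
            + table)

    # maximal contiguous run of admissible thresholds
    runs, start = [], None
    for i, flag in enumerate(ok):
        if flag and start is None:
            start = i
        if (not flag or i == len(ok) - 1) and start is not None:
            end = i if flag else i - 1
            runs.append((start, end))
            start = None
    lo, hi = max(runs, key=lambda r: r[1] - r[0])

    def _bound(idx: int, neighbor: int) -> str:
        if neighbor < 0 or neighbor >= len(candidates):
            return "grid_end"
        s, d, dok, g, gok = diag_rows[neighbor]
        if not dok:
            return "degree"
        return "sigma"

    bounded_by = {
        "lower": _bound(lo, lo - 1),
        "upper": _bound(hi, hi + 1),
        "degree_bound": float(deg_bound),
        "sigma_floor": float(sigma_floor),
        "diagnostics": [
            {"s": r[0], "mean_degree": r[1], "degree_ok": bool(r[2]),
             "sigma": None if np.isnan(r[3]) else r[3],
             "sigma_ok": bool(r[4])}
            for r in diag_rows
        ],
    }
    return SparsityGrid(float(candidates[lo]), float(candidates[hi]), step,
                        bounded_by)
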