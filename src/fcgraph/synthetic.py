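"""Synthetic resting-state cohorts with known connectivity ground truth.

Real regional BOLD time series for this kind of study are rarely shareable,
so every downstream stage is exercised against simulated cohorts whose true
partial-correlation structure is known exactly. Ground truth is
parameterised by the *precision* (inverse covariance) matrix, because the
pipeline estimates partial correlations: the true partial correlation of a
region pair (i, j) is ``-P_ij / sqrt(P_ii P_jj)``, so recovery tests are
exact in expectation.

The generator emulates the salient features of preprocessed resting-state
data: multivariate-normal regional signals with community-structured
covariance (which makes thresholded networks small-world), slow drift
(linear ramp plus sub-0.01 Hz sinusoids) that band-pass filtering must
remove, broadband white noise, and a leak of six smoothed-random-walk
"motion" regressors that nuisance regression must remove. It does not
simulate voxel-level images, hemodynamics, or motion spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import TimeSeriesMatrix
from ._seeds import child_rng

__all__ = [
    "PrecisionModel",
    "CohortSpec",
    "Cohort",
    "make_precision_model",
    "study_precision_model",
    "connected_edge_set",
    "plant_group_effect",
    "simulate_cohort",
    "true_partial_correlations",
    "default_region_labels",
]


def default_region_labels(n: int) -> list[str]:
    return [f"R{i + 1:03d}" for i in range(n)]


def true_partial_correlations(precision: np.ndarray) -> np.ndarray:
    """Ground-truth partial correlations -P_ij / sqrt(P_ii P_jj)."""
    d = np.sqrt(np.diag(precision))
    rho = -precision / np.outer(d, d)
    np.fill_diagonal(rho, 0.0)
    return rho


@dataclass
class PrecisionModel:
    """Ground-truth inverse covariance of one group's regional signals."""

    precision: np.ndarray
    community_labels: np.ndarray
    planted_edges: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        p = np.asarray(self.precision, dtype=float)
        n = p.shape[0]
        if p.shape != (n, n) or not np.allclose(p, p.T, atol=1e-10):
            raise ValueError("precision must be a symmetric square matrix")
        eigmin = float(np.linalg.eigvalsh(p)[0])
        if eigmin <= 0:
            raise ValueError(
                f"precision is not positive-definite (min eigenvalue {eigmin:.3g})")
        if len(self.community_labels) != n:
            raise ValueError("community_labels length mismatch")
        for i, j, _ in self.planted_edges:
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"invalid planted edge ({i}, {j})")
        rho = true_partial_correlations(p)
        off = ~np.eye(n, dtype=bool)
        if np.any(np.abs(rho[off]) >= 1):
            raise ValueError("a true partial correlation falls outside (-1, 1)")
        self.precision = 0.5 * (p + p.T)
        self.community_labels = np.asarray(self.community_labels)

    @property
    def n_regions(self) -> int:
        return self.precision.shape[0]

    def partial_correlations(self) -> np.ndarray:
        return true_partial_correlations(self.precision)

    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)


@dataclass(frozen=True)
class CohortSpec:
    """Simulation settings for one two-group cohort.

    Defaults mirror the acquisition this generator emulates: 20 subjects
    per group, 200 retained timepoints at TR = 2 s.
    """

    n_per_group: int = 20
    n_timepoints: int = 200
    tr_seconds: float = 2.0
    drift_amplitude: float = 1.0
    highfreq_noise_sd: float = 0.3
    motion_leak_sd: float = 0.2
    signal_band_hz: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.n_timepoints < 30:
            raise ValueError("need at least 30 timepoints")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")


@dataclass
class Cohort:
    """Simulated two-group cohort with its ground truth attached."""

    subjects: list[TimeSeriesMatrix]
    groups: list[str]                      # "A" or "B" per subject
    motion: list[np.ndarray]               # (T, 6) nuisance regressors
    model_a: PrecisionModel
    model_b: PrecisionModel
    spec: CohortSpec

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def by_group(self) -> tuple[list[int], list[int]]:
        idx_a = [i for i, g in enumerate(self.groups) if g == "A"]
        idx_b = [i for i, g in enumerate(self.groups) if g == "B"]
        return idx_a, idx_b


def make_precision_model(n_regions: int, n_blocks: int,
                         within_block_strength: float = 0.4,
                         seed: int = 0,
                         within_block_density: float = 0.9,
                         between_block_strength: float = 0.05,
                         spectral_margin: float = 0.9) -> PrecisionModel:
    """Community-structured, sparse, positive-definite precision matrix.

    Regions are split into ``n_blocks`` contiguous communities. A target
    partial-correlation matrix R is drawn: within-block region pairs get a
    positive partial correlation near ``within_block_strength`` with
    probability ``within_block_density``; a few weak between-block links
    keep the network connected. The precision is ``P = I - R`` with unit
    diagonal, so the true partial correlation of a pair equals R exactly.
    Positive-definiteness requires the largest eigenvalue of R to stay
    below 1; R is rescaled to spectral radius ``spectral_margin`` when it
    exceeds that bound (mutually high partial correlations inside a block
    are not jointly attainable, so realised values are somewhat below the
    nominal strength at study scale).
    """
    if not 1 <= n_blocks <= n_regions:
        raise ValueError("need n_regions >= n_blocks >= 1")
    rng = child_rng(seed, "precision-model")
    labels = np.repeat(np.arange(n_blocks),
                       int(np.ceil(n_regions / n_blocks)))[:n_regions]
    r = np.zeros((n_regions, n_regions))
    if within_block_strength != 0:
        for i in range(n_regions):
            for j in range(i + 1, n_regions):
                if labels[i] == labels[j]:
                    if rng.random() < within_block_density:
                        r[i, j] = r[j, i] = \
                            within_block_strength * rng.uniform(0.6, 1.0)
                elif rng.random() < 0.02:
                    r[i, j] = r[j, i] = \
                        between_block_strength * rng.uniform(0.5, 1.0)
        lam_max = float(np.linalg.eigvalsh(r)[-1])
        if lam_max >= spectral_margin:
            r *= spectral_margin / lam_max
    p = np.eye(n_regions) - r
    eigmin = float(np.linalg.eigvalsh(p)[0])
    if eigmin <= 0:  # unreachable after spectral rescaling
        raise RuntimeError(
            f"constructed precision not positive-definite (min eig {eigmin:.3g})")
    return PrecisionModel(p, labels)


def study_precision_model(seed: int = 0, n_regions: int = 90,
                          n_blocks: int = 18) -> PrecisionModel:
    """The packaged study-scale ground truth: 90 regions in 18 tight clusters.

    Small, near-complete communities give the thresholded networks their
    small-world character (high clustering from within-cluster triangles,
    short paths from the between-cluster links and retained noise edges) at
    the study's estimation scale of ~200 timepoints.
    """
    return make_precision_model(n_regions, n_blocks, seed=seed)


def connected_edge_set(n_regions: int, seed: int, n_nodes: int = 7,
                       n_edges: int = 10) -> list[tuple[int, int]]:
    """A connected edge set on randomly chosen regions (path + chords).

    Used to plant a localized group difference whose supra-threshold edges
    form one connected component.
    """
    if n_edges < n_nodes - 1 or n_edges > n_nodes * (n_nodes - 1) // 2:
        raise ValueError("n_edges incompatible with a connected simple graph")
    rng = child_rng(seed, "planted-component")
    nodes = rng.choice(n_regions, size=n_nodes, replace=False)
    edges = [(int(nodes[i - 1]), int(nodes[i])) for i in range(1, n_nodes)]
    chords = [(int(nodes[i]), int(nodes[j]))
              for i in range(n_nodes) for j in range(i + 1, n_nodes)
              if j - i > 1]
    extra = rng.choice(len(chords), size=n_edges - (n_nodes - 1),
                       replace=False)
    edges += [chords[i] for i in sorted(extra)]
    return edges


def plant_group_effect(model: PrecisionModel,
                       edges: list[tuple[int, int]] | list[tuple[int, int, float]],
                       delta: float) -> PrecisionModel:
    """Return a copy of ``model`` with ``delta`` added to listed precision entries.

    Adding ``delta`` to ``P_ij`` shifts the true partial correlation of that
    pair by about ``-delta / sqrt(P_ii P_jj)`` and leaves every other pair's
    partial correlation unchanged (partial correlations depend only on the
    corresponding precision entry and the diagonal). If the perturbed matrix
    loses positive-definiteness, ``delta`` is halved (up to 20 times); the
    applied per-edge delta is recorded in ``planted_edges``.
    """
    pairs = [(int(e[0]), int(e[1])) for e in edges]
    n = model.n_regions
    for i, j in pairs:
        if i == j or not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"invalid edge ({i}, {j})")
    if delta == 0 or not pairs:
        return PrecisionModel(model.precision.copy(),
                              model.community_labels.copy(),
                              [(i, j, 0.0) for i, j in pairs])
    applied = float(delta)
    for _ in range(21):
        p = model.precision.copy()
        for i, j in pairs:
            p[i, j] += applied
            p[j, i] += applied
        if np.linalg.eigvalsh(p)[0] > 0:
            return PrecisionModel(p, model.community_labels.copy(),
                                  [(i, j, applied) for i, j in pairs])
        applied /= 2.0
    bad = max(pairs, key=lambda e: abs(model.precision[e[0], e[1]]))
    raise ValueError(
        f"cannot keep precision positive-definite after shrinking delta; "
        f"offending edge {bad}")


def _motion_regressors(rng: np.random.Generator, t: int) -> np.ndarray:
    """Six smoothed random walks mimicking realignment parameters."""
    walk = np.cumsum(rng.normal(0.0, 0.05, size=(t, 6)), axis=0)
    kernel = np.ones(5) / 5.0
    smooth = np.empty_like(walk)
    for c in range(6):
        smooth[:, c] = np.convolve(walk[:, c], kernel, mode="same")
    return smooth


def _drift(rng: np.random.Generator, t: int, tr: float,
           amplitude: float) -> np.ndarray:
    """Linear ramp plus two sinusoids below 0.01 Hz (one column)."""
    time = np.arange(t) * tr
    d = amplitude * np.linspace(-1.0, 1.0, t)
    for _ in range(2):
        f = rng.uniform(0.002, 0.01)
        phase = rng.uniform(0, 2 * np.pi)
        d = d + amplitude * np.sin(2 * np.pi * f * time + phase)
    return d


def _lowpass_shape(x: np.ndarray, tr: float, band_hz: float) -> np.ndarray:
    """Restrict a series' spectrum to (0, band_hz], preserving total variance.

    Resting-state regional signals are low-frequency dominated; shaping the
    latent multivariate-normal draw into the band keeps its cross-regional
    covariance (each retained frequency bin carries the full spatial
    covariance; the rescale restores overall power).
    """
    t = x.shape[0]
    freqs = np.fft.rfftfreq(t, d=tr)
    mask = (freqs > 0) & (freqs <= band_hz + 1e-12)
    if not mask.any() or mask.all():
        return x
    spec = np.fft.rfft(x, axis=0)
    spec[~mask, :] = 0.0
    frac = (mask.sum() + 0.0) / max(len(freqs) - 1, 1)
    return np.fft.irfft(spec, n=t, axis=0) / np.sqrt(frac)


def simulate_cohort(model_a: PrecisionModel, model_b: PrecisionModel,
                    spec: CohortSpec,
                    region_labels: list[str] | None = None) -> Cohort:
    """Simulate a two-group cohort of regional time series.

    Each subject's series is a multivariate-normal draw from the group
    covariance (inverse of the group precision), spectrally shaped into the
    low-frequency band ``signal_band_hz`` (set 0 to keep it white), plus
    drift, white noise, and a leak of the subject's six synthetic motion
    regressors. Identical spec and seed give bit-identical cohorts.
    """
    if model_a.n_regions != model_b.n_regions:
        raise ValueError("groups must share the region set")
    n = model_a.n_regions
    labels = region_labels or default_region_labels(n)
    if len(labels) != n:
        raise ValueError("region label count mismatch")
    t = spec.n_timepoints

    subjects: list[TimeSeriesMatrix] = []
    groups: list[str] = []
    motions: list[np.ndarray] = []
    chol = {"A": np.linalg.cholesky(model_a.covariance()),
            "B": np.linalg.cholesky(model_b.covariance())}
    for s_idx in range(2 * spec.n_per_group):
        group = "A" if s_idx < spec.n_per_group else "B"
        rng = child_rng(spec.seed, "cohort-subject", s_idx)
        z = rng.standard_normal((t, n))
        x = z @ chol[group].T
        if spec.signal_band_hz > 0:
            x = _lowpass_shape(x, spec.tr_seconds, spec.signal_band_hz)
        if spec.drift_amplitude > 0:
            for c in range(n):
                x[:, c] += _drift(rng, t, spec.tr_seconds,
                                  spec.drift_amplitude)
        if spec.highfreq_noise_sd > 0:
            x += rng.normal(0.0, spec.highfreq_noise_sd, size=(t, n))
        motion = _motion_regressors(rng, t)
        if spec.motion_leak_sd > 0:
            loading = rng.normal(0.0, spec.motion_leak_sd, size=(6, n))
            x += motion @ loading
        sid = f"sub-{s_idx + 1:03d}"
        subjects.append(TimeSeriesMatrix(x, list(labels), spec.tr_seconds, sid))
        groups.append(group)
        motions.append(motion)
    return Cohort(subjects, groups, motions, model_a, model_b, spec)
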