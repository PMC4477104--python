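# Methods

This note documents the models, estimators, numerical conventions and
design choices behind `fcgraph`, and what the synthetic cohorts do and do
not establish about real data.

## The analysis model

The pipeline treats each subject as a T × N matrix of regional signals
(default T = 200 retained timepoints at TR = 2 s, N = 90 regions — the
standard whole-brain parcellation scale). Connectivity is the partial
correlation between regions: with Ω the inverse covariance (precision),

    ρ_ij = − Ω_ij / sqrt(Ω_ii · Ω_jj).

Partial correlation removes the linear influence of all other regions, so
it is the natural estimand when ground truth is parameterised by a sparse
precision matrix — recovery tests are then exact in expectation.

With T ≈ 2N the sample covariance is near-singular. Signals are
standardised per region (this makes the estimator exactly invariant to
affine rescaling of any region's signal) and the correlation matrix is
shrunk toward the identity with the Ledoit–Wolf analytic intensity before
inversion. The realised intensity is recorded in each matrix's
`estimator_note`. A plain Pearson estimator is available
(`estimator.method = "pearson"`), partial correlation being the default.

### Thresholding and the sparsity grid

A weighted graph at sparsity S keeps the K = round(S·N(N−1)/2) largest
|ρ| entries (half-up rounding; ties broken lexicographically by (i, j) so
results are reproducible) with edge weight |ρ|. Storing absolute values
keeps all retained weights in (0, 1] and edge lengths 1/w well defined;
sign information is not used by the topological metrics but is retained in
the connectivity matrices, where the NBS stage reads it.

The admissible grid is the maximal contiguous candidate range on which
(a) group-mean small-worldness σ exceeds a floor (default 1.1) and (b) the
mean binary degree 2K/N exceeds 2 ln N (natural log by default; the base
is configurable). The degree criterion is deterministic given N and S; σ
is evaluated per subject with a reduced null ensemble (default 10) and
averaged. Both criteria target ~90-node networks: at N ≲ 25 the degree
bound forces networks so dense that σ cannot exceed 1.1, so the bundled
demo uses a fixed grid instead (`demo_config`).

### Graph metrics

* **Clustering C_p** — Onnela geometric-mean-of-triangle-weights form on
  weights normalised by the network maximum; nodes with degree < 2 score 0.
  The arithmetic (Barrat) variant is available via `clustering_variant`.
* **Distances** — edge length 1/w, all-pairs Dijkstra. **L_p** is the mean
  over *reachable* pairs only (keeps L_p finite on fragmented graphs);
  the efficiencies use 1/∞ = 0 and need no convention.
* **E_glob** — mean inverse distance over all ordered pairs; nodal
  efficiency is its per-node row mean, so the node average equals E_glob
  exactly. **E_loc** — mean over nodes of the global efficiency of the
  node's neighbourhood subgraph (node removed).
* **Betweenness** — weighted Brandes accumulation (fractional counting of
  tied geodesics, endpoints excluded, unnormalised counts).
* **Degree** — binary incident-edge count, not strength; the estimability
  criterion 2 ln N only makes sense for counts.
* **γ, λ, σ** — ratios against the mean of (default) 100 degree-preserving
  null networks: double-edge swaps (a compiled kernel; target 10 successful
  swaps per edge, budget 100× attempts, a warning reports shortfalls on
  rigid graphs) followed by random reassignment of the original weight
  multiset to the rewired edges. Nulls whose L_p is undefined are resampled
  within a 5× budget.
* **AUC** — trapezoid sum Σ [Y(S_k) + Y(S_{k+1})]·ΔS/2; exactly
  c·(S_n − S_1) for constant curves and exact for linear ones.

### Inference

Group comparisons are two-tailed permutation tests on AUC values: labels
are reallocated preserving group sizes (default 10,000 times) and

    p = (1 + #{|null diff| ≥ |observed diff|}) / (1 + n_perm),

the add-one form that cannot return zero. The 95th percentile of |null| is
reported as the critical value. The seven global metrics are reported
without multiplicity correction (each p is raw, by design). For nodal
centralities, one shared set of label permutations is used across the N
nodes of a metric (valid because exchangeability is over subjects, and
orders of magnitude faster); BH-FDR at q = 0.05 is applied per centrality
across nodes, and a region is *altered* when any of degree, efficiency or
betweenness survives — three families matching the three reported p-value
columns, with the union rule for selection.

### Network-based statistic

Edge statistics are pooled-variance two-sample t values on the raw signed
partial correlations (not the thresholded absolute weights), positive t
meaning group A > group B. Screening is two-sided at |t| ≥ T (default 1.6)
with per-edge increase/decrease labels; component size is the edge count
(extent). Significance is family-wise: the permutation null records the
maximum component size per relabelling, and each observed component is
compared against that single distribution (add-one p as above). The
max-size null search uses an internal union-find; the user-facing
component extraction uses networkx and is checked against an independent
union-find oracle in the tests.

**Why NBS runs on the altered-node universe.** At a primary threshold of
T = 1.6 the null supra-threshold edge rate is ≈ 0.12 (df ≈ 20–40), so on a
whole 30–90-node universe the null supra-threshold graph has mean degree
well above 1 and *percolates*: nearly every permutation produces one giant
component, and extent-based FWE has essentially no power. Restricting the
edge universe to the FDR-selected altered regions (the pipeline's default,
`nbs.scope = "altered"`; a whole-network mode exists) keeps the null
subcritical and is what makes a threshold as low as 1.6 usable. This is a
property worth knowing when interpreting two-stage analyses of this form.

## The synthetic cohort generator

Ground truth is the precision matrix. `make_precision_model` draws a
target partial-correlation matrix R with community structure — near-complete
small blocks (default: within-block pairs present with probability 0.9 at
strength ≈ 0.4 before scaling; rare weak between-block links) — and sets
Ω = I − R after rescaling R to spectral radius 0.9 if needed, which
guarantees positive-definiteness and makes the true partial correlation of
every pair equal R exactly. Mutually high partial correlations inside a
block are not jointly attainable (the spectral bound), so realised values
are ≈ 0.15–0.25 at study scale; `study_precision_model` uses 18 blocks of
5 regions, chosen so that thresholded networks are small-world (σ > 1.1
over a non-empty sparsity range) under realistic estimation noise — with
T = 200 timepoints band-limited to 0.08 Hz the effective sample size is
≈ 64, giving a per-edge estimation SD of ≈ 0.12, and only tight,
triangle-rich communities survive ranking noise.

Each subject's series is a multivariate-normal draw from the group
covariance Ω⁻¹, spectrally shaped into (0, 0.08] Hz (resting-state signal
is low-frequency dominated; shaping preserves the cross-regional
covariance and gives the band-pass filter a real job), plus a linear ramp
and two sub-0.01 Hz sinusoids (drift, amplitude 1.0), white noise
(SD 0.3), and a leak of six smoothed-random-walk motion regressors
(loading SD 0.2) that the nuisance regression must remove. Group effects
are planted by adding δ to chosen precision entries, which shifts exactly
those pairs' partial correlations and no others; δ is halved (≤ 20 times)
if positive-definiteness would be lost, and the applied value is recorded.

What the generator does **not** emulate: hemodynamic response functions,
voxel-level spatial structure, motion spikes/artefacts, non-Gaussian or
non-stationary signals, site/scanner effects. Passing tests therefore
establish the correctness and calibration of the estimators and inference
machinery under a known sparse-precision world, not the sensitivity of the
pipeline to real pathology.

## Calibrations and problem sizes

* **Planted-effect size.** The NBS power studies use a connected 7-node,
  10-edge component with δ = −0.22 on a 30-region base model with lighter
  community structure (strength 0.25, density 0.5, leaving spectral
  headroom so δ applies unshrunk). At 10 subjects per group this yields a
  mean per-edge |t| ≈ 3, the regime the power analysis targets; it was
  calibrated once against that t-level and then frozen.
* **Test scales.** The suite verifies metric implementations against
  exhaustive oracles on 200 random ≤ 8-node graphs; permutation type-I
  error on 1,000 null comparisons (10 vs 10, 500 permutations); NBS FWE on
  200 null cohorts and power on 25 replicates (30 regions, 10/group); grid
  determination on a 90-region cohort with 3 subjects per group and
  reduced null ensembles (6–8) — sizes chosen to exercise study-scale
  behaviour at unit-test cost. The acceptance script runs the full
  pipeline at 90 regions, 20 per group, with 20 nulls per σ evaluation and
  10,000 permutations.
* **Global-difference experiment.** The acceptance script weakens one
  group's partial correlations by a factor 0.85 — a modest, realistic
  global effect. Note an instructive artefact: weakening structured
  connectivity toward the estimation-noise floor makes the thresholded
  networks *more random*, which lowers C_p, γ, σ and E_loc but can
  slightly *raise* global efficiency (random graphs have short paths);
  direction of E_glob differences under global weakening is therefore not
  diagnostic in this world.

## Numerical conventions and degenerate inputs

* Band-pass is a hard FFT mask (bit-exact, no filter-family parameters);
  the DC bin is always removed, so outputs are mean-centred. The default
  band starts at 0.0 Hz, so drift components above ~1/T Hz survive the
  default band — the drift in the generator is calibrated to be mild, and
  a 0.01 Hz low cut is available where drift removal matters.
* Zero-variance regions raise with the region named; rank-deficient
  nuisance designs warn and fall back to the pseudo-inverse; collinear
  regions warn and rely on shrinkage.
* γ is undefined if the entire null ensemble has zero clustering (possible
  on very sparse small graphs); configurations are chosen away from that
  regime and the AUC operation rejects non-finite curves loudly.
* All randomness flows from one integer seed through named, keyed
  substreams (`_seeds.child_seed`), so re-running a late stage never
  perturbs an earlier stage and staged CLI runs numerically reproduce the
  one-shot pipeline.
* Zero pooled variance on an edge gives t = 0 with a warning; permutation
  tests on constant data return p = 1 with a warning.

## Known limitations

* Partial correlations at N = 90, T = 200 are heavily noise-dominated
  (effective SNR per edge < 2 even for strong true connections); the
  admissible sparsity range on synthetic cohorts is correspondingly narrow
  (typically S ≈ 0.11–0.15).
* The nodal-centrality FDR screen has limited power against effects that
  are strong per edge but touch few edges per node; with a 10-edge planted
  component it typically selects only a subset of the affected regions.
  The NBS stage conditioned on a correct screen is well powered (see the
  acceptance script's paired quantities).
* L_p's reachable-pairs convention makes values from graphs with different
  fragmentation not strictly comparable; the efficiency metrics are the
  robust alternative and are always reported alongside.
* The rewiring null preserves the binary degree sequence and the weight
  multiset but not weight-degree correlations.
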