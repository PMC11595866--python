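# Methods

`lungmorph` quantifies the morphometric complexity of lung parenchyma on
chest CT and relates it to time-to-event outcomes (radiation pneumonitis,
RP). This note documents the models, the parameters that matter, the
synthetic data used for validation, and the numerical choices made where
the underlying procedure left the design open.

## Normal Attenuation Area (NAA)

Intact lung parenchyma is segmented by attenuation alone: a voxel belongs
to the NAA iff its value lies in the half-open interval
**(−950 HU, −700 HU]** — strictly above −950 (excluding emphysema-like
low attenuation and air) and at most −700 (excluding consolidation,
fibrosis, vessels and soft tissue). The boundary semantics are exact and
are exercised by fixtures that place voxels at exactly −950 (excluded)
and −700 (included). An optional region-of-interest mask (e.g. a lung
segmentation) can restrict the threshold; by default none is applied,
since thresholding alone already excludes outside-body air and soft
tissue. Which choice was used is recorded in the run manifest.

Volumes are kept on their reconstructed grid; no resampling is performed
and voxel spacing (default 1.0 × 1.0 × 2.5 mm) is carried as metadata.
All three estimators below operate in voxel index space. This is a
deliberate, recorded limitation: with anisotropic voxels the indices are
properties of the reconstruction grid, which is why a fixed acquisition
protocol matters when comparing subjects. `estimate_mst_dimension`
accepts `physical=True` to weight steps in millimetres for sensitivity
analyses.

## Box-counting fractal dimension

The mask is covered by an axis-aligned grid of ε-cubes anchored at the
array origin (boundary cubes truncated; a partial cube counts if it
contains foreground). With N(ε) the number of occupied cubes,

    FD_box = slope of log N(ε) vs. log(1/ε)   (OLS over the ladder).

Choices: a single grid offset (no offset averaging), which keeps all
counts integers and exactly reproducible; the default ladder is powers
of 2 from 1 to ⌊min(shape)/4⌋ with at least four rungs. Exactly
self-similar phantoms (Menger sponge) are evaluated on the powers-of-3
ladder, where counts have closed forms (20^(level−k) at ε = 3^k) and the
fitted dimension equals log 20 / log 3 to 1e−9. FD_box is bounded by 0
and 3 for consistent counts; degenerate ladders (all counts equal) are
rejected rather than fitted.

## Gliding-box lacunarity

A cubic box of edge ε glides over all (shape − ε + 1) positions; the box
mass is the foreground count inside. Lacunarity is the relative variance
of the mass distribution,

    Λ(ε) = σ²(ε) / μ²(ε),

zero iff all boxes carry equal mass and larger for gappier, more
clustered arrangements. Among the σ/μ² and (σ/μ)² readings seen in
typeset definitions of this statistic, the standard gliding-box relative
variance Λ = σ²/μ² is used — the reading under which "higher Λ means
more heterogeneous" holds. Boxes overlapping empty space are included (mass
0 is an observation). Only axis-aligned cubic boxes are used, so the
orientation index of rotational-invariance constructions is degenerate
here; rotated boxes are out of scope. The per-subject aggregate is the
unweighted mean of Λ(ε) over the ladder (default: powers of 2 from 2 to
⌊min(shape)/4⌋); the full curve is always emitted so any other reduction
can be recomputed. Masses are computed exactly with an integer
integral-volume table, so Λ carries no floating-point accumulation error
beyond the final division.

## MST fractal dimension

From the largest 26-connected component of the mask, N_R voxels are
sampled uniformly without replacement. The distance between two sampled
voxels is the shortest path **through the mask** — 26-connected steps
weighted 1, √2, √3 — not the Euclidean chord, so the metric respects
obstacles and disconnections in the parenchyma. The minimum spanning
tree of the sampled nodes under this geodesic metric has m = N_R − 1
edges with lengths l_i, and the mean edge length

    S(m) = (1/m) Σ l_i

decays as S(m) = C·m^(−1/h) for a set of dimension h: the nearest-link
scale of m points spread through a d-dimensional set shrinks as m^(−1/d).
Hence h = −1/slope of the OLS fit of log S̄(m) against log m, with S̄(m)
averaged over independent replicate samples at each scale. The scaling
exponent is implemented with unit numerator (α = 1) and the decaying
sign, the standard MST-dimension form; a non-negative fitted slope means
no decay, in which case h is reported as NaN with the full fit attached.

Defaults: N_R ∈ {16, 32, 64, 128, 256, 512}, 8 replicates per scale,
independent samples per scale (nested subsets would correlate the errors
across m), one master seed with per-(N_R, replicate) derived streams, so
identical inputs give bit-identical results.

**Exact fast path.** Estimation does not build the N_R × N_R distance
matrix. For each replicate, one multi-source Dijkstra sweep from the
sampled nodes yields the geodesic Voronoi partition of the component;
every mask edge crossing two Voronoi cells proposes a candidate
node-to-node connection of weight d(s,u) + w(u,v) + d(v,t). The MST of
this candidate network has exactly the same total weight as the MST of
the complete geodesic distance graph (Mehlhorn's distance-network
construction), and S(m) depends only on that total. The exact pairwise
route remains available (`geodesic_distance_matrix` + `mst_edge_lengths`)
and the test suite asserts equality of the two routes to 1e−9 on masks
with and without obstacles. The fast path makes the default grid on a
64³ solid cube (~260k voxels) run in about a minute on one core instead
of tens of minutes.

Validation: at the default grid the estimator recovers the analytic
dimensions of a digital line (1), a one-voxel slab (2) and a solid cube
(3) within ±0.25, preserves their strict ordering, and places a level-3
Menger sponge strictly between the slab and cube estimates. Finite-size
bias is visible at these scales (e.g. the cube estimates near 2.75—2.8
rather than 3.0, since m ≤ 511 points in 262k voxels sit well short of
the asymptotic regime); the estimator is used as a comparative index, as
in the downstream association stage, not as an unbiased measurement of
topological dimension.

## Synthetic phantoms and cohorts

The phantoms module provides every ground-truth input the tests and the
acceptance script need:

* `menger_sponge(level)` — 20^level voxels on a (3^level)³ grid; exact
  box counts and closed-form dimension log 20 / log 3 ≈ 2.7268.
* `reference_set(cube|slab|line, extent)` — analytic dimensions 3/2/1.
* `fractal_percolation(b, p, levels, seed)` — Mandelbrot percolation
  with expected dimension log(b³p)/log b and branching-process mass
  expectation (b³p)^levels, used as a randomized phantom.
* `mask_to_hu(mask, seed)` — renders any mask as an HU volume whose NAA
  is exactly that mask: foreground uniform on (−950, −700] with one
  voxel pinned at −700, background alternating −1000/+40 with one voxel
  pinned at −950, so both interval boundaries are exercised on every
  round trip.
* `simulate_cohort(spec)` — exponential event times with multiplicative
  hazards: baseline 0.02/month, hazard ratio `hr_low_stratum` (default
  2.3) for subjects whose primary index falls below the cohort median,
  optional log-linear covariate effects, administrative censoring at a
  24-month horizon. The default censoring mode draws a uniform
  staggered-entry censor within the horizon, giving roughly a 35%
  grade ≥ 2 event fraction at the defaults (about 61 events per 175
  subjects); `censor_mode="horizon"` censors everyone at the horizon,
  under which the observed event fraction has the closed form
  1 − exp(−λ·horizon) used in tests. Covariate marginals default to a
  population resembling the intended clinical setting (76% male, 53.7%
  ever-smokers, 29.1% COPD, 8.6% IPF, 53.1% stage I–II, 20.6% SABR).
  Index values are drawn continuous, so the median split is unambiguous;
  the tie rule is still tested separately. Because event times are
  exponential with multiplicative hazards, the data-generating process
  satisfies proportional hazards exactly, which is what makes the
  Schoenfeld type-I calibration meaningful.

What the phantoms do **not** emulate: anatomy (airways, vessels, lobes),
scanner noise and kernel effects, dose distributions, and informative
censoring. Passing tests therefore demonstrate correctness of the
estimators and of the statistical machinery under their stated
assumptions, not clinical performance on real scans.

## Survival association stage

Each index is dichotomized at the sample median; values equal to the
median join the upper stratum, so 175 distinct values split 88 upper /
87 lower, with the upper (higher-complexity) stratum as the reference
level. Kaplan–Meier curves per stratum are compared by the two-sample
log-rank test. Cox proportional-hazards models are fit by partial
likelihood with Efron tie handling (Newton iterations, convergence
precision 1e−12), reporting HR = exp(β) with Wald 95% CIs
exp(β ± 1.96·se) and p-values, Harrell's C (ties in risk counted 1/2),
and per-term Schoenfeld-residual PH tests with the identity time
transform. Model fitting is delegated to lifelines; the test suite pins
the wrapper against independent oracles: a 1-D partial-likelihood grid
maximizer, the score-test = log-rank identity (to 1e−6), a hand-worked
product-limit table, an explicit risk-table log-rank, and exhaustive
O(n²) concordance enumeration.

The adjusted model uses age, sex, smoking status, underlying lung
disease (none/COPD/IPF), radiotherapy technique (SABR/IMRT), clinical
stage (I–II/III), histology, and DLCO% (continuous), expanded against
fixed reference levels. With few events (the grade ≥ 3 threshold) this
model can be unidentifiable (monotone likelihood); cohort runs emit a
flagged row rather than aborting, and single fits raise with the
solver's diagnosis rather than reporting silently.

Calibration measured by the acceptance suite at the defaults: over 200
simulated cohorts (n = 175, true HR 2.3) the mean estimated ln HR is
within 10% of ln 2.3 with Wald CI coverage near 0.95; log-rank and
Schoenfeld type-I error rates under their nulls lie in [0.03, 0.07] at
α = 0.05.

## Problem sizes and determinism

The validation suite uses a 64³ cube (262,144 voxels) as its largest
MST input and 175-subject cohorts with 200–1000 replications for the
statistical calibrations; these sizes put every scaling regime on
display while keeping a full run in the minutes range on a single core.
All stochastic steps take explicit integer seeds and derive independent
streams per scale/replicate; identical configurations reproduce outputs
byte-identically, and the CLI writes a JSON manifest of every resolved
parameter (thresholds, ladders, node grids, seeds, ties method) with
each run.

## Known limitations

* Indices are grid-quantities: anisotropic spacing is ignored by default
  (consistent across subjects only under a fixed protocol).
* The ε fit range and the N_R grid influence the absolute values of
  FD_box and h; both are logged with every result, and comparisons
  should hold them fixed.
* Lacunarity's reduction to a single per-subject number (mean over the
  ladder) is one of several defensible choices; the per-ε curve is
  always emitted.
* The MST dimension estimator is finite-size biased toward low values on
  space-filling sets at small N_R; it is validated as a rank-preserving
  comparative instrument.
* No lung segmentation is bundled; on real scans an ROI mask should be
  supplied to exclude non-pulmonary voxels in the NAA interval (e.g.
  bowel gas, trachea).
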