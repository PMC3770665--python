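# Methods

This note records the statistical model behind `restflow`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Design and coordinates

The design has six conditions — no flow (NF), rest-inserted flow (RF) and
continuous flow (CF), each at two time points (immediately post-flow, one
hour post-flow) — with one pooled sample per condition and therefore no
replicates. All inference is distributional and gene-set based; no per-gene
significance testing is attempted.

Per-gene log2 flow/no-flow ratios `x_t = CF_t − NF_t`, `y_t = RF_t − NF_t`
(differences of log2 expression) are time-averaged to `x, y`. Averaging two
time points halves the variance contributed by independent per-time-point
fluctuation while preserving sustained differences, which trades sensitivity
to single-time-point responders for selectivity.

The 45° rotation `x' = (x+y)/√2`, `y' = (y−x)/√2` is *unitary* so that it is
an isometry and invertible to machine precision. The analysis only requires
the rotated coordinates to scale with distance along/from the diagonal, so
the normalization constant is exposed (`transform.ROTATION_SCALE`); the
aspect ratio and all relative distributions are invariant to it. The sign
convention makes `y' > 0` mean "up-regulated by rest insertion", so Group A
(positive tail) is the rest-up signature.

The "bounding ellipse" is computed literally as the axis-aligned ranges in
the rotated frame, `x'max − x'min` and `y'max − y'min`, not as a
least-squares ellipse fit. These ranges are sometimes described as
semi-axes although they are full ranges; the summary therefore reports both
the ranges (`extent_*`) and their halves (`semi_axis_*`). Profile variances
are pooled as the mean of per-profile sample variances (ddof = 1): over
{x, y} for the time-averaged value and over {x0, x1, y0, y1} for the
single-time-point value.

## Preprocessing

Fixed order: quantile normalization → flooring (linear intensities below 10
set to 10) → log2 → detection filter → annotation filter, with probe counts
recorded at each stage. The detection filter keeps a probe when *any* sample
has detection p strictly below 0.01 (the strict reading of "less than").
Quantile normalization maps each column onto the row-mean of the
column-sorted matrix; ties within a column receive the mean of the reference
values of their tied ranks, a standard convention chosen because it makes
identical inputs map to identical outputs. Probes whose symbol is missing,
empty, or carries the reserved "unnamed cDNA clone" prefix are removed;
distinct probes sharing a symbol are kept as distinct rows (no collapsing).

`run_preprocess` exposes two switches used for *matched* preprocessing of
simulated data: `quantile=False` and `floor=None`. Noise-free simulated
columns differ only by bounded ratio shifts, and forcing them onto a common
reference distribution (or clamping a low-intensity stratum) would distort
exact ratio recovery; with the switches off the pipeline recovers generated
coordinates to ≤1e−6. On real data both steps should stay on.

## Synthetic data generator

The generator is the package's test bed: it emits the six-condition
intensity matrix, detection p-values, probe annotations and a ground-truth
table. Each detected gene receives a true common score x'\* and differential
score y'\*; the inverse rotation gives true (x, y); independent Gaussian
noise of variance `noise_var_per_timepoint` is added to each of the four
ratios; and intensities are `NF_t = 2^b`, `CF_t = 2^(b + x_t)`,
`RF_t = 2^(b + y_t)` with baseline `b ~ N(8, 1.5)` log2 units for detected
probes — well above the flooring threshold so flooring cannot distort
ratios. Undetected probes are dimmer (mean 4 log2 units) with a 5% stratum
near 1 log2 unit that sits below the floor and exercises the clamp.

Score distributions: x'\* is truncated standard normal (±3σ) and y'\* is
truncated Laplace (±4 scale units), both affinely rescaled so their sample
spans equal `common_extent` and `differential_extent` *exactly* — extents
are recovered identically on noise-free data. The Laplace choice gives the
differential axis heavier mass near zero than the common axis, reproducing
the qualitative structure under study (many small differential changes, a
mean-magnitude ratio near one half, relative density above 1 at low
quantiles and below 1 at high quantiles). Both distributions are
configurable.

Defaults emulate the study conditions: 45,281 probes, 34.6% passing
detection, 23.7% unannotated, spans 0.52 × 0.29 log2-ratio units, and
`noise_var_per_timepoint = 1e−3`. The noise default is a compromise made
once: the two calibration observations the generator must support —
(a) time-averaging halving a profile variance of ~8e−3 to ~4e−3 and (b) an
elliptical cloud with aspect ratio near 1.8 — are mutually inconsistent
inside this generator, because its ratio noise is independent across x and y
and therefore splits evenly between the rotated axes (noise-dominated data
would have aspect ratio 1). The variance-halving condition is therefore
exercised with zero signal spread and noise 8e−3 (where the halving is exact
in expectation), while the geometry and distribution-shape conditions use
the default small noise where signal dominates. With the defaults the total
time-averaged profile variance lands at ~5e−3, the right order of magnitude.

Planted sets shift the true y' of randomly chosen detected, annotated genes
by ±`effect_size`, and `planted_collection` packages them with random decoy
sets into a GMT-style collection for end-to-end enrichment recovery tests.
Detection p-values are Uniform(0, 0.01) in one random sample for detected
probes and Uniform(0.01, 1) elsewhere — the filter only needs the threshold
crossed. What the generator does *not* emulate: bead-level replicate
structure, background subtraction, scanner artifacts, pooling variance
across the three pooled experiments per condition (one sample per condition
is emitted), and probe-to-gene many-to-one mappings (symbols are unique per
probe). Passing tests therefore validate the analysis logic, not robustness
to those artifacts.

## Distributions

Magnitude densities use a Gaussian kernel with Silverman's rule-of-thumb
bandwidth on a 512-point grid over [0, 1.1·max], without boundary
reflection, and are renormalized on the grid (trapezoid) so the reported
curve integrates to 1 despite the small leak of kernel mass below zero.
Degenerate samples (zero spread) raise an explicit error. KS tests use the
exact two-sample null when both samples have ≤100 values, the asymptotic
approximation otherwise.

The relative distribution of a query against a reference is estimated by the
grade transform: query values are pushed through the reference empirical CDF
and the density of the resulting grades on (0, 1) is estimated with a
reflected Gaussian kernel (reflection at both boundaries, standard practice
for relative distributions). This is numerically stable where the reference
density is small; a pointwise KDE-ratio estimator evaluated at the reference
quantiles is provided as an independent cross-check mode, and the two agree
away from the boundaries. Grid size defaults to 100 quantile midpoints.

## Groups and enrichment

With N analyzed genes and selection fraction f (default 0.01), Group A takes
the ⌈fN⌉ genes with the largest y' and Group B the ⌊fN⌋ with the smallest —
the ceiling/floor asymmetry is a convention fixed here because it uniquely
reproduces a 120/119 split at N = 11,970; ties break deterministically by
gene id. Membership is sign-restricted (A members must have y' > 0, B
members y' < 0); an exhausted tail truncates the group with a warning rather
than crossing zero.

Over-representation uses the upper-tail hypergeometric probability
P(X ≥ k) for overlap k between a query of size n and a set of size m in a
universe of N genes, with Benjamini–Hochberg FDR across the sets of a
collection. The universe is the post-filter analyzed gene list — what could
have been selected — not the whole array. Gene symbols are matched
case-insensitively; set members absent from the universe are dropped with a
logged count. Pathway-membership collections and perturbation-response
signature collections run through the same statistic (the `mode` flag is
metadata only). The hypergeometric p-value is discrete, hence conservative:
under a uniform null the rejection fraction at level α equals the largest
attainable tail probability below α, which approaches α only as the counts
grow; the test suite checks calibration against this exact discrete value
rather than against α itself.

The sensitivity sweep evaluates the top-k prefix of a ranked tail for
k = 5, 10, …, 200 (configurable), reporting the per-set FDR trajectory, the
first size reaching FDR < 0.05 and the size attaining the minimum FDR
(smallest size on ties).

## Assay closed forms

The orbital-shaker maximal wall shear stress is `τ = a·√(ρη(2πf)³)` with
inputs accepted in bench units (cm, poise, g/ml, Hz) and converted to SI
internally; at f = 2.2 Hz, a = 0.95 cm, η = 0.01 P, ρ = 1.0 g/ml it gives
0.488 ≈ 0.5 Pa. It is a first-order estimate that ignores fluid height and
well radius. qPCR quantification is `2^(−ΔΔCT)` with ΔCT = target −
housekeeping per condition and ΔΔCT = treated − control.

## Reproducibility and problem sizes

All randomness flows through a single integer seed (`numpy.random.
default_rng`); identical configurations yield byte-identical reports, and
the run log records package version, parameters and seed without
timestamps. Tests and the acceptance script use scaled problem sizes chosen
to make sampling error negligible for each check: 20,000 genes for the
variance-halving and distribution-shape checks, 10,000 for extent recovery,
10,000 Monte-Carlo replicates for null calibration, and full printed sizes
(45,281 / 15,686 / 3,716 / 11,970) for the filter-accounting arithmetic.
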