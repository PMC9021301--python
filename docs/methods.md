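# Methods

## Overview

`wayfind` reimplements, as a tested pipeline, an analysis linking
naturalistic driving behavior in older adults to resting-state
functional connectivity (rsfc): 30-second GPS breadcrumb logs are
reduced to per-trip route-selection metrics, compressed to one summary
row per driver, joined to a 13x13 network-connectivity feature matrix,
and screened with a bootstrap-lasso stability-selection procedure.
Because no raw driving or MRI data ships with the package, a synthetic
study generator with planted, generator-known effects stands in for
the study inputs; every stage of the pipeline is exercised against it.

## Trip metrics

A *trip* is a sequence of timestamped GPS fixes (nominally every 30 s)
with instantaneous speeds in mph. From each trip:

* **Route straightness** = haversine(origin, destination) / driven path
  length, where the driven path length is the chain of great-circle
  distances between consecutive fixes. Straightness is 1 for a
  perfectly direct route and lies in (0, 1] whenever the endpoints
  differ. Out-and-back loops (identical endpoints) are assigned
  straightness 0 and flagged rather than erroring, so driver-level
  medians remain defined.
* **Actual-optimal distance ratio** = driven path length / length of
  the *time*-optimal route between the trip's endpoints snapped to the
  road network. Routing minimizes predicted travel duration — the
  quickest route, not the shortest — so the shortest-distance path can
  beat the quickest one in length and ratios slightly below 1 occur.
* **Actual-optimal time ratio** = observed trip duration / free-flow
  duration of the time-optimal route.
* **Driving events.** The study's telematics vendor computed event
  counts with a proprietary rule, so events are re-derived here from
  epoch-to-epoch speed deltas: a hard brake (acceleration) is a
  decrease (increase) exceeding a threshold, default 15 mph per 30-s
  epoch; an epoch is overspeeding when its recorded speed exceeds the
  nearest edge's posted limit plus a tolerance (default 0 mph), and an
  overspeeding *event* is a maximal run of such epochs. These are
  documented proxies, and the synthetic generator plants events under
  the same rule.

All geometry uses the haversine formula on a sphere of radius
6,371,008.8 m (IUGG mean). Meters are used internally; miles
(1609.344 m) appear only in reported summaries.

### Known approximations

* 30-second sampling cuts corners: the breadcrumb chain is shorter
  than the road-constrained path, so distance ratios carry a small
  downward bias (about 1–3 % at the default trip scale). This is a
  property of the measurement process being emulated, not a defect.
* Endpoint matching is nearest-*node* snapping, adequate for the
  synthetic grids used here; real data would want nearest-edge
  projection or proper map matching.

## Driver summaries

Per driver: medians of distance, straightness, and both ratios; means
of the four event rates; trips per year; radius of gyration (RMS
haversine distance of all breadcrumbs from their coordinate centroid —
the standard human-mobility definition; trip-endpoint-only mode is
available since the source of the original figure is unstated); and
destination uniqueness by greedy fixed-radius clustering of trip
endpoints in time order (an endpoint joins the first cluster whose
seed is within 250 m, else seeds a new cluster). Missing per-trip
metrics (failed routing) are excluded pairwise. Medians use the
midpoint convention for even counts.

## Connectivity features

ROI time series → Pearson ROI-pair correlations → network blocks:
block (i, j) is the inverse-Fisher transform of the mean Fisher z over
all ROI pairs spanning networks i and j, self-pairs excluded on the
diagonal. The reduction rule is a package choice (standard practice);
a precomputed 13x13 matrix can be supplied directly, and in the
synthetic study it is. The 13 default labels (VIS, SMN, AUD, CO, SAL,
VAN, DAN, FP, DMN, SubCort, MTL, Reward, Unassigned) are illustrative
and configurable. Features are the row-major upper triangle including
the diagonal — 91 cells named `NETixNETj` with i ≤ j in network order —
plus driver age: 92 columns.

## Stability selection

For one response over n drivers, each of `n_iterations` (default 1000)
iterations:

1. draw a 2/3 training subsample without replacement (the wording
   "trained on 2/3 and tested on the remaining 1/3" implies
   subsampling; a classical with-replacement bootstrap is available
   but not default);
2. standardize features on the training split only (population
   variances; the same transform is applied to the held-out third —
   no leakage);
3. choose the lasso penalty by 10-fold cross-validation on the
   training split: a 100-point log grid from λ_max (the smallest
   penalty with an all-zero fit, max_j |X_jᵀy|/n) down to λ_max/1000,
   CV-minimum rule (the 1-SE rule is available); folds are capped at
   the training size for tiny cohorts;
4. fit at the selected penalty and record (a) the features with
   nonzero coefficients — "retained" — and (b) the MAPE,
   100·mean(|y−ŷ|/|y|), of the held-out predictions.

Retention counts over iterations rank feature stability; a response
with mean MAPE below 10 % is flagged as predictable. MAPE is undefined
for responses containing zeros (possible for event rates); such
responses are reported as ineligible rather than patched, mirroring
the original screening's implicit restriction to positive-valued route
metrics. Age is penalized exactly like the connectivity cells.
"Retained" means nonzero at the CV-selected penalty, not anywhere on
the path. The whole procedure is a deterministic function of (data,
parameters, seed).

### The solver

The lasso objective (1/2n)‖y − β₀ − Xβ‖² + λ‖β‖₁ is minimized by
cyclic coordinate descent with soft-thresholding (numba-compiled),
warm-started along the descending λ grid, with active-set sweeps
between full sweeps; convergence is a maximum coefficient change below
1e-7 in a full sweep. Within cross-validation, each path point has a
budget of 50 sweeps: warm starts converge in a handful of sweeps
except in the dense p > n tail of the grid (the interpolation regime),
where extra refinement cannot change which penalty minimizes the CV
curve. The tests verify the solver against an exhaustive sign-pattern
quadratic-program oracle on small problems, against ordinary least
squares at λ = 0, against the closed-form soft-threshold solution for
a single predictor, and against scikit-learn's implementation.

## Synthetic study generator

The generator emulates the study inputs at their reported scale — 64
drivers, about 3 years of enrollment (mean 3.01, SD 1.06, clipped at
1), 200 trips per driver, ages 60–85 — on a 17x17 street grid with
600 m blocks and speed-limit classes {25, 35, 55} mph.

Each driver carries two latent navigation traits, jointly normal with
correlation 0.25 (the two route metrics were only weakly correlated in
the study this emulates, so a single shared trait would be wrong):

* **Directness** controls trip geometry: the displacement between
  origin and destination is split between the two grid axes by a
  per-trip diagonality draw whose mean falls with the trait. On a
  lattice, near-axis trips have straightness near 1 and diagonal trips
  near 1/√2, so the driver's median straightness rises with
  directness.
* **Adherence** controls route choice: with probability falling in the
  trait, the driver routes via a waypoint placed 1–2 blocks *outside*
  the origin-destination bounding rectangle (excursion size growing as
  adherence falls). The waypoint construction is deliberate: on a
  uniform lattice every monotone staircase between two nodes has
  identical length, so removing edges of the optimal route and
  re-routing — the obvious detour mechanism — almost never changes the
  driven distance. Only an out-of-corridor excursion (a driver getting
  lost, or hugging familiar streets) inflates the actual-optimal
  distance ratio.

Kinematics: each trip is driven at a per-trip pace (Beta-distributed,
0.55–0.92 of the posted limit, median time ratio ≈ 1.3), with nominal
speed ramped at ≤ 10 mph per epoch (vehicles do not jump 30 mph in
30 s), near-standstill first and last fixes, and N(0, 1 mph) recorded-
speed noise. Hard brakes, hard accelerations and overspeeding bursts
are injected at per-trip Poisson rates set to the cohort means of the
emulated study (0.110, 0.0423, 0.394 per trip), at interior epochs
spaced ≥ 2 apart, with one-sided recovery ramps so an injected event
and its recovery cannot register as additional events.

Connectivity: background cells are N(template, 0.12) around a fixed
template (intra 0.45, inter 0.20); each planted cell is
template + β·z + ε, where z is the cohort-standardized trait aligned
with its response (the ratio effect tracks −adherence so that the
planted correlation is positive, matching the reported direction of
all three effects: VANxVAN(+) and SALxDAN(+) with straightness,
FPxSubCort(+) with the distance ratio). Defaults β = 0.16 with cell
noise 0.08–0.09 were chosen, once, so that the planted cell explains
roughly half of the response variance end-to-end given the measured
trait-to-response couplings (r ≈ 0.75 for straightness, ≈ −0.77 for
the ratio at the default study size). All values clip to [−1, 1].

### What the generator does not emulate

Real road topology (one lattice, no one-way systems or turn
restrictions), traffic and time-of-day structure, GPS position error,
scanner/preprocessing artifacts in connectivity, and any nonlinear or
multi-cell brain-behavior structure. Passing the planted-effect
recovery test therefore shows the *pipeline* recovers linear planted
signal at study scale under realistic noise — not that the original
biological findings replicate.

## Routing

Two implementations, one contract: `optimal_route` is an exact
Dijkstra with a lexicographic tie-break on the node sequence (the
reference; verified against brute-force path enumeration), and
`Router` precomputes all-pairs distances/predecessors with
scipy.sparse.csgraph for the simulator and batch pipeline (verified to
produce the same minimized totals; its tie-breaking among exactly
equal-cost routes follows the csgraph traversal order instead). Edge
travel time is length / speed-limit; no turn penalties or congestion.

## Problem sizes and determinism

The full analysis (64 drivers × 200 trips, 1000 iterations × 4
responses) is what `analysis/01_…05_*.py` run. The test suite
exercises the same code at the scales its checks need — e.g. 20
seeded replicates of the default study with 200 stability iterations
for planted-effect recovery, and 10,000 trips for the straightness
bound — chosen to keep the whole suite comfortably re-runnable on one
CPU. Every random quantity flows from an explicit integer seed through
`numpy.random.default_rng`; identical (data, parameters, seed) gives
bit-identical results, which the tests assert.
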