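# wayfind

Route-selection metrics from naturalistic GPS breadcrumb logs, and
their association with resting-state functional connectivity (rsfc)
via bootstrap-lasso stability selection.

## The problem

Older adults' everyday driving leaves a rich movement record: a GPS
logger in the car emits a fix (time, position, speed) every 30 seconds.
Movement ecology summarizes how *direct* such travel is with two
metrics per trip:

* **route straightness** — great-circle distance between trip origin
  and destination divided by the driven path length,
  `S = d_hav(o, d) / Σᵢ d_hav(pᵢ, pᵢ₊₁)`, equal to 1 for a perfectly
  direct route;
* **actual–optimal distance ratio** — driven path length divided by
  the length of the *time-optimal* route between the same endpoints on
  the road network (the quickest route, not the shortest, so values
  slightly below 1 occur).

Each driver's multi-year history is compressed to a one-row summary
(medians of the route metrics, event rates, radius of gyration,
destination uniqueness). The scientific question is which brain
networks track these behaviors: each driver also has a 13×13 matrix of
inter- and intra-network rsfc correlations, flattened to 91 cells plus
age as regression features. For each driving summary in turn as the
response, the package runs a 1000-iteration bootstrap lasso: train on
a random 2/3 of drivers, pick the penalty by tenfold cross-validation,
test on the held-out 1/3, and count how often each feature is retained
with a nonzero coefficient. Responses with mean absolute percentage
error (MAPE) below 10 % are flagged as predictable, and the
most-retained cells are the stable correlates.

Because the original driving/MRI data are private, the package ships a
synthetic study generator (road grid, drivers with latent navigation
traits, breadcrumb trips, connectivity matrices with planted effects)
so the entire pipeline is testable end to end. See `docs/methods.md`
for the model details and design choices.

## Worked example

Generate a small synthetic study and associate straightness with
connectivity:

```python
from wayfind.simulate import SimulationConfig, simulate_study
from wayfind.pipeline import analyze_study

study = simulate_study(SimulationConfig(seed=42))
res = analyze_study(
    study.trips, study.network, study.connectivity, study.covariates,
    responses=("median_straightness", "median_actual_optimal_distance_ratio"),
    n_iterations=200, seed=42,
)
for name, sr in res["stability"].items():
    print(name, f"mean MAPE {sr.mean_mape:.2f}%", sr.top_features(3))
```

prints

```
median_straightness mean MAPE 4.47% ['FPxSubCort', 'SALxDAN', 'VANxVAN']
median_actual_optimal_distance_ratio mean MAPE 3.40% ['FPxSubCort', 'AUDxDAN', 'VANxFP']
```

Both responses pass the 10 % MAPE screen, and the retention rankings
recover the generator's planted cells: the two straightness effects
(`VANxVAN`, `SALxDAN`) sit at the top of the straightness ranking, and
`FPxSubCort` — planted on the distance ratio — leads its own ranking
outright (it also surfaces for straightness because detours lengthen
the driven path, coupling the two metrics; `AUDxDAN` and `VANxFP` are
noise cells retained in under a third of iterations).

The same computation on the Fig-style worked example: a trip driven
for six miles against a four-mile optimal route has

```python
>>> actual_optimal_distance_ratio(trip, net)
1.5
```

## Analysis scripts

The full study-scale analysis is a numbered sequence under
`analysis/` (raw intermediates go to `scratch/`, result tables to
`results/`):

```bash
python analysis/01_simulate_study.py      # 64 drivers x 200 trips + rsfc
python analysis/02_trip_metrics.py        # per-trip metric panel (12,800 trips)
python analysis/03_driver_summaries.py    # one-row-per-driver cohort table
python analysis/04_build_features.py      # 64 x 92 design matrix
python analysis/05_stability_selection.py # 1000-iteration bootstrap lasso x 4 responses
```

A `wayfind` CLI wraps the same steps for external data
(`wayfind simulate | trip-metrics | summarize | features | associate |
run-all`); inputs are plain CSV (breadcrumb log, edge-list network or
GeoJSON, per-driver 13×13 connectivity, covariates).

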