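"""End-to-end orchestration: breadcrumbs -> trip metrics -> driver
summaries -> feature table -> stability selection.

``analyze_study`` is the in-memory core (used by the tests and the
acceptance machinery); ``run_pipeline`` wraps it with file I/O, config
parsing and a JSON run report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .drivers import (
    DEFAULT_CLUSTER_RADIUS_M,
    RESPONSE_COLUMNS,
    summaries_to_frame,
    summarize_driver,
)
from .rsfc import build_feature_table, load_connectivity_csv
from .roads import RoadNetwork, Router, load_network_csv, load_network_geojson
from .stability import StabilityResult, ZeroResponseError, run_stability
from .trips import (
    DEFAULT_EVENT_THRESHOLD_MPH,
    DEFAULT_OVERSPEED_TOLERANCE_MPH,
    Trip,
    compute_trip_metrics,
)

log = logging.getLogger("wayfind")

#: Responses screened by default: the navigation metrics plus distance.
DEFAULT_RESPONSES = (
    "median_straightness",
    "median_actual_optimal_distance_ratio",
    "median_actual_optimal_time_ratio",
    "median_distance_mi",
)


@dataclass
class RunConfig:
    breadcrumbs: str | Path = "breadcrumbs.csv"
    network: str | Path = "network.csv"
    connectivity_dir: str | Path = "connectivity"
    covariates: str | Path = "covariates.csv"
    out_dir: str | Path = "out"
    responses: tuple[str, ...] = DEFAULT_RESPONSES
    routing_criterion: str = "time"
    brake_threshold_mph: float = DEFAULT_EVENT_THRESHOLD_MPH
    accel_threshold_mph: float = DEFAULT_EVENT_THRESHOLD_MPH
    overspeed_tolerance_mph: float = DEFAULT_OVERSPEED_TOLERANCE_MPH
    cluster_radius_m: float = DEFAULT_CLUSTER_RADIUS_M
    n_iterations: int = 1000
    train_fraction: float = 2.0 / 3.0
    n_folds: int = 10
    mape_threshold: float = 10.0
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "responses" in raw:
            raw["responses"] = tuple(raw["responses"])
        return cls(**raw)


def load_breadcrumbs(path, epoch_s: float = 30.0) -> dict[str, list[Trip]]:
    """Parse a breadcrumb CSV (driver_id, trip_id, timestamp, lat, lon,
    speed_mph) into per-driver Trip lists. Trips with a single fix are
    dropped with a log message."""
    df = pd.read_csv(path)
    need = {"driver_id", "trip_id", "timestamp", "lat", "lon", "speed_mph"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"breadcrumb CSV missing columns: {sorted(missing)}")
    t = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    df = df.assign(_t=(t - t.min()).dt.total_seconds())
    out: dict[str, list[Trip]] = {}
    for (did, tid), g in df.groupby(["driver_id", "trip_id"], sort=True):
        g = g.sort_values("_t")
        if len(g) < 2:
            log.warning("trip %s has < 2 breadcrumbs; dropped", tid)
            continue
        out.setdefault(str(did), []).append(
            Trip(
                driver_id=str(did),
                trip_id=str(tid),
                times=g["_t"].to_numpy(),
                lats=g["lat"].to_numpy(),
                lons=g["lon"].to_numpy(),
                speeds_mph=g["speed_mph"].to_numpy(),
                epoch_s=epoch_s,
            )
        )
    return out


def trip_metrics_table(
    trips: dict[str, list[Trip]],
    net: RoadNetwork,
    router: Router | None = None,
    brake_threshold_mph: float = DEFAULT_EVENT_THRESHOLD_MPH,
    accel_threshold_mph: float = DEFAULT_EVENT_THRESHOLD_MPH,
    overspeed_tolerance_mph: float = DEFAULT_OVERSPEED_TOLERANCE_MPH,
) -> tuple[pd.DataFrame, dict[str, list]]:
    """Metric panel for every trip; returns (long table, per-driver
    TripMetrics lists)."""
    if router is None:
        router = Router(net, criterion="time")
    per_driver: dict[str, list] = {}
    for did in sorted(trips):
        per_driver[did] = [
            compute_trip_metrics(
                t, net, router,
                brake_threshold_mph=brake_threshold_mph,
                accel_threshold_mph=accel_threshold_mph,
                overspeed_tolerance_mph=overspeed_tolerance_mph,
            )
            for t in trips[did]
        ]
    table = pd.DataFrame(
        [dataclasses.asdict(m) for ms in per_driver.values() for m in ms]
    )
    return table, per_driver


def driver_summary_table(
    trips: dict[str, list[Trip]],
    per_driver_metrics: dict[str, list],
    enrollment_years: pd.Series,
    cluster_radius_m: float = DEFAULT_CLUSTER_RADIUS_M,
) -> pd.DataFrame:
    summaries = []
    for did in sorted(per_driver_metrics):
        summaries.append(
            summarize_driver(
                per_driver_metrics[did],
                trips[did],
                float(enrollment_years[did]),
                cluster_radius_m=cluster_radius_m,
            )
        )
    return summaries_to_frame(summaries)


def load_connectivity_dir(path) -> dict[str, "object"]:
    path = Path(path)
    out = {}
    for f in sorted(path.glob("*.csv")):
        out[f.stem] = load_connectivity_csv(f)
    if not out:
        raise ValueError(f"no connectivity CSVs found under {path}")
    return out


def screen_responses(
    features: pd.DataFrame,
    summaries: pd.DataFrame,
    responses,
    n_iterations: int,
    train_fraction: float,
    n_folds: int,
    mape_threshold: float,
    seed: int,
) -> tuple[dict[str, StabilityResult], list[str]]:
    """Run stability selection for each requested response.

    Responses containing zeros (MAPE undefined) or missing values are
    skipped and reported, not fatal."""
    results: dict[str, StabilityResult] = {}
    skipped: list[str] = []
    for i, name in enumerate(responses):
        if name not in summaries.columns:
            raise KeyError(f"unknown response {name!r}")
        y = summaries.loc[features.index, name]
        if y.isna().any():
            log.warning("response %s has missing drivers; skipped", name)
            skipped.append(name)
            continue
        try:
            results[name] = run_stability(
                features, y, response_name=name,
                n_iterations=n_iterations, train_fraction=train_fraction,
                n_folds=n_folds, mape_threshold=mape_threshold,
                seed=seed + i,
            )
        except ZeroResponseError as exc:
            log.warning("%s", exc)
            skipped.append(name)
    return results, skipped


def analyze_study(
    trips: dict[str, list[Trip]],
    net: RoadNetwork,
    connectivity: dict,
    covariates: pd.DataFrame,
    responses=DEFAULT_RESPONSES,
    n_iterations: int = 1000,
    train_fraction: float = 2.0 / 3.0,
    n_folds: int = 10,
    mape_threshold: float = 10.0,
    cluster_radius_m: float = DEFAULT_CLUSTER_RADIUS_M,
    brake_threshold_mph: float = DEFAULT_EVENT_THRESHOLD_MPH,
    accel_threshold_mph: float = DEFAULT_EVENT_THRESHOLD_MPH,
    overspeed_tolerance_mph: float = DEFAULT_OVERSPEED_TOLERANCE_MPH,
    seed: int = 0,
) -> dict:
    """Full in-memory analysis; returns every stage's output keyed by
    name (trip_metrics, driver_summaries, features, stability, skipped)."""
    common = sorted(set(trips) & set(connectivity) & set(covariates.index))
    if not common:
        raise ValueError("no drivers shared by driving and connectivity inputs")
    if len(common) < len(trips):
        log.warning(
            "dropping %d drivers absent from rsfc/covariates", len(trips) - len(common)
        )
    trips = {d: trips[d] for d in common}
    router = Router(net, criterion="time")
    metrics_table, per_driver = trip_metrics_table(
        trips, net, router,
        brake_threshold_mph=brake_threshold_mph,
        accel_threshold_mph=accel_threshold_mph,
        overspeed_tolerance_mph=overspeed_tolerance_mph,
    )
    summaries = driver_summary_table(
        trips, per_driver, covariates["enrollment_years"], cluster_radius_m
    )
    features = build_feature_table(
        {d: connectivity[d] for d in common}, covariates["age"]
    )
    features = features.loc[summaries.index]
    stability, skipped = screen_responses(
        features, summaries, responses,
        n_iterations, train_fraction, n_folds, mape_threshold, seed,
    )
    return {
        "trip_metrics": metrics_table,
        "driver_summaries": summaries,
        "features": features,
        "stability": stability,
        "skipped_responses": skipped,
    }


def run_pipeline(config: RunConfig) -> dict:
    """File-based run: read inputs, analyze, write per-stage CSVs and a
    JSON report under ``config.out_dir``; returns the report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("run config: %s", dataclasses.asdict(config))
        netpath = str(config.network)
        net = (
            load_network_geojson(netpath)
            if netpath.endswith((".json", ".geojson"))
            else load_network_csv(netpath)
        )
        trips = load_breadcrumbs(config.breadcrumbs)
        connectivity = load_connectivity_dir(config.connectivity_dir)
        covariates = pd.read_csv(config.covariates, index_col="driver_id")
        res = analyze_study(
            trips, net, connectivity, covariates,
            responses=config.responses,
            n_iterations=config.n_iterations,
            train_fraction=config.train_fraction,
            n_folds=config.n_folds,
            mape_threshold=config.mape_threshold,
            cluster_radius_m=config.cluster_radius_m,
            brake_threshold_mph=config.brake_threshold_mph,
            accel_threshold_mph=config.accel_threshold_mph,
            overspeed_tolerance_mph=config.overspeed_tolerance_mph,
            seed=config.seed,
        )
        res["trip_metrics"].to_csv(out / "trip_metrics.csv", index=False)
        res["driver_summaries"].to_csv(out / "driver_summaries.csv")
        res["features"].to_csv(out / "features.csv")
        report = {
            "seed": config.seed,
            "n_drivers": int(len(res["driver_summaries"])),
            "skipped_responses": res["skipped_responses"],
            "responses": {},
        }
        for name, sr in res["stability"].items():
            sr.save_json(out / f"stability_{name}.json")
            sr.ranking().to_csv(out / f"retention_{name}.csv", index=False)
            report["responses"][name] = {
                "mean_mape": sr.mean_mape,
                "predictive_flag": sr.predictive_flag,
                "top_features": sr.top_features(10),
            }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)
        with open(out / "run_parameters.json", "w") as fh:
            json.dump({k: str(v) if isinstance(v, Path) else v
                       for k, v in dataclasses.asdict(config).items()}, fh, indent=1)
        log.info("pipeline complete: %d drivers", report["n_drivers"])
        return report
    finally:
        log.removeHandler(handler)
        handler.close()
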