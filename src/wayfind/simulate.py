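"""Synthetic study generator: road network, drivers, breadcrumb trips,
and connectivity matrices with planted, generator-known structure.

The generator emulates the inputs of a naturalistic-driving /
resting-state connectivity study so that every pipeline stage can be
exercised end to end without any external data:

* a lattice **road network** with per-edge speed-limit classes;
* **drivers**, each carrying two latent navigation traits — a
  *directness* trait (how directly their chosen trips line up with the
  road grid, which drives route straightness) and a *route-adherence*
  trait (how closely they follow the time-optimal route, which drives
  the actual–optimal distance ratio). The traits are weakly correlated
  (default 0.25), reflecting that the two route-selection metrics carry
  largely distinct information;
* **breadcrumb trips** at 30-s epochs: the chosen route is either the
  time-optimal one or a detour via a waypoint outside the trip's direct
  corridor (excursion size growing as adherence falls), traversed below
  the posted limit with GPS-like speed noise and accel/decel ramping,
  plus injected hard-brake / hard-acceleration / overspeeding events at
  configured per-trip rates;
* **connectivity matrices** (13x13 by default) whose background cells
  are noise around a fixed template and whose planted cells follow
  ``alpha + beta * z(trait) + noise``, clipped to the correlation scale.

Everything is a deterministic function of the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .geo import EARTH_RADIUS_M, MPH_TO_MPS, GeoPoint, haversine_distance
from .rsfc import (
    DEFAULT_NETWORKS,
    ConnectivityMatrix,
    cell_feature_name,
    save_connectivity_csv,
)
from .roads import Edge, RoadNetwork, Route, Router, save_network_csv
from .trips import Trip

_M_PER_DEG_LAT = np.pi / 180.0 * EARTH_RADIUS_M  # ~111.2 km


@dataclass(frozen=True)
class Effect:
    """One planted association between a connectivity cell and a
    driving response. ``beta`` is on the correlation scale per SD of the
    response-aligned trait; ``sign`` orients the trait so beta > 0
    plants a positive cell-response correlation."""

    cell: tuple[str, str]
    response: str
    beta: float
    noise_sd: float
    trait_index: int
    sign: float = 1.0


def default_effects() -> tuple[Effect, ...]:
    # directness trait raises straightness; adherence trait lowers the
    # actual-optimal ratio, so its planted cell tracks -trait.
    return (
        Effect(("VAN", "VAN"), "median_straightness", 0.16, 0.09, 0, +1.0),
        Effect(("SAL", "DAN"), "median_straightness", 0.16, 0.09, 0, +1.0),
        Effect(("FP", "SubCort"), "median_actual_optimal_distance_ratio", 0.16, 0.08, 1, -1.0),
    )


@dataclass
class SimulationConfig:
    seed: int = 0
    n_drivers: int = 64
    grid_rows: int = 17
    grid_cols: int = 17
    edge_length_m: float = 600.0
    speed_limit_classes: tuple[float, ...] = (25.0, 35.0, 55.0)
    origin_lat: float = 38.60
    origin_lon: float = -90.30
    epoch_s: float = 30.0
    trips_per_driver: int = 200
    # latent traits: (directness, adherence), each N(mean, sd), corr rho
    skill_mean: float = 0.0
    skill_sd: float = 1.0
    trait_correlation: float = 0.25
    # trip geometry
    steps_min: int = 8
    steps_max: int = 18
    diagonality_slope: float = 1.6
    diagonality_concentration: float = 8.0
    # detour model
    detour_intercept: float = 0.2
    detour_slope: float = 1.0
    detour_poisson_scale: float = 0.3
    detour_poisson_decay: float = 0.7
    max_detour_blocks: int = 2
    # kinematics
    pace_beta_a: float = 5.0
    pace_beta_b: float = 2.0
    pace_min: float = 0.55
    pace_range: float = 0.33
    speed_noise_mph: float = 1.0
    ramp_limit_mph: float = 10.0  # max nominal speed change per epoch
    # per-trip event injection rates (cohort means of a naturalistic
    # OBD-II study: brakes 0.110, accels 0.0423, overspeed events 0.394)
    hard_brake_rate: float = 0.110
    hard_accel_rate: float = 0.0423
    overspeed_event_rate: float = 0.394
    event_threshold_mph: float = 15.0
    overspeed_tolerance_mph: float = 0.0
    # cohort covariates
    age_min: float = 60.0
    age_max: float = 85.0
    enrollment_mean_years: float = 3.01
    enrollment_sd_years: float = 1.06
    # connectivity model
    networks: tuple[str, ...] = DEFAULT_NETWORKS
    intra_baseline: float = 0.45
    inter_baseline: float = 0.20
    background_noise_sd: float = 0.12
    effects: tuple[Effect, ...] = field(default_factory=default_effects)


@dataclass
class Study:
    """A complete in-memory synthetic study."""

    config: SimulationConfig
    network: RoadNetwork
    trips: dict[str, list[Trip]]
    connectivity: dict[str, ConnectivityMatrix]
    covariates: pd.DataFrame  # index driver_id; columns age, enrollment_years
    truth: dict


def make_grid_network(
    config: SimulationConfig, rng: np.random.Generator
) -> RoadNetwork:
    """Fully connected lattice with seeded random speed-limit classes.

    Node (r, c) has integer id ``r * cols + c``; edge lengths are the
    great-circle distances between adjacent nodes (~``edge_length_m``).
    """
    R, C = config.grid_rows, config.grid_cols
    if R < 2 or C < 2:
        raise ValueError("grid must be at least 2x2")
    dlat = config.edge_length_m / _M_PER_DEG_LAT
    dlon = config.edge_length_m / (
        _M_PER_DEG_LAT * np.cos(np.radians(config.origin_lat))
    )
    nodes: dict[int, GeoPoint] = {}
    for r in range(R):
        for c in range(C):
            nodes[r * C + c] = GeoPoint(
                config.origin_lat + r * dlat, config.origin_lon + c * dlon
            )
    edges: list[Edge] = []
    for r in range(R):
        for c in range(C):
            u = r * C + c
            if c + 1 < C:
                v = u + 1
                edges.append(
                    Edge(u, v, haversine_distance(nodes[u], nodes[v]),
                         float(rng.choice(config.speed_limit_classes)))
                )
            if r + 1 < R:
                v = u + C
                edges.append(
                    Edge(u, v, haversine_distance(nodes[u], nodes[v]),
                         float(rng.choice(config.speed_limit_classes)))
                )
    return RoadNetwork(nodes, edges)


def _route_speed_limits(router: Router, route_nodes: tuple) -> np.ndarray:
    """Posted limit (mph) of each traversed edge."""
    lims = []
    for a, b in zip(route_nodes[:-1], route_nodes[1:]):
        L, dur = router._edge_info[(router.node_index(a), router.node_index(b))]
        lims.append((L / dur) / MPH_TO_MPS)
    return np.array(lims)


def _spaced_slots(rng: np.random.Generator, n_ep: int, k: int) -> list[int]:
    """Up to k interior epoch indices at least 2 apart, so injected
    events cannot cancel each other."""
    slots: list[int] = []
    if k <= 0:
        return slots
    for i in rng.permutation(np.arange(1, n_ep - 1)):
        if all(abs(int(i) - s) >= 2 for s in slots):
            slots.append(int(i))
            if len(slots) == k:
                break
    return slots


def _ramp_after(speeds: np.ndarray, i: int, ramp: float, direction: str) -> None:
    """Ease the recovery after an injected event so it does not register
    as a second event: after a brake (``direction="up"``) cap rises at
    ``ramp`` per epoch until the profile is rejoined; after an
    acceleration (``direction="down"``) cap falls. One-sided on purpose —
    a chain that clamped both directions could walk across the trip and
    erase other injected events."""
    for j in range(i, speeds.size - 1):
        if direction == "up" and speeds[j + 1] > speeds[j] + ramp:
            speeds[j + 1] = speeds[j] + ramp
        elif direction == "down" and speeds[j + 1] < speeds[j] - ramp:
            speeds[j + 1] = speeds[j] - ramp
        else:
            break


def _choose_route(
    router: Router,
    origin: int,
    dest: int,
    adherence: float,
    rng: np.random.Generator,
    config: SimulationConfig,
):
    """Time-optimal route, or a waypoint detour.

    With probability falling in the adherence trait, the driver routes
    via a waypoint placed ``h`` blocks outside the origin–destination
    bounding rectangle (h growing as adherence falls). On a lattice,
    any reroute *inside* that rectangle has identical length (all
    monotone staircases tie), so only an out-of-corridor excursion — a
    driver getting lost or hugging familiar streets — actually inflates
    the driven distance relative to the optimal route.
    """
    opt = router.route(origin, dest)
    p_det = float(np.clip(
        expit(config.detour_intercept - config.detour_slope * adherence), 0.03, 0.97
    ))
    if rng.random() >= p_det or len(opt.nodes) < 3:
        return opt
    h = 1 + int(rng.poisson(
        config.detour_poisson_scale * np.exp(-config.detour_poisson_decay * adherence)
    ))
    h = min(h, config.max_detour_blocks)
    R, C = config.grid_rows, config.grid_cols
    orow, ocol = divmod(int(origin), C)
    drow, dcol = divmod(int(dest), C)
    rmin, rmax = min(orow, drow), max(orow, drow)
    cmin, cmax = min(ocol, dcol), max(ocol, dcol)
    base = opt.nodes[int(rng.integers(1, len(opt.nodes) - 1))]
    brow, bcol = divmod(int(base), C)
    if rng.random() < 0.5:
        wrow = (rmin - h) if rng.random() < 0.5 else (rmax + h)
        wcol = bcol
    else:
        wcol = (cmin - h) if rng.random() < 0.5 else (cmax + h)
        wrow = brow
    wrow = min(max(wrow, 0), R - 1)
    wcol = min(max(wcol, 0), C - 1)
    wp = wrow * C + wcol
    if wp == origin or wp == dest:
        return opt
    leg_a = router.route(origin, wp)
    leg_b = router.route(wp, dest)
    return Route(
        leg_a.nodes + leg_b.nodes[1:],
        leg_a.total_length_m + leg_b.total_length_m,
        leg_a.total_duration_s + leg_b.total_duration_s,
    )


def simulate_trip(
    net: RoadNetwork,
    router: Router,
    origin: int,
    dest: int,
    adherence: float,
    rng: np.random.Generator,
    config: SimulationConfig,
    driver_id: str = "d000",
    trip_id: str = "t0000",
    start_time_s: float = 0.0,
    n_brakes: int | None = None,
    n_accels: int | None = None,
    n_overspeed_events: int | None = None,
) -> Trip:
    """One breadcrumb trip between two network nodes.

    The route follows :func:`_choose_route`; the vehicle traverses each
    edge at ``pace * limit`` (pace < 1, drawn per trip) and a fix is
    emitted every ``epoch_s`` seconds by interpolating along the route
    polyline, with Gaussian noise on the recorded speed. Hard-brake,
    hard-acceleration and overspeeding events are then written into the
    recorded speed sequence; event counts default to Poisson draws at
    the configured per-trip rates.
    """
    if origin == dest:
        raise ValueError("origin and destination must differ")
    route = _choose_route(router, origin, dest, adherence, rng, config)
    nlat = np.array([net.nodes[u].lat for u in route.nodes])
    nlon = np.array([net.nodes[u].lon for u in route.nodes])
    limits = _route_speed_limits(router, route.nodes)  # mph per leg
    leg_len = np.array([
        router._edge_info[(router.node_index(a), router.node_index(b))][0]
        for a, b in zip(route.nodes[:-1], route.nodes[1:])
    ])
    pace = config.pace_min + config.pace_range * rng.beta(
        config.pace_beta_a, config.pace_beta_b
    )
    leg_speed_mps = limits * MPH_TO_MPS * pace
    leg_time = leg_len / leg_speed_mps
    cum_t = np.concatenate([[0.0], np.cumsum(leg_time)])
    cum_d = np.concatenate([[0.0], np.cumsum(leg_len)])
    T = float(cum_t[-1])

    ts = np.arange(0.0, T, config.epoch_s)
    if T - ts[-1] > 1.0:
        ts = np.append(ts, T)
    if ts.size < 2:
        ts = np.array([0.0, T])
    d_at = np.interp(ts, cum_t, cum_d)
    seg = np.clip(np.searchsorted(cum_d, d_at, side="right") - 1, 0, leg_len.size - 1)
    frac = (d_at - cum_d[seg]) / leg_len[seg]
    lats = nlat[seg] + frac * (nlat[seg + 1] - nlat[seg])
    lons = nlon[seg] + frac * (nlon[seg + 1] - nlon[seg])
    # put the endpoints exactly on the terminal nodes
    lats[0], lons[0] = nlat[0], nlon[0]
    lats[-1], lons[-1] = nlat[-1], nlon[-1]
    # nominal speed follows the local limit at the trip's pace, with a
    # forward/backward ramp so speed-zone changes spread over epochs
    # (drivers do not change speed 30 mph in one step)
    nominal = limits[seg] * pace
    ramp = config.ramp_limit_mph
    # trips begin and end from/to a near stop
    nominal[0] = min(nominal[0], ramp)
    nominal[-1] = min(nominal[-1], ramp)
    for i in range(1, nominal.size):
        if nominal[i] > nominal[i - 1] + ramp:
            nominal[i] = nominal[i - 1] + ramp
    for i in range(nominal.size - 2, -1, -1):
        if nominal[i] > nominal[i + 1] + ramp:
            nominal[i] = nominal[i + 1] + ramp
    speeds = nominal + rng.normal(0.0, config.speed_noise_mph, ts.size)
    epoch_limits = limits[seg]

    n_ep = ts.size
    thr = config.event_threshold_mph
    if n_brakes is None:
        n_brakes = int(rng.poisson(config.hard_brake_rate))
    if n_accels is None:
        n_accels = int(rng.poisson(config.hard_accel_rate))
    if n_overspeed_events is None:
        n_overspeed_events = int(rng.poisson(config.overspeed_event_rate))
    ramp = config.ramp_limit_mph
    if n_ep >= 3:
        for i in _spaced_slots(rng, n_ep, n_brakes):
            speeds[i - 1] = max(speeds[i - 1], thr + 8.0)
            speeds[i] = max(0.0, speeds[i - 1] - (thr + 3.0 + rng.uniform(0.0, 6.0)))
            _ramp_after(speeds, i, ramp, "up")
        for i in _spaced_slots(rng, n_ep, n_accels):
            speeds[i] = speeds[i - 1] + thr + 3.0 + rng.uniform(0.0, 6.0)
            _ramp_after(speeds, i, ramp, "down")
        for _ in range(n_overspeed_events):
            run = 1 + int(rng.poisson(0.4))
            i = int(rng.integers(1, n_ep - 1))
            stop = min(i + run, n_ep - 1)
            # one value over the run's highest limit, so every burst
            # epoch overspeeds without a mid-burst jump
            speeds[i:stop] = (
                float(np.max(epoch_limits[i:stop]))
                + config.overspeed_tolerance_mph
                + 1.0
                + rng.uniform(0.0, 2.0)
            )
            # ease in and out so the burst is not itself a hard event
            j = i - 1
            while j >= 0 and speeds[j] < speeds[j + 1] - ramp:
                speeds[j] = speeds[j + 1] - ramp
                j -= 1
            _ramp_after(speeds, stop - 1, ramp, "down")
    speeds = np.clip(speeds, 0.0, None)
    return Trip(
        driver_id=driver_id,
        trip_id=trip_id,
        times=start_time_s + ts,
        lats=lats,
        lons=lons,
        speeds_mph=speeds,
        epoch_s=config.epoch_s,
    )


def _choose_endpoints(
    directness: float,
    home: int,
    rng: np.random.Generator,
    config: SimulationConfig,
) -> tuple[int, int]:
    """Origin/destination choice encoding the directness trait.

    The trip displacement has ``m`` grid steps split between the two
    axes by a diagonality draw: direct drivers favor near-axis trips
    (Manhattan routes close to the straight line), low-directness
    drivers favor diagonal ones (straightness near 1/sqrt(2))."""
    R, C = config.grid_rows, config.grid_cols
    origin = home if rng.random() < 0.5 else int(rng.integers(0, R * C))
    orow, ocol = divmod(origin, C)
    for _ in range(20):
        m = int(rng.integers(config.steps_min, config.steps_max + 1))
        mt = float(np.clip(expit(-config.diagonality_slope * directness), 0.05, 0.95))
        kap = config.diagonality_concentration
        t = rng.beta(kap * mt, kap * (1.0 - mt))  # dy/(dx+dy) diagonality
        dy = int(round(m * 0.5 * t))  # t=1 -> even split, t=0 -> on-axis
        dx = m - dy
        if rng.random() < 0.5:
            dx, dy = dy, dx
        drow = dy if rng.random() < 0.5 else -dy
        dcol = dx if rng.random() < 0.5 else -dx
        trow = min(max(orow + drow, 0), R - 1)
        tcol = min(max(ocol + dcol, 0), C - 1)
        dest = trow * C + tcol
        if dest != origin:
            return origin, dest
    # degenerate corner case: step one column over
    return origin, origin + (1 if ocol + 1 < C else -1)


def simulate_driver_trips(
    net: RoadNetwork,
    router: Router,
    driver_id: str,
    directness: float,
    adherence: float,
    rng: np.random.Generator,
    config: SimulationConfig,
) -> list[Trip]:
    home = int(rng.integers(0, len(net.nodes)))
    trips = []
    for k in range(config.trips_per_driver):
        origin, dest = _choose_endpoints(directness, home, rng, config)
        trips.append(
            simulate_trip(
                net, router, origin, dest, adherence, rng, config,
                driver_id=driver_id,
                trip_id=f"{driver_id}-{k:04d}",
                start_time_s=k * 21_600.0,  # one trip every 6 h
            )
        )
    return trips


def simulate_rsfc(
    traits: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[ConnectivityMatrix]:
    """Connectivity matrices with planted trait-linked cells.

    ``traits``: (n_drivers, 2) latent trait matrix. Background cells are
    template + N(0, background_noise_sd); each planted cell is
    ``template + beta * z + N(0, noise_sd)`` where z is the cohort-
    standardized, sign-oriented trait. All values clip to [-1, 1].
    """
    nets = tuple(config.networks)
    k = len(nets)
    idx = {n: i for i, n in enumerate(nets)}
    template = np.full((k, k), config.inter_baseline)
    np.fill_diagonal(template, config.intra_baseline)
    traits = np.atleast_2d(np.asarray(traits, dtype=float))
    n = traits.shape[0]
    zs = {}
    for e in config.effects:
        t = e.sign * traits[:, e.trait_index]
        sd = t.std()
        zs[id(e)] = (t - t.mean()) / (sd if sd > 0 else 1.0)
    out = []
    iu = np.triu_indices(k)
    for d in range(n):
        vals = template.copy()
        noise = rng.normal(0.0, config.background_noise_sd, size=iu[0].size)
        vals[iu] += noise
        vals[(iu[1], iu[0])] = vals[iu]
        for e in config.effects:
            i, j = idx[e.cell[0]], idx[e.cell[1]]
            v = template[i, j] + e.beta * zs[id(e)][d] + rng.normal(0.0, e.noise_sd)
            vals[i, j] = vals[j, i] = v
        vals = np.clip(vals, -0.999, 0.999)
        out.append(ConnectivityMatrix(nets, vals))
    return out


def simulate_study(config: SimulationConfig) -> Study:
    """Generate the full study (network, trips, connectivity,
    covariates, truth) deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    net = make_grid_network(config, rng)
    router = Router(net, criterion="time")

    n = config.n_drivers
    rho = config.trait_correlation
    cov = (config.skill_sd**2) * np.array([[1.0, rho], [rho, 1.0]])
    traits = rng.multivariate_normal([config.skill_mean] * 2, cov, size=n)
    ages = rng.uniform(config.age_min, config.age_max, size=n)
    enroll = np.clip(
        rng.normal(config.enrollment_mean_years, config.enrollment_sd_years, size=n),
        1.0, None,
    )
    driver_ids = [f"d{i:03d}" for i in range(n)]

    trips = {
        did: simulate_driver_trips(
            net, router, did, traits[i, 0], traits[i, 1], rng, config
        )
        for i, did in enumerate(driver_ids)
    }
    matrices = simulate_rsfc(traits, config, rng)
    connectivity = dict(zip(driver_ids, matrices))
    covariates = pd.DataFrame(
        {"age": ages, "enrollment_years": enroll}, index=pd.Index(driver_ids, name="driver_id")
    )
    truth = {
        "seed": config.seed,
        "traits": {
            did: {"directness": float(traits[i, 0]), "adherence": float(traits[i, 1])}
            for i, did in enumerate(driver_ids)
        },
        "effects": [
            {
                "cell": list(e.cell),
                "feature": cell_feature_name(*e.cell, networks=config.networks),
                "response": e.response,
                "beta": e.beta,
                "noise_sd": e.noise_sd,
                "trait_index": e.trait_index,
                "sign": e.sign,
            }
            for e in config.effects
        ],
    }
    return Study(config, net, trips, connectivity, covariates, truth)


_EPOCH_ORIGIN = pd.Timestamp("2021-01-01T00:00:00Z")


def breadcrumbs_frame(trips: dict[str, list[Trip]]) -> pd.DataFrame:
    """Long-format breadcrumb table (ISO-8601 UTC timestamps)."""
    rows = []
    for did, tl in trips.items():
        for t in tl:
            stamps = _EPOCH_ORIGIN + pd.to_timedelta(t.times, unit="s")
            rows.append(pd.DataFrame({
                "driver_id": did,
                "trip_id": t.trip_id,
                "timestamp": stamps.strftime("%Y-%m-%dT%H:%M:%S.%fZ"),
                "lat": t.lats,
                "lon": t.lons,
                "speed_mph": t.speeds_mph,
            }))
    return pd.concat(rows, ignore_index=True)


def write_study(study: Study, outdir) -> dict[str, Path]:
    """Write the study as the file set the pipeline consumes:
    breadcrumbs.csv, network.csv, connectivity/<driver>.csv,
    covariates.csv, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "breadcrumbs": outdir / "breadcrumbs.csv",
        "network": outdir / "network.csv",
        "connectivity": outdir / "connectivity",
        "covariates": outdir / "covariates.csv",
        "truth": outdir / "truth.json",
    }
    breadcrumbs_frame(study.trips).to_csv(paths["breadcrumbs"], index=False)
    save_network_csv(study.network, paths["network"])
    paths["connectivity"].mkdir(exist_ok=True)
    for did, cm in study.connectivity.items():
        save_connectivity_csv(cm, paths["connectivity"] / f"{did}.csv")
    study.covariates.to_csv(paths["covariates"])
    with open(paths["truth"], "w") as fh:
        json.dump(study.truth, fh, indent=1)
    return paths


def generate_study(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Simulate and write in one step."""
    return write_study(simulate_study(config), outdir)
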