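import json

import numpy as np
import pytest

from wayfind.roads import Router
from wayfind.simulate import (
    Effect,
    SimulationConfig,
    make_grid_network,
    simulate_rsfc,
    simulate_study,
    simulate_trip,
    write_study,
)
from wayfind.trips import detect_overspeeding, detect_speed_events, straightness


def tiny_cfg(**kw):
    base = dict(seed=0, n_drivers=4, trips_per_driver=10, grid_rows=8, grid_cols=8,
                steps_min=3, steps_max=6)
    base.update(kw)
    return SimulationConfig(**base)


class TestGridNetwork:
    def test_2x2_counts(self):
        cfg = SimulationConfig(grid_rows=2, grid_cols=2)
        net = make_grid_network(cfg, np.random.default_rng(0))
        assert len(net.nodes) == 4
        assert len(net.edges) == 4

    def test_edge_lengths_near_nominal(self):
        cfg = tiny_cfg()
        net = make_grid_network(cfg, np.random.default_rng(1))
        lengths = np.array([e.length_m for e in net.edges])
        assert np.all(np.abs(lengths - cfg.edge_length_m) < 2.0)
        assert all(e.speed_limit_mph in cfg.speed_limit_classes for e in net.edges)

    def test_same_seed_same_network(self):
        cfg = tiny_cfg()
        a = make_grid_network(cfg, np.random.default_rng(9))
        b = make_grid_network(cfg, np.random.default_rng(9))
        assert [e.speed_limit_mph for e in a.edges] == [
            e.speed_limit_mph for e in b.edges
        ]

    def test_fully_connected(self):
        cfg = tiny_cfg()
        net = make_grid_network(cfg, np.random.default_rng(2))
        router = Router(net)
        assert np.all(np.isfinite(router.dist))


class TestSimulateTrip:
    def _setup(self, cfg=None):
        cfg = cfg or tiny_cfg()
        net = make_grid_network(cfg, np.random.default_rng(3))
        return cfg, net, Router(net, "time")

    def test_high_adherence_follows_optimal_route(self):
        cfg, net, router = self._setup()
        from wayfind.trips import actual_optimal_distance_ratio

        ratios = []
        rng = np.random.default_rng(4)
        for k in range(40):
            o, d = (int(x) for x in rng.choice(len(net.nodes), 2, replace=False))
            if router.route(o, d).total_length_m < 2000:
                continue
            t = simulate_trip(net, router, o, d, adherence=50.0, rng=rng, config=cfg)
            ratios.append(actual_optimal_distance_ratio(t, net, router))
        # near-perfect adherence: driven length tracks the optimal route
        # (30-s sampling cuts corners, so a small downward bias remains)
        assert np.median(ratios) == pytest.approx(1.0, abs=0.08)

    def test_injected_hard_brakes_detected(self):
        cfg, net, router = self._setup()
        rng = np.random.default_rng(5)
        found = 0
        for k in range(10):
            t = simulate_trip(
                net, router, 0, 63, adherence=0.0, rng=rng, config=cfg,
                n_brakes=2, n_accels=0, n_overspeed_events=0,
            )
            b, _ = detect_speed_events(t, cfg.event_threshold_mph, cfg.event_threshold_mph)
            found += int(b >= 2)
        assert found >= 9  # collisions of injection slots are rare

    def test_injected_overspeeding_detected(self):
        cfg, net, router = self._setup()
        rng = np.random.default_rng(6)
        fracs = []
        for k in range(10):
            t = simulate_trip(
                net, router, 0, 63, adherence=0.0, rng=rng, config=cfg,
                n_brakes=0, n_accels=0, n_overspeed_events=2,
            )
            _, frac = detect_overspeeding(t, net, cfg.overspeed_tolerance_mph, router)
            fracs.append(frac)
        assert np.mean(fracs) > 0.05

    def test_straightness_decreases_with_detour_magnitude(self):
        results = []
        for scale in (0.0, 1.0, 3.0):
            cfg = tiny_cfg(detour_poisson_scale=scale, detour_intercept=5.0)
            net = make_grid_network(cfg, np.random.default_rng(3))
            router = Router(net, "time")
            rng = np.random.default_rng(7)
            vals = []
            for _ in range(100):
                o, d = (int(x) for x in rng.choice(len(net.nodes), 2, replace=False))
                t = simulate_trip(net, router, o, d, adherence=0.0, rng=rng, config=cfg)
                vals.append(straightness(t)[0])
            results.append(np.mean(vals))
        assert results[0] > results[1] > results[2]

    def test_same_seed_identical_trip(self):
        cfg, net, router = self._setup()
        a = simulate_trip(net, router, 0, 60, 0.5, np.random.default_rng(8), cfg)
        b = simulate_trip(net, router, 0, 60, 0.5, np.random.default_rng(8), cfg)
        assert np.array_equal(a.lats, b.lats)
        assert np.array_equal(a.speeds_mph, b.speeds_mph)


class TestSimulateRsfc:
    def test_outputs_bounded(self):
        cfg = tiny_cfg()
        rng = np.random.default_rng(0)
        traits = rng.normal(size=(50, 2))
        mats = simulate_rsfc(traits, cfg, rng)
        assert len(mats) == 50
        for m in mats:
            assert np.all(m.values >= -1) and np.all(m.values <= 1)
            assert np.allclose(m.values, m.values.T)

    def test_strong_effect_tracks_trait(self):
        effects = (Effect(("VAN", "VAN"), "median_straightness", 0.3, 0.01, 0, +1.0),)
        cfg = tiny_cfg(effects=effects)
        rng = np.random.default_rng(1)
        traits = rng.normal(size=(200, 2))
        mats = simulate_rsfc(traits, cfg, rng)
        cell = np.array([m.cell("VAN", "VAN") for m in mats])
        assert np.corrcoef(cell, traits[:, 0])[0, 1] > 0.9

    def test_null_effect_indistinguishable_from_background(self):
        from scipy.stats import mannwhitneyu

        effects = (
            Effect(("VAN", "VAN"), "median_straightness", 0.0, 0.12, 0, +1.0),
        )
        cfg = tiny_cfg(effects=effects, intra_baseline=0.3)
        rng = np.random.default_rng(2)
        traits = rng.normal(size=(500, 2))
        mats = simulate_rsfc(traits, cfg, rng)
        planted = np.array([m.cell("VAN", "VAN") for m in mats])
        background = np.array([m.cell("DMN", "DMN") for m in mats])
        p = mannwhitneyu(planted, background).pvalue
        assert p > 0.01


class TestStudy:
    def test_default_counts(self):
        study = simulate_study(SimulationConfig(seed=0, trips_per_driver=5))
        assert len(study.trips) == 64
        assert all(len(v) == 5 for v in study.trips.values())
        assert len(study.connectivity) == 64
        assert study.covariates.shape == (64, 2)

    def test_truth_lists_three_planted_effects(self):
        study = simulate_study(tiny_cfg())
        effects = study.truth["effects"]
        assert len(effects) == 3
        pairs = {(e["feature"], e["response"]) for e in effects}
        assert pairs == {
            ("VANxVAN", "median_straightness"),
            ("SALxDAN", "median_straightness"),
            ("FPxSubCort", "median_actual_optimal_distance_ratio"),
        }

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        from wayfind.simulate import breadcrumbs_frame

        a = simulate_study(tiny_cfg(seed=77))
        b = simulate_study(tiny_cfg(seed=77))
        fa, fb = breadcrumbs_frame(a.trips), breadcrumbs_frame(b.trips)
        assert fa.equals(fb)
        for d in a.connectivity:
            assert np.array_equal(a.connectivity[d].values, b.connectivity[d].values)

    def test_monotone_coupling_in_mean_skill(self):
        from wayfind.pipeline import trip_metrics_table, driver_summary_table

        med_s, med_r = [], []
        for mean in (-1.0, 0.0, 1.0):
            cfg = tiny_cfg(seed=5, n_drivers=6, trips_per_driver=40, skill_mean=mean)
            study = simulate_study(cfg)
            _, per_driver = trip_metrics_table(study.trips, study.network)
            ds = driver_summary_table(
                study.trips, per_driver, study.covariates["enrollment_years"]
            )
            med_s.append(ds["median_straightness"].median())
            med_r.append(ds["median_actual_optimal_distance_ratio"].median())
        assert med_s[0] < med_s[1] < med_s[2]
        assert med_r[0] > med_r[1] > med_r[2]

    def test_write_study_files(self, tmp_path):
        study = simulate_study(tiny_cfg())
        paths = write_study(study, tmp_path / "study")
        assert paths["breadcrumbs"].exists()
        assert paths["network"].exists()
        assert len(list(paths["connectivity"].glob("*.csv"))) == 4
        truth = json.loads(paths["truth"].read_text())
        assert len(truth["effects"]) == 3
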