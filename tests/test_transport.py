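"""Advection, diffusion and the full release/settle simulation."""

import numpy as np
import pytest

import driftsource as ds
from driftsource.errors import ValidationError
from driftsource.fields import M_PER_DEG


class TestAdvect:
    def test_uniform_field_analytic_displacement(self, uniform_field):
        # 0.1 m/s for one day at the equator = 8,640 m = 0.0777° east
        lon, lat = ds.advect_rk4(uniform_field, 5.0, 0.0, "2024-01-02", 86_400,
                                 "forward")
        assert lon - 5.0 == pytest.approx(8_640.0 / M_PER_DEG, rel=1e-9)
        assert lat == pytest.approx(0.0, abs=1e-12)

    def test_backward_reverses_forward(self, uniform_field):
        lon1, lat1 = ds.advect_rk4(uniform_field, 5.0, 2.0, "2024-01-02", 86_400,
                                   "forward")
        t1 = np.datetime64("2024-01-02") + np.timedelta64(1, "D")
        lon0, lat0 = ds.advect_rk4(uniform_field, lon1, lat1, t1, 86_400, "backward")
        assert lon0 == pytest.approx(5.0, abs=1e-9)
        assert lat0 == pytest.approx(2.0, abs=1e-9)

    def test_solid_body_radius_conserved(self):
        # one full revolution in 100 RK4 steps: radius drift < 0.1%
        period = 30 * 86_400.0
        omega = 2 * np.pi / period
        f = ds.synth.make_field("solid_body", ((0.0, 20.0), (10.0, 30.0)), 0.5,
                                ("2024-01-01", "2024-03-15"), omega=omega,
                                center=(10.0, 20.0))
        lon, lat = 13.0, 20.0
        t = np.datetime64("2024-01-01", "s").astype("int64").astype(float)
        dt = period / 100
        for _ in range(100):
            lon, lat = ds.advect_rk4(f, lon, lat, t, dt, "forward")
            t += dt
        r = np.hypot((lon - 10.0 + 180) % 360 - 180, lat - 20.0)
        assert abs(r - 3.0) / 3.0 < 1e-3

    def test_forward_backward_roundtrip_under_1km(self, gyre_field):
        # deterministic 30-day round trip on an analytic field, hourly steps
        lon, lat = 4.0, 17.0
        t = np.datetime64("2024-01-05", "s").astype("int64").astype(float)
        for _ in range(30 * 24):
            lon, lat = ds.advect_rk4(gyre_field, lon, lat, t, 3600.0, "forward")
            t += 3600.0
        for _ in range(30 * 24):
            lon, lat = ds.advect_rk4(gyre_field, lon, lat, t, 3600.0, "backward")
            t -= 3600.0
        err_km = ds.haversine_km((lon, lat), (4.0, 17.0))
        assert err_km < 1.0


class TestDiffuse:
    def test_zero_K_is_identity(self):
        rng = np.random.default_rng(0)
        lon, lat = ds.diffuse(12.3, 45.6, 86_400, 0.0, rng)
        assert (lon, lat) == (12.3, 45.6)

    def test_variance_matches_2KdT(self):
        # 10,000 particles, K = 10, dt = 1 day -> per-axis var 1.728e6 m^2
        rng = np.random.default_rng(1)
        n = 10_000
        lon, lat = ds.diffuse(np.full(n, 180.0), np.zeros(n), 86_400, 10.0, rng)
        var_y = np.var((lat - 0.0) * M_PER_DEG)
        var_x = np.var((lon - 180.0) * M_PER_DEG)  # cos(0) = 1
        expect = 2 * 10.0 * 86_400
        assert var_y == pytest.approx(expect, rel=0.05)
        assert var_x == pytest.approx(expect, rel=0.05)

    def test_same_seed_reproducible(self):
        a = ds.diffuse(np.zeros(5) + 10, np.zeros(5), 3600, 10.0,
                       np.random.default_rng(42))
        b = ds.diffuse(np.zeros(5) + 10, np.zeros(5), 3600, 10.0,
                       np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_ensemble_centroid_stays_at_release(self):
        rng = np.random.default_rng(2)
        n = 4000
        lon, lat = np.full(n, 50.0), np.full(n, 0.0)
        for _ in range(20):
            lon, lat = ds.diffuse(lon, lat, 3600.0, 10.0, rng)
        sigma = np.sqrt(2 * 10.0 * 3600 * 20) / M_PER_DEG
        se = sigma / np.sqrt(n)
        assert abs(lat.mean() - 0.0) < 3 * se
        assert abs(lon.mean() - 50.0) < 3 * se


class TestReleaseSchedule:
    def test_study_schedule_releases_584300(self):
        sched = ds.ReleaseSchedule()  # 100/day, 2000-01-01..2015-12-30
        assert sched.total_particles() == 584_300

    def test_inclusive_single_day(self):
        s = ds.ReleaseSchedule(start_date="2024-03-01", end_date="2024-03-01",
                               particles_per_day=7)
        assert s.total_particles() == 7

    def test_invalid_schedule(self):
        with pytest.raises(ValidationError):
            ds.ReleaseSchedule(start_date="2024-02-01", end_date="2024-01-01")
        with pytest.raises(ValidationError):
            ds.ReleaseSchedule(particles_per_day=0)


class TestRunSimulation:
    def test_convergent_sink_all_land(self, sink_field, sink_settlement):
        sched = ds.ReleaseSchedule(site=(16.0, 24.0), particles_per_day=50,
                                   start_date="2024-04-25", end_date="2024-04-25")
        cfg = ds.TransportConfig(K=0.0, direction="backward", seed=1)
        res = ds.run_simulation(sink_field, sched, sink_settlement, cfg)
        assert res.counts["landed"] == res.counts["released"] == 50
        # closed-form inward radial flow: all land in the island's cells
        island_cells = sink_settlement.active_ids
        assert set(res.landings["cell_id"]) <= island_cells

    def test_empty_settlement_no_landings(self, sink_field):
        sched = ds.ReleaseSchedule(site=(16.0, 24.0), particles_per_day=10,
                                   start_date="2024-04-25", end_date="2024-04-25")
        cfg = ds.TransportConfig(K=10.0, direction="backward", seed=1)
        res = ds.run_simulation(sink_field, sched, None, cfg)
        assert res.counts["landed"] == 0
        assert (res.counts["expired"] + res.counts["escaped"]
                + res.counts["active"]) == 10

    def test_particle_count_conservation(self, gyre_field, unit_grid):
        sched = ds.ReleaseSchedule(site=(5.0, 20.0), particles_per_day=20,
                                   start_date="2024-02-01", end_date="2024-02-03")
        cfg = ds.TransportConfig(K=10.0, direction="backward", seed=3,
                                 max_duration_days=10)
        res = ds.run_simulation(gyre_field, sched, None, cfg)
        c = res.counts
        assert c["released"] == 60
        assert c["landed"] + c["escaped"] + c["expired"] + c["active"] == 60

    def test_schedule_outside_field_rejected(self, gyre_field):
        sched = ds.ReleaseSchedule(site=(5.0, 20.0), particles_per_day=1,
                                   start_date="2030-01-01", end_date="2030-01-02")
        cfg = ds.TransportConfig()
        with pytest.raises(ValidationError):
            ds.run_simulation(gyre_field, sched, None, cfg)

    def test_drift_days_equals_elapsed_days(self, sink_field, sink_settlement):
        sched = ds.ReleaseSchedule(site=(16.0, 24.0), particles_per_day=20,
                                   start_date="2024-04-25", end_date="2024-04-25")
        cfg = ds.TransportConfig(K=10.0, direction="backward", seed=5)
        res = ds.run_simulation(sink_field, sched, sink_settlement, cfg)
        rel = res.landings["release_date"].to_numpy(dtype="datetime64[s]")
        land = res.landings["landing_date"].to_numpy(dtype="datetime64[s]")
        days = np.abs((land - rel) / np.timedelta64(1, "D"))
        np.testing.assert_array_equal(res.landings["drift_days"], days.astype(int))

    def test_order_independent_rng(self, gyre_field):
        """Per-particle substreams: a particle's path does not depend on how
        many other particles are in the run."""
        kw = dict(start_date="2024-02-01", end_date="2024-02-01")
        cfg = ds.TransportConfig(K=10.0, direction="forward", seed=9,
                                 max_duration_days=5)
        big = ds.run_simulation(
            gyre_field, ds.ReleaseSchedule(site=(5.0, 20.0), particles_per_day=8, **kw),
            None, cfg)
        small = ds.run_simulation(
            gyre_field, ds.ReleaseSchedule(site=(5.0, 20.0), particles_per_day=3, **kw),
            None, cfg)
        b = big.trajectories.query("particle_id == 2").reset_index(drop=True)
        s = small.trajectories.query("particle_id == 2").reset_index(drop=True)
        np.testing.assert_allclose(b[["lon", "lat"]], s[["lon", "lat"]])

    def test_regional_domain_exit_escapes(self):
        f = ds.synth.make_field("uniform", ((10.0, 20.0), (0.0, 5.0)), 0.5,
                                ("2024-01-01", "2024-03-01"), u0=0.3)
        assert not f.is_global_lon
        sched = ds.ReleaseSchedule(site=(18.0, 2.0), particles_per_day=5,
                                   start_date="2024-01-02", end_date="2024-01-02")
        cfg = ds.TransportConfig(K=0.0, direction="forward", seed=0)
        res = ds.run_simulation(f, sched, None, cfg)
        assert res.counts["escaped"] == 5
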