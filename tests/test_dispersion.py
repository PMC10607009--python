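"""Particle equation of motion: self-propulsion, vertical physics, boundaries."""

import numpy as np
import pytest

from conftest import START, make_ensemble
from mothflight.arrival import haversine
from mothflight.dispersion import (
    SimConfig,
    advance,
    apply_boundaries,
    leeward_velocity,
    run_simulation,
    vertical_increment,
)
from mothflight.release import ReleasePlan, build_release
from mothflight.synthetic import (
    KzSpec,
    ScenarioParams,
    TempSpec,
    WindSpec,
    lapse_for_ceiling,
    uniform_flow,
)


def single_particle_plan(takeoff="2021-04-30T10:00", start="2021-04-30T10:00",
                         lat=30.0, lon=125.0):
    return ReleasePlan(
        ids=np.array([0]),
        sources=np.array(["toy"], dtype=object),
        takeoff=np.array([np.datetime64(takeoff, "ns")]),
        lat=np.array([lat]),
        lon=np.array([lon]),
        zstar=np.array([0.0]),
        start=np.datetime64(start, "ns"),
        window_s=3600.0,
    )


class TestLeewardVelocity:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ((4.0, 3.0), None, (2.4, 1.8)),   # 3 m/s along the unit wind vector
            ((0.0, 0.0), None, (0.0, 0.0)),   # calm air: heading undefined
            ((10.0, 0.0), None, (3.0, 0.0)),  # ground speed 13 m/s downwind
        ],
    )
    def test_examples(self, u, v, expected):
        sx, sy = leeward_velocity(u[0], u[1], 3.0)
        assert (sx, sy) == pytest.approx(expected)

    def test_vectorised_matches_scalar(self):
        u = np.array([4.0, 0.0, 10.0])
        v = np.array([3.0, 0.0, 0.0])
        sx, sy = leeward_velocity(u, v, 3.0)
        np.testing.assert_allclose(sx, [2.4, 0.0, 3.0])
        np.testing.assert_allclose(sy, [1.8, 0.0, 0.0])


class TestVerticalIncrement:
    def test_all_zero_fields_give_zero(self):
        cfg = SimConfig(dt_s=120)
        dz = vertical_increment(0.0, 0.0, 0.0, cfg, ascending=False, R=0.3)
        assert dz == pytest.approx(0.0)

    def test_ascent_rate_90_m_per_step(self):
        # 0.75 m/s for a 120 s step; 1800 s airborne -> 1350 m, the radar anchor
        cfg = SimConfig(dt_s=120)
        dz = vertical_increment(0.0, 0.0, 0.0, cfg, ascending=True, R=0.0)
        assert dz == pytest.approx(90.0)
        assert 15 * dz == pytest.approx(1350.0)

    def test_random_walk_step_standard_deviation(self):
        # sqrt(24 Kz dt) * R with R ~ U[-0.5, 0.5]: step variance 2 Kz dt
        cfg = SimConfig(dt_s=120)
        rng = np.random.default_rng(11)
        R = rng.uniform(-0.5, 0.5, size=200_000)
        dz = vertical_increment(0.0, 10.0, 0.0, cfg, ascending=False, R=R)
        assert dz.std() == pytest.approx(np.sqrt(2 * 10.0 * 120.0), rel=0.01)
        assert np.abs(dz).max() <= np.sqrt(24 * 10.0 * 120.0) * 0.5 + 1e-9


class TestBoundaries:
    def test_ground_reflection(self, still_air_met):
        cfg = SimConfig()
        z = apply_boundaries(np.array([50.0]), np.array([-30.0]),
                             np.array([25.0]), still_air_met, cfg)
        assert z[0] == pytest.approx(30.0)

    def test_cold_candidate_cancels_vertical_move(self, still_air_met):
        cfg = SimConfig()
        z = apply_boundaries(np.array([1200.0]), np.array([1600.0]),
                             np.array([12.9]), still_air_met, cfg)
        assert z[0] == pytest.approx(1200.0)

    def test_horizontal_exit_deactivates(self, westerly_met):
        ens = make_ensemble(1, 500.0, lat=30.0, lon=139.9)
        cfg = SimConfig(dt_s=120, ascent_end_s=0)
        rng = np.random.default_rng(0)
        for k in range(10):
            advance(ens, westerly_met, cfg, START + np.timedelta64(120 * k, "s"), rng)
        assert not ens.active[0]
        assert ens.lon[0] <= 140.0  # frozen at the last valid position
        frozen = (ens.lat[0], ens.lon[0], ens.zstar[0])
        advance(ens, westerly_met, cfg, START + np.timedelta64(1200, "s"), rng)
        assert (ens.lat[0], ens.lon[0], ens.zstar[0]) == frozen


class TestAdvance:
    def test_future_takeoff_unmoved(self, westerly_met):
        ens = make_ensemble(1, 0.0, takeoff=START + np.timedelta64(30, "m"))
        advance(ens, westerly_met, SimConfig(), START, np.random.default_rng(1))
        assert (ens.lat[0], ens.lon[0], ens.zstar[0]) == (30.0, 125.0, 0.0)

    def test_still_air_post_ascent_horizontal_freeze(self, still_air_met):
        ens = make_ensemble(3, 1000.0)
        cfg = SimConfig(ascent_end_s=0)
        advance(ens, still_air_met, cfg, START, np.random.default_rng(2))
        np.testing.assert_array_equal(ens.lat, 30.0)
        np.testing.assert_array_equal(ens.lon, 125.0)

    def test_analytic_downwind_transport(self, westerly_met):
        # 10 m/s wind + 3 m/s self-speed for 10 h: 468 km within 0.5 %
        plan = single_particle_plan(lat=30.0, lon=120.0)
        cfg = SimConfig(dt_s=120, horizon_h=10, seed=0)
        traj = run_simulation(plan, westerly_met, cfg)
        d = haversine(traj.lat[0, 0], traj.lon[0, 0], traj.lat[-1, 0], traj.lon[-1, 0])
        assert d == pytest.approx(468.0, rel=0.005)


class TestRunSimulation:
    def test_snapshot_count_and_conservation(self, still_air_met, toy_source):
        plan = build_release([toy_source], START, n_per_source=20,
                             rng=np.random.default_rng(3))
        cfg = SimConfig(dt_s=120, horizon_h=2, seed=3)
        traj = run_simulation(plan, still_air_met, cfg)
        assert traj.times.size == 2 * 30 + 1
        assert traj.active.shape[1] == 20
        assert traj.hourly.sum() == 3

    def test_same_seed_identical_trajectories(self, still_air_met, toy_source):
        plan = build_release([toy_source], START, 10, rng=np.random.default_rng(4))
        cfg = SimConfig(dt_s=120, horizon_h=2, seed=9)
        a = run_simulation(plan, still_air_met, cfg)
        b = run_simulation(plan, still_air_met, cfg)
        np.testing.assert_array_equal(a.lat, b.lat)
        np.testing.assert_array_equal(a.zstar, b.zstar)

    def test_still_air_hover_height_closed_form(self, still_air_met):
        # climbing 0.75 m/s from individual take-off until one hour after the
        # release start: a 10:30 take-off ends its ascent at 1350 m and hovers
        plan = single_particle_plan(takeoff="2021-04-30T10:30")
        cfg = SimConfig(dt_s=120, horizon_h=2, seed=5)
        traj = run_simulation(plan, still_air_met, cfg)
        assert traj.zstar[-1, 0] == pytest.approx(0.75 * 1800.0)
        airborne = traj.times >= np.datetime64("2021-04-30T10:30", "ns")
        ascent = airborne & (traj.times <= np.datetime64("2021-04-30T11:00", "ns"))
        z = traj.zstar[ascent, 0]
        assert np.all(np.diff(z) > 0)  # strictly monotone ascent
        post = traj.zstar[traj.times > np.datetime64("2021-04-30T11:00", "ns"), 0]
        assert np.all(post == post[0])

    def test_no_teleport(self, westerly_met, toy_source):
        plan = build_release([toy_source], START, 30, rng=np.random.default_rng(6))
        cfg = SimConfig(dt_s=120, horizon_h=2, seed=6)
        traj = run_simulation(plan, westerly_met, cfg)
        step_km = haversine(traj.lat[:-1], traj.lon[:-1], traj.lat[1:], traj.lon[1:])
        limit_km = (10.0 + 3.0) * 120.0 / 1000.0
        assert step_km.max() <= limit_km * 1.005  # degree-conversion slack

    def test_insufficient_met_coverage_rejected(self, still_air_met, toy_source):
        plan = build_release([toy_source], START, 5, rng=np.random.default_rng(7))
        cfg = SimConfig(horizon_h=48)  # met only spans 12 h
        with pytest.raises(ValueError, match="coverage"):
            run_simulation(plan, still_air_met, cfg)


class TestTemperatureCeiling:
    def test_no_occupancy_of_cold_air(self, toy_source):
        # inversion crossing 13 degC at 1500 m: after every step all active
        # moths sit strictly above the ceiling temperature
        params = ScenarioParams(
            lat_min=25, lat_max=35, lon_min=120, lon_max=130, duration_h=4,
            levels=(0, 250, 500, 750, 1000, 1250, 1500, 1750, 2000),
            wind=WindSpec(kind="uniform", u0=3.0, v0=3.0),
            temp=TempSpec(surface_c=24.0, lapse_c_per_km=lapse_for_ceiling(24.0, 1500.0)),
            kz=KzSpec(kind="constant", k0=10.0),
        )
        met = uniform_flow(params)
        plan = build_release([toy_source], START, 100, rng=np.random.default_rng(8))
        cfg = SimConfig(dt_s=120, horizon_h=4, seed=8)
        traj = run_simulation(plan, met, cfg)
        for k in range(traj.times.size):
            act = traj.active[k]
            temps = met.sample(traj.times[k], traj.lat[k][act], traj.lon[k][act],
                               np.clip(traj.zstar[k][act], 0, 2000),
                               names=("temp",))["temp"]
            assert np.all(temps > 13.0)
        # the ceiling actually binds: ascent alone would overshoot 1500 m
        assert traj.zstar[-1].max() < 1500.0 + 1e-9
        assert traj.zstar[-1].max() > 1200.0
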