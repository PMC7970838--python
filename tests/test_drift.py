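"""Larval drift model: release scheduling, advection, DVM, densities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest, truncnorm

from driftquant.drift import (
    DVM_BAND_M,
    GROWTH_MM_PER_DAY,
    HATCH_LENGTH_MM,
    ParticleState,
    ReleaseConfig,
    SpawningGround,
    advect_step,
    density_grid,
    diel_target_depth,
    largest_remainder_counts,
    release_particles,
    run_simulation,
)
from driftquant.flowfield import EARTH_RADIUS_M

from conftest import make_field


def grounds4():
    return (
        SpawningGround("More", 5.8, 62.8, 0.5),
        SpawningGround("Haltenbanken", 8.2, 64.3, 0.2),
        SpawningGround("Sklinna", 10.0, 65.2, 0.1),
        SpawningGround("Rost", 11.0, 67.0, 0.2),
    )


# --------------------------------------------------------------------------- #
# Release scheduling
# --------------------------------------------------------------------------- #

class TestRelease:
    def test_per_ground_counts_are_exact_fractions(self):
        cfg = ReleaseConfig(grounds=grounds4(), total_particles=198_580, rng_seed=1)
        ens = release_particles(cfg)
        counts = pd.Series(ens.ground).value_counts()
        assert counts["More"] == 99_290
        assert counts["Haltenbanken"] == 39_716
        assert counts["Sklinna"] == 19_858
        assert counts["Rost"] == 39_716
        assert len(ens) == 198_580

    def test_zero_total_gives_empty_release(self):
        cfg = ReleaseConfig(grounds=grounds4(), total_particles=0)
        assert len(release_particles(cfg)) == 0

    def test_initial_state_is_newly_hatched(self):
        ens = release_particles(ReleaseConfig(grounds=grounds4(), total_particles=500))
        assert np.all(ens.length == HATCH_LENGTH_MM)
        assert np.all(ens.age == 0.0)
        assert np.all(ens.status == 0)

    def test_hatch_times_follow_truncated_gaussian(self):
        cfg = ReleaseConfig(grounds=grounds4(), total_particles=10_000, rng_seed=42)
        ens = release_particles(cfg)
        start, end = cfg.window
        days = (ens.hatch_time - start) / pd.Timedelta(days=1)
        assert days.min() >= 0 and days.max() <= (end - start) / pd.Timedelta(days=1)
        span = (end - start) / pd.Timedelta(days=1)
        mean_d, sd = span / 2.0, cfg.sd_days
        a, b = (0 - mean_d) / sd, (span - mean_d) / sd
        stat = kstest(days, truncnorm(a, b, loc=mean_d, scale=sd).cdf).statistic
        assert stat < 0.02

    def test_same_seed_reproduces_release_exactly(self):
        cfg = ReleaseConfig(grounds=grounds4(), total_particles=2000, rng_seed=7)
        a, b = release_particles(cfg), release_particles(cfg)
        assert np.array_equal(a.hatch_time.asi8, b.hatch_time.asi8)
        assert np.array_equal(a.lon, b.lon) and np.array_equal(a.ground, b.ground)

    def test_bad_fractions_rejected(self):
        bad = (SpawningGround("a", 5, 63, 0.6), SpawningGround("b", 6, 64, 0.6))
        with pytest.raises(ValueError, match="sum"):
            ReleaseConfig(grounds=bad)

    def test_empty_grounds_rejected(self):
        with pytest.raises(ValueError):
            ReleaseConfig(grounds=())

    def test_polygon_release_stays_inside(self):
        poly = ((5.0, 62.0), (6.0, 62.0), (6.0, 63.0), (5.0, 63.0))
        g = (SpawningGround("area", 5.5, 62.5, 1.0, polygon=poly),)
        ens = release_particles(ReleaseConfig(grounds=g, total_particles=300, rng_seed=3))
        assert np.all((ens.lon >= 5.0) & (ens.lon <= 6.0))
        assert np.all((ens.lat >= 62.0) & (ens.lat <= 63.0))

    @settings(max_examples=100, deadline=None)
    @given(
        total=st.integers(0, 10**6),
        weights=st.lists(st.floats(0.01, 1.0), min_size=1, max_size=8),
    )
    def test_largest_remainder_split_is_exact_and_fair(self, total, weights):
        fr = np.array(weights) / np.sum(weights)
        counts = largest_remainder_counts(total, fr)
        assert counts.sum() == total
        assert np.all(counts >= 0)
        # never off by a full unit from the exact share
        assert np.all(np.abs(counts - total * fr) < 1.0)


# --------------------------------------------------------------------------- #
# Advection
# --------------------------------------------------------------------------- #

def _particle(lon=0.0, lat=0.0, depth=20.0):
    return ParticleState(0, lon, lat, depth, HATCH_LENGTH_MM,
                         pd.Timestamp("2017-03-15"), 0.0, "g")


class TestAdvection:
    def test_zero_velocity_keeps_position_grows_length(self):
        f = make_field()
        p = advect_step(_particle(), f, "2017-03-15", 3600.0)
        assert (p.lon, p.lat) == (0.0, 0.0)
        assert p.length == HATCH_LENGTH_MM + GROWTH_MM_PER_DAY * (3600 / 86400)
        assert p.status == "active"

    def test_uniform_eastward_flow_matches_closed_form(self):
        f = make_field(u_fn=lambda lo, la: np.full_like(lo, 0.5))
        p, t = _particle(), pd.Timestamp("2017-03-15")
        for _ in range(24):
            p = advect_step(p, f, t, 3600.0)
            t += pd.Timedelta(hours=1)
        dx = np.deg2rad(p.lon) * EARTH_RADIUS_M
        assert dx == pytest.approx(0.5 * 86400, rel=1e-3)  # 43.2 km

    def test_solid_body_rotation_closes_orbit(self):
        omega = 2 * np.pi / (48 * 3600.0)

        def u_fn(lon, lat):
            return -omega * np.deg2rad(lat) * EARTH_RADIUS_M

        def v_fn(lon, lat):
            return omega * np.deg2rad(lon) * EARTH_RADIUS_M

        f = make_field(u_fn, v_fn, max_speed=20.0)
        radius_deg = 0.2
        p, t = _particle(lon=radius_deg), pd.Timestamp("2017-03-15")
        for _ in range(48):  # one full period at dt = 3600 s
            p = advect_step(p, f, t, 3600.0)
            t += pd.Timedelta(hours=1)
        radius_m = np.deg2rad(radius_deg) * EARTH_RADIUS_M
        miss = np.hypot(np.deg2rad(p.lon - radius_deg), np.deg2rad(p.lat)) * EARTH_RADIUS_M
        assert miss < 0.01 * radius_m

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError, match="dt"):
            advect_step(_particle(), make_field(), "2017-03-15", 0.0)

    def test_land_contact_beaches_particle(self):
        lon_ax = np.arange(-1, 2.01, 0.1)
        land = np.zeros((21, lon_ax.size), dtype=bool)
        land[:, lon_ax >= 0.55] = True  # coast from the 0.6 column eastward

        def u_fn(lon, lat):
            # onshore flow, zero only on the land cells themselves
            return np.where(lon >= 0.55, 0.0, 1.0)

        f = make_field(u_fn=u_fn, land_mask=land)
        p, t = _particle(lon=0.3), pd.Timestamp("2017-03-15")
        for _ in range(24 * 3):
            p = advect_step(p, f, t, 3600.0)
            t += pd.Timedelta(hours=1)
            if p.status != "active":
                break
        assert p.status == "beached"
        assert p.lon < 0.6  # frozen at the last wet position

    def test_domain_exit_freezes_particle(self):
        f = make_field(u_fn=lambda lo, la: np.full_like(lo, 1.0))
        p, t = _particle(lon=1.9), pd.Timestamp("2017-03-15")
        for _ in range(24 * 5):
            p = advect_step(p, f, t, 3600.0)
            t += pd.Timedelta(hours=1)
            if p.status != "active":
                break
        assert p.status == "exited"
        assert f.lon[0] <= p.lon <= f.lon[-1]


class TestDVM:
    def test_day_and_night_targets(self):
        # equatorial noon/midnight are unambiguous day and night
        assert diel_target_depth("2017-03-20 12:07", 0.0, 0.0) == DVM_BAND_M[1]
        assert diel_target_depth("2017-03-20 00:07", 0.0, 0.0) == DVM_BAND_M[0]

    def test_midnight_sun_uses_fallback_window(self):
        # polar day: shallow only inside the window around solar midnight
        assert diel_target_depth("2017-06-21 23:00", 15.0, 70.0) == DVM_BAND_M[0]
        assert diel_target_depth("2017-06-21 11:00", 15.0, 70.0) == DVM_BAND_M[1]

    def test_depth_stays_in_band_and_moves_at_swim_speed(self):
        f = make_field()
        p = _particle(depth=5.0)
        # midday: swims down toward 40 m at 0.1 BL/s = 0.9 mm/s for 9 mm larva
        p2 = advect_step(p, f, "2017-03-20 12:07", 3600.0)
        expected = min(5.0 + 0.1 * 9e-3 * 3600, 40.0)
        assert p2.depth == pytest.approx(expected)
        assert DVM_BAND_M[0] <= p2.depth <= DVM_BAND_M[1]


# --------------------------------------------------------------------------- #
# Simulation driver and densities
# --------------------------------------------------------------------------- #

def small_release(n=200, seed=11, window=("2017-03-15", "2017-03-17")):
    return ReleaseConfig(
        grounds=grounds4(), total_particles=n, rng_seed=seed,
        hatch_start=window[0], hatch_end=window[1],
    )


class TestSimulation:
    def test_particle_budget_conserved_at_every_snapshot(self, jet_field):
        res = run_simulation(small_release(), jet_field, end_date="2017-03-25")
        for snap in res.snapshots:
            counts = snap["status"].value_counts()
            assert counts.sum() == 200

    def test_mean_latitude_increases_in_northward_jet(self):
        from driftquant.synthetic import gen_flow_field

        field = gen_flow_field(n_days=40, eddy_amplitude=0.0, seed=0)
        res = run_simulation(small_release(), field, end_date="2017-04-05")
        # after the 2-day hatch window everyone drifts north
        lats = [s["lat"].mean() for s in res.snapshots[3:]]
        assert np.all(np.diff(lats) > 0)

    def test_length_age_relation_exact(self, jet_field):
        res = run_simulation(small_release(), jet_field, end_date="2017-03-30")
        final = res.snapshots[-1]
        assert np.array_equal(
            final["length"].to_numpy(),
            HATCH_LENGTH_MM + GROWTH_MM_PER_DAY * final["age"].to_numpy(),
        )

    def test_depths_confined_to_dvm_band(self, jet_field):
        res = run_simulation(small_release(), jet_field, end_date="2017-03-30")
        final = res.snapshots[-1]
        act = final[final["status"] == "active"]
        assert act["depth"].between(*DVM_BAND_M).all()

    def test_same_seed_reproduces_trajectories_exactly(self, jet_field):
        r1 = run_simulation(small_release(), jet_field, end_date="2017-03-22")
        r2 = run_simulation(small_release(), jet_field, end_date="2017-03-22")
        pd.testing.assert_frame_equal(r1.snapshots[-1], r2.snapshots[-1])

    def test_end_at_window_start_means_no_displacement(self, jet_field):
        cfg = small_release()
        res = run_simulation(cfg, jet_field, end_date=cfg.hatch_start)
        snap = res.snapshots[-1]
        ens = release_particles(cfg)
        assert np.array_equal(snap["lon"].to_numpy(), ens.lon)
        assert np.array_equal(snap["lat"].to_numpy(), ens.lat)

    def test_field_ending_before_window_rejected(self):
        f = make_field(n_days=2, start="2016-01-01")
        with pytest.raises(ValueError):
            run_simulation(small_release(), f, end_date="2017-04-01")


class TestDensityGrid:
    def _result(self, jet_field):
        return run_simulation(small_release(), jet_field, end_date="2017-03-20")

    def test_single_particle_occupies_one_cell(self, jet_field):
        res = run_simulation(
            ReleaseConfig(grounds=(SpawningGround("x", 8.0, 64.0, 1.0),),
                          total_particles=1, hatch_start="2017-03-15",
                          hatch_end="2017-03-16"),
            jet_field, end_date="2017-03-16",
        )
        g = density_grid(res, res.snapshot_times[0], np.arange(2, 16.5, 0.5),
                         np.arange(62, 72.1, 0.5))
        assert g.counts.sum() == 1
        assert (g.counts > 0).sum() == 1
        assert g.counts.max() == 1

    def test_raw_total_equals_in_grid_active_particles(self, jet_field):
        res = self._result(jet_field)
        g = density_grid(res, res.snapshot_times[-1], np.arange(2, 16.5, 0.5),
                         np.arange(62, 72.1, 0.5))
        snap = res.snapshots[-1]
        act = snap[snap["status"] == "active"]
        in_grid = act[(act["lon"].between(2, 16)) & (act["lat"].between(62, 72))]
        assert g.counts.sum() == len(in_grid)

    def test_transforms(self, jet_field):
        res = self._result(jet_field)
        edges = (np.arange(2, 16.5, 4), np.arange(62, 72.1, 4))
        raw = density_grid(res, res.snapshot_times[-1], *edges, "raw")
        logn = density_grid(res, res.snapshot_times[-1], *edges, "log_n")
        sqr = density_grid(res, res.snapshot_times[-1], *edges, "sqrt_n")
        assert np.allclose(logn.values, np.log(raw.counts + 1))
        assert np.allclose(sqr.values, np.sqrt(raw.counts))
        # 49 particles in a cell transforms to exactly 7
        assert np.sqrt(49) == 7.0

    def test_unknown_transform_rejected(self, jet_field):
        res = self._result(jet_field)
        with pytest.raises(ValueError, match="transform"):
            density_grid(res, res.snapshot_times[-1], np.arange(2, 16.5, 0.5),
                         np.arange(62, 72.1, 0.5), "cuberoot")

    def test_missing_snapshot_rejected(self, jet_field):
        res = self._result(jet_field)
        with pytest.raises(KeyError):
            density_grid(res, "1999-01-01", np.arange(2, 16.5, 0.5),
                         np.arange(62, 72.1, 0.5))
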