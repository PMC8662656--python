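import numpy as np
import pytest
import xarray as xr

from ventseep.ocean import EARTH_RADIUS_M, OceanConfig, make_synthetic_ocean
from ventseep.particles import (
    ParticleSet,
    advect,
    basin_exchange,
    default_gates,
    release_particles,
    trough_polygon,
)


@pytest.fixture(scope="module")
def ocean():
    cfg = OceanConfig(levels=(500, 1000, 1250), n_days=40)
    return cfg, make_synthetic_ocean(cfg, rng_seed=3)


def _flat_field(u_fn, v_fn, extent=1.0, step=0.05):
    lat = np.arange(-extent, extent + 1e-9, step)
    lon = np.arange(-extent, extent + 1e-9, step)
    lon2, lat2 = np.meshgrid(lon, lat)
    x = np.deg2rad(lon2) * EARTH_RADIUS_M
    y = np.deg2rad(lat2) * EARTH_RADIUS_M
    field = xr.Dataset(
        {"u": (("lat", "lon"), u_fn(x, y)), "v": (("lat", "lon"), v_fn(x, y))},
        coords={"lat": lat, "lon": lon},
    )
    bathy = xr.DataArray(
        np.full(lat2.shape, 5000.0), coords={"lat": lat, "lon": lon},
        dims=("lat", "lon"),
    )
    return field, bathy


class TestReleaseParticles:
    def test_all_within_radius(self, ocean):
        cfg, ds = ocean
        ps = release_particles((123.0, 26.0), 1000, 2000, "2011-01-01",
                               ds["bathymetry"], radius_km=25, rng_seed=1)
        d = _gc_km(ps.lon, ps.lat, 123.0, 26.0)
        assert d.max() <= 25.0 + 1e-6

    def test_area_uniform_mean_distance(self, ocean):
        """Uniform disk: E[distance to center] = (2/3) * radius."""
        cfg, ds = ocean
        ps = release_particles((123.0, 26.0), 1000, 20_000, "2011-01-01",
                               ds["bathymetry"], radius_km=25, rng_seed=2)
        d = _gc_km(ps.lon, ps.lat, 123.0, 26.0)
        assert d.mean() == pytest.approx(2 / 3 * 25, rel=0.01)

    def test_tiny_radius_collapses_to_center(self, ocean):
        cfg, ds = ocean
        ps = release_particles((123.0, 26.0), 1000, 50, "2011-01-01",
                               ds["bathymetry"], radius_km=1e-6, rng_seed=0)
        assert np.allclose(ps.lon, 123.0, atol=1e-6)
        assert np.allclose(ps.lat, 26.0, atol=1e-6)

    def test_land_center_rejected(self, ocean):
        cfg, ds = ocean
        with pytest.raises(ValueError, match="center"):
            release_particles((123.0, 31.0), 1000, 10, "2011-01-01",
                              ds["bathymetry"])

    def test_deterministic(self, ocean):
        cfg, ds = ocean
        a = release_particles((123.0, 26.0), 1000, 100, "2011-01-01",
                              ds["bathymetry"], rng_seed=5)
        b = release_particles((123.0, 26.0), 1000, 100, "2011-01-01",
                              ds["bathymetry"], rng_seed=5)
        assert np.array_equal(a.lon, b.lon) and np.array_equal(a.lat, b.lat)


def _gc_km(lon, lat, lon0, lat0):
    p1 = np.deg2rad(lat)
    p0 = np.deg2rad(lat0)
    dl = np.deg2rad(lon - lon0)
    h = np.sin((p1 - p0) / 2) ** 2 + np.cos(p0) * np.cos(p1) * np.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(h)) / 1000


class TestAdvect:
    def test_zero_field_keeps_particles_still(self):
        field, bathy = _flat_field(lambda x, y: 0 * x, lambda x, y: 0 * x)
        ps = ParticleSet(lon=np.array([0.1, -0.2]), lat=np.array([0.0, 0.3]),
                         depth=0.0, release_date=np.datetime64("2011-01-01"),
                         center=(0, 0), radius_km=0)
        traj = advect(ps, field, bathy, 5)
        assert np.allclose(traj.lon[-1], ps.lon) and np.allclose(traj.lat[-1], ps.lat)

    def test_solid_body_rotation_returns_to_start(self):
        """RK5(4) on u=-Omega*y, v=Omega*x: one period closes the orbit to
        <1e-3 of the radius and radius drift stays below 0.1%."""
        period_days = 10
        omega = 2 * np.pi / (period_days * 86_400.0)
        field, bathy = _flat_field(lambda x, y: -omega * y, lambda x, y: omega * x)
        r0 = 25_000.0
        lon0 = np.rad2deg(r0 / EARTH_RADIUS_M)
        ps = ParticleSet(lon=np.array([lon0]), lat=np.array([0.0]), depth=0.0,
                         release_date=np.datetime64("2011-01-01"),
                         center=(0, 0), radius_km=0)
        traj = advect(ps, field, bathy, period_days)
        x = np.deg2rad(traj.lon[:, 0]) * EARTH_RADIUS_M
        y = np.deg2rad(traj.lat[:, 0]) * EARTH_RADIUS_M
        radius = np.hypot(x, y)
        assert np.abs(radius - r0).max() / r0 < 1e-3          # < 0.1% drift
        assert np.hypot(x[-1] - r0, y[-1]) / r0 < 1e-3        # orbit closes

    def test_halving_rtol_changes_little(self):
        period_days = 10
        omega = 2 * np.pi / (period_days * 86_400.0)
        field, bathy = _flat_field(lambda x, y: -omega * y, lambda x, y: omega * x)
        lon0 = np.rad2deg(25_000.0 / EARTH_RADIUS_M)
        ps = ParticleSet(lon=np.array([lon0]), lat=np.array([0.0]), depth=0.0,
                         release_date=np.datetime64("2011-01-01"),
                         center=(0, 0), radius_km=0)
        a = advect(ps, field, bathy, period_days, rtol=1e-5)
        b = advect(ps, field, bathy, period_days, rtol=5e-6)
        drift = np.hypot(a.lon[-1, 0] - b.lon[-1, 0], a.lat[-1, 0] - b.lat[-1, 0])
        assert drift < 1e-5  # degrees; far below the solver's error budget

    def test_beached_particles_stop_and_never_resume(self, ocean):
        cfg, ds = ocean
        ps = release_particles((123.0, 26.8), 1000, 300, "2011-01-01",
                               ds["bathymetry"], radius_km=25, rng_seed=4)
        traj = advect(ps, ds, ds["bathymetry"], 39)
        status = traj.status
        # one-way transitions: once beached/exited, never active again
        for t in range(1, status.shape[0]):
            regressed = (status[t - 1] > 0) & (status[t] != status[t - 1])
            assert not regressed.any()
        # beached particles keep their final position
        beached_at = (status[:-1] == 0) & (status[1:] == 1)
        for t, pid in zip(*np.nonzero(beached_at)):
            assert traj.lon[t + 1, pid] == traj.lon[-1, pid]

    def test_masking_invariant_every_output_step(self, ocean):
        """No active particle ever occupies a cell shallower than its depth."""
        cfg, ds = ocean
        from ventseep.particles import _nearest_cell_depth

        ps = release_particles((123.0, 26.0), 1000, 300, "2011-01-01",
                               ds["bathymetry"], radius_km=25, rng_seed=6)
        traj = advect(ps, ds, ds["bathymetry"], 39)
        for t in range(traj.status.shape[0]):
            act = traj.status[t] == 0
            if act.any():
                cell = _nearest_cell_depth(
                    ds["bathymetry"], traj.lon[t, act], traj.lat[t, act]
                )
                assert (cell >= 1000).all()

    def test_seed_determinism_end_to_end(self, ocean):
        cfg, ds = ocean
        out = []
        for _ in range(2):
            ps = release_particles((123.0, 26.0), 1000, 50, "2011-01-01",
                                   ds["bathymetry"], rng_seed=11)
            traj = advect(ps, ds, ds["bathymetry"], 10)
            out.append((traj.lon.copy(), traj.lat.copy(), traj.status.copy()))
        assert np.array_equal(out[0][0], out[1][0])
        assert np.array_equal(out[0][2], out[1][2])


class TestBasinExchange:
    def test_static_particles_inside_counted_constant(self):
        field, bathy = _flat_field(lambda x, y: 0 * x, lambda x, y: 0 * x)
        ps = ParticleSet(lon=np.array([0.0, 0.1]), lat=np.array([0.0, 0.1]),
                         depth=0.0, release_date=np.datetime64("2011-01-01"),
                         center=(0, 0), radius_km=0)
        traj = advect(ps, field, bathy, 5)
        poly = [(-0.5, -0.5), (0.5, -0.5), (0.5, 0.5), (-0.5, 0.5)]
        res = basin_exchange(traj, poly)
        assert (res.counts["n_inside"] == 2).all()
        assert (res.counts["cum_crossed"] == 0).all()

    def test_straight_crossing_attributed_to_gate(self):
        u0 = 0.5  # m/s eastward
        field, bathy = _flat_field(lambda x, y: 0 * x + u0, lambda x, y: 0 * x)
        ps = ParticleSet(lon=np.array([-0.3]), lat=np.array([0.0]), depth=0.0,
                         release_date=np.datetime64("2011-01-01"),
                         center=(0, 0), radius_km=0)
        traj = advect(ps, field, bathy, 3)
        poly = [(-0.5, -0.5), (0.2, -0.5), (0.2, 0.5), (-0.5, 0.5)]
        gates = {"east_gate": ((0.2, -0.1), (0.2, 0.1))}
        res = basin_exchange(traj, poly, gates)
        assert res.gate_crossings == {"east_gate": 1, "other": 0}
        assert res.counts["cum_crossed"].iloc[-1] == 1
        assert res.counts["cum_crossed"].is_monotonic_increasing

    def test_invalid_polygon_rejected(self):
        field, bathy = _flat_field(lambda x, y: 0 * x, lambda x, y: 0 * x)
        ps = ParticleSet(lon=np.array([0.0]), lat=np.array([0.0]), depth=0.0,
                         release_date=np.datetime64("2011-01-01"),
                         center=(0, 0), radius_km=0)
        traj = advect(ps, field, bathy, 1)
        bowtie = [(0, 0), (1, 1), (1, 0), (0, 1)]
        with pytest.raises(ValueError, match="polygon"):
            basin_exchange(traj, bowtie)

    def test_basin_open_above_sill_sealed_below_gaps(self):
        """Topographic constraint on exchange: particles leave the basin at
        500 m (the whole ridge is below them) but none escape at 1,250 m,
        which lies below the sill and below every gap channel's floor."""
        results = {}
        for depth, days in ((500, 240), (1250, 60)):
            cfg = OceanConfig(levels=(depth,), n_days=days, eddy_energy=0.6)
            ds = make_synthetic_ocean(cfg, rng_seed=8)
            ps = release_particles((123.0, 25.8), depth, 400, "2011-01-01",
                                   ds["bathymetry"], radius_km=40, rng_seed=9)
            traj = advect(ps, ds, ds["bathymetry"], days - 1)
            res = basin_exchange(traj, trough_polygon(cfg), default_gates(cfg))
            results[depth] = int(res.counts["cum_crossed"].iloc[-1])
        assert results[500] > 0
        assert results[1250] == 0
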