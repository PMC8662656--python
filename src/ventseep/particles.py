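"""Lagrangian particle release, advection and basin-exchange accounting.

Particles represent passively drifting lecithotrophic larvae: they are
released uniformly within a disk around a site, stay at their release
depth (horizontal-only advection), and are integrated through the
gridded velocity field with an adaptive Dormand-Prince RK5(4) scheme.
Velocity is sampled by bicubic interpolation in the horizontal and
linear interpolation in time between daily snapshots; positions advance
on the sphere (angular rates ``u / (R cos(phi))``, ``v / R``).

A particle entering a grid cell whose seafloor is shallower than its
depth — or a land cell — *beaches* and stops (terminal; larvae have no
documented swimming ability to escape).  Leaving the domain marks it
*exited*.  Both checks run at every daily output step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.integrate import solve_ivp
from scipy.interpolate import RectBivariateSpline
from shapely import contains_xy
from shapely.geometry import LineString, Point, Polygon

from .ocean import EARTH_RADIUS_M

ACTIVE, BEACHED, EXITED = 0, 1, 2
_STATUS_NAMES = {ACTIVE: "active", BEACHED: "beached", EXITED: "exited-domain"}


@dataclass
class ParticleSet:
    lon: np.ndarray
    lat: np.ndarray
    depth: float
    release_date: np.datetime64
    center: tuple[float, float]
    radius_km: float

    @property
    def n(self) -> int:
        return self.lon.size


@dataclass
class TrajectorySet:
    """Daily particle positions and status codes."""

    times: pd.DatetimeIndex
    lon: np.ndarray          # (n_times, n)
    lat: np.ndarray
    status: np.ndarray       # (n_times, n) int8
    depth: float

    @property
    def n(self) -> int:
        return self.lon.shape[1]

    def final_status_counts(self) -> dict[str, int]:
        last = self.status[-1]
        return {name: int((last == code).sum()) for code, name in _STATUS_NAMES.items()}

    def to_dataframe(self) -> pd.DataFrame:
        n_t, n = self.lon.shape
        return pd.DataFrame(
            {
                "id": np.tile(np.arange(n), n_t),
                "time": np.repeat(self.times.values, n),
                "lon": self.lon.ravel(),
                "lat": self.lat.ravel(),
                "status": [
                    _STATUS_NAMES[s] for s in self.status.ravel()
                ],
            }
        )


def _nearest_cell_depth(bathy: xr.DataArray, lon: np.ndarray, lat: np.ndarray
                        ) -> np.ndarray:
    lons = bathy["lon"].values
    lats = bathy["lat"].values
    i = np.clip(np.round((lat - lats[0]) / (lats[1] - lats[0])).astype(int),
                0, lats.size - 1)
    j = np.clip(np.round((lon - lons[0]) / (lons[1] - lons[0])).astype(int),
                0, lons.size - 1)
    return bathy.values[i, j]


def release_particles(
    center: tuple[float, float],
    depth: float,
    n: int,
    date,
    bathy: xr.DataArray,
    radius_km: float = 25.0,
    rng_seed: int = 0,
) -> ParticleSet:
    """Area-uniform release within a great-circle disk around ``center``.

    Points falling on land or on seafloor shallower than the release
    depth are resampled; an entirely unsuitable disk raises.
    """
    lon0, lat0 = center
    if _nearest_cell_depth(bathy, np.array([lon0]), np.array([lat0]))[0] < depth:
        raise ValueError("release center is on land or shallower than the depth")
    rng = np.random.default_rng(rng_seed)
    lon = np.empty(n)
    lat = np.empty(n)
    todo = np.arange(n)
    phi0 = np.deg2rad(lat0)
    lam0 = np.deg2rad(lon0)
    for _ in range(200):
        m = todo.size
        if m == 0:
            break
        delta = (radius_km * 1000 / EARTH_RADIUS_M) * np.sqrt(rng.random(m))
        alpha = 2 * np.pi * rng.random(m)
        phi = np.arcsin(
            np.sin(phi0) * np.cos(delta) + np.cos(phi0) * np.sin(delta) * np.cos(alpha)
        )
        lam = lam0 + np.arctan2(
            np.sin(alpha) * np.sin(delta) * np.cos(phi0),
            np.cos(delta) - np.sin(phi0) * np.sin(phi),
        )
        lon[todo] = np.rad2deg(lam)
        lat[todo] = np.rad2deg(phi)
        ok = _nearest_cell_depth(bathy, lon[todo], lat[todo]) >= depth
        todo = todo[~ok]
    else:
        raise ValueError("release disk lies (almost) entirely on unsuitable seafloor")
    return ParticleSet(
        lon=lon, lat=lat, depth=float(depth),
        release_date=np.datetime64(pd.Timestamp(date)),
        center=(lon0, lat0), radius_km=radius_km,
    )


def _level_fields(field: xr.Dataset, depth: float) -> xr.Dataset:
    if "depth" in field.dims:
        zi = int(np.argmin(np.abs(field["depth"].values - depth)))
        return field.isel(depth=zi)
    return field


class _Sampler:
    """Bicubic space / linear time velocity sampler for one depth level."""

    def __init__(self, field: xr.Dataset, depth: float):
        lf = _level_fields(field, depth)
        self.lat = lf["lat"].values
        self.lon = lf["lon"].values
        self.static = "time" not in lf["u"].dims
        if self.static:
            self.u = lf["u"].values[None]
            self.v = lf["v"].values[None]
            self.times = None
        else:
            self.u = lf["u"].values
            self.v = lf["v"].values
            self.times = pd.DatetimeIndex(lf["time"].values)
        kx = min(3, self.lat.size - 1)
        ky = min(3, self.lon.size - 1)
        self._cache: dict[int, tuple] = {}
        self._kx, self._ky = kx, ky

    def n_snapshots(self) -> int:
        return self.u.shape[0]

    def splines(self, ti: int):
        if ti not in self._cache:
            self._cache[ti] = (
                RectBivariateSpline(self.lat, self.lon, self.u[ti],
                                    kx=self._kx, ky=self._ky),
                RectBivariateSpline(self.lat, self.lon, self.v[ti],
                                    kx=self._kx, ky=self._ky),
            )
            for old in [k for k in self._cache if k < ti - 1]:
                del self._cache[old]
        return self._cache[ti]

    def velocity(self, ti0: int, tau: float, lon, lat):
        """Velocity at fraction ``tau`` of day between snapshots ti0, ti0+1."""
        su0, sv0 = self.splines(ti0)
        lat_c = np.clip(lat, self.lat[0], self.lat[-1])
        lon_c = np.clip(lon, self.lon[0], self.lon[-1])
        u = su0.ev(lat_c, lon_c)
        v = sv0.ev(lat_c, lon_c)
        if not self.static and ti0 + 1 < self.u.shape[0] and tau > 0:
            su1, sv1 = self.splines(ti0 + 1)
            u = (1 - tau) * u + tau * su1.ev(lat_c, lon_c)
            v = (1 - tau) * v + tau * sv1.ev(lat_c, lon_c)
        if np.any(~np.isfinite(u)) or np.any(~np.isfinite(v)):
            raise ValueError("NaN velocity encountered: corrupt field")
        return u, v


def advect(
    particles: ParticleSet,
    field: xr.Dataset,
    bathy: xr.DataArray,
    duration_days: int,
    rtol: float = 1e-5,
    atol: float = 1e-8,
) -> TrajectorySet:
    """Integrate particles through the field with adaptive RK5(4).

    Daily chunks; within a chunk the velocity is linear in time between
    the two bounding snapshots.  Status transitions (active -> beached /
    exited) are one-way and evaluated at each daily output.
    """
    sampler = _Sampler(field, particles.depth)
    if sampler.static:
        start_index = 0
        n_snap = None
    else:
        t0 = pd.Timestamp(particles.release_date)
        start_index = int(np.searchsorted(sampler.times.values, np.datetime64(t0)))
        n_snap = sampler.n_snapshots()
        if start_index + duration_days > n_snap - 1:
            raise ValueError("duration exceeds the field's time span")

    n = particles.n
    lon = particles.lon.copy()
    lat = particles.lat.copy()
    status = np.zeros(n, dtype=np.int8)
    out_lon = np.empty((duration_days + 1, n))
    out_lat = np.empty((duration_days + 1, n))
    out_status = np.empty((duration_days + 1, n), dtype=np.int8)

    lon_lims = (sampler.lon[0], sampler.lon[-1])
    lat_lims = (sampler.lat[0], sampler.lat[-1])

    def check(day):
        nonlocal status
        act = status == ACTIVE
        off = act & (
            (lon < lon_lims[0]) | (lon > lon_lims[1])
            | (lat < lat_lims[0]) | (lat > lat_lims[1])
        )
        status[off] = EXITED
        act = status == ACTIVE
        if act.any():
            cell = _nearest_cell_depth(bathy, lon[act], lat[act])
            grounded = (cell < particles.depth) | (cell <= 0)
            ids = np.flatnonzero(act)[grounded]
            status[ids] = BEACHED
        out_lon[day] = lon
        out_lat[day] = lat
        out_status[day] = status

    check(0)
    deg = 180.0 / np.pi
    for day in range(duration_days):
        act = np.flatnonzero(status == ACTIVE)
        if act.size:
            ti = start_index if sampler.static else start_index + day

            def rhs(t, y, ti=ti, m=act.size):
                lo = y[:m]
                la = y[m:]
                tau = 0.0 if sampler.static else t / 86400.0
                u, v = sampler.velocity(ti, tau, lo, la)
                dlon = u / (EARTH_RADIUS_M * np.cos(np.deg2rad(la))) * deg
                dlat = v / EARTH_RADIUS_M * deg
                return np.concatenate([dlon, dlat])

            y0 = np.concatenate([lon[act], lat[act]])
            sol = solve_ivp(
                rhs, (0.0, 86400.0), y0, method="RK45", rtol=rtol, atol=atol,
            )
            if not sol.success:
                raise RuntimeError(f"integration failed on day {day}: {sol.message}")
            lon[act] = sol.y[: act.size, -1]
            lat[act] = sol.y[act.size:, -1]
        check(day + 1)

    times = pd.date_range(pd.Timestamp(particles.release_date),
                          periods=duration_days + 1, freq="D")
    return TrajectorySet(times=times, lon=out_lon, lat=out_lat,
                         status=out_status, depth=particles.depth)


# --- basin exchange ---------------------------------------------------------

@dataclass
class ExchangeResult:
    counts: pd.DataFrame             # time, n_inside, n_outside, cum_crossed
    gate_crossings: dict[str, int]   # first crossings attributed per gate
    first_crossing: pd.DataFrame     # particle id, time, gate


def basin_exchange(
    traj: TrajectorySet,
    basin_polygon,
    gates: dict[str, tuple[tuple[float, float], tuple[float, float]]] | None = None,
    max_gate_distance: float = 1.0,
) -> ExchangeResult:
    """Count particles inside/outside a basin and attribute crossings.

    ``basin_polygon`` is a shapely Polygon or a coordinate sequence.
    The *first* boundary crossing of each particle (in either direction)
    is attributed to the nearest gate segment, or to ``"other"`` when no
    gate lies within ``max_gate_distance`` degrees of the crossing
    midpoint.  Cumulative crossing counts are monotone by construction.
    """
    poly = basin_polygon if isinstance(basin_polygon, Polygon) else Polygon(basin_polygon)
    if not poly.is_valid:
        raise ValueError("basin polygon is invalid (self-intersecting?)")
    gates = gates or {}
    gate_lines = {name: LineString(seg) for name, seg in gates.items()}

    n_t, n = traj.lon.shape
    inside = np.empty((n_t, n), dtype=bool)
    for t in range(n_t):
        inside[t] = contains_xy(poly, traj.lon[t], traj.lat[t])

    changed = inside != inside[0]
    first_t = np.where(changed.any(axis=0), changed.argmax(axis=0), -1)

    names, times, ids = [], [], []
    gate_counts = {name: 0 for name in gates}
    gate_counts["other"] = 0
    for pid in np.flatnonzero(first_t > 0):
        t = first_t[pid]
        mid = Point(
            0.5 * (traj.lon[t - 1, pid] + traj.lon[t, pid]),
            0.5 * (traj.lat[t - 1, pid] + traj.lat[t, pid]),
        )
        best, best_d = "other", max_gate_distance
        for name, line in gate_lines.items():
            d = line.distance(mid)
            if d <= best_d:
                best, best_d = name, d
        gate_counts[best] += 1
        ids.append(pid)
        times.append(traj.times[t])
        names.append(best)

    crossed_by = np.where(first_t > 0, first_t, n_t + 1)
    cum = np.array([(crossed_by <= t).sum() for t in range(n_t)])
    counts = pd.DataFrame(
        {
            "time": traj.times,
            "n_inside": inside.sum(axis=1),
            "n_outside": n - inside.sum(axis=1),
            "cum_crossed": cum,
        }
    )
    return ExchangeResult(
        counts=counts,
        gate_crossings=gate_counts,
        first_crossing=pd.DataFrame({"id": ids, "time": times, "gate": names}),
    )


def trough_polygon(config) -> Polygon:
    """The trough basin including its bounding ridge band and land rims.

    Only the southern edge (the ridge with its gap channels) is a real
    flow boundary; the western, northern and eastern edges sit on land or
    on the enclosing ridge cap, with a margin so that particles beaching
    on the rim still count as retained.
    """
    ridge_w = config.ridge_lat[1] - config.ridge_lat[0]
    west = config.trough_lon[0] - 0.75
    east = config.trough_lon[1] + ridge_w + 0.25
    north = config.shelf_lat + 0.75
    south = config.ridge_lat[0]
    return Polygon([(west, south), (east, south), (east, north), (west, north)])


def default_gates(config) -> dict[str, tuple[tuple[float, float], tuple[float, float]]]:
    """Gate segments on the basin boundary, one per ridge gap."""
    y = config.ridge_lat[0]
    return {
        name: ((gap.lon_min, y), (gap.lon_max, y))
        for name, gap in config.gaps.items()
    }
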