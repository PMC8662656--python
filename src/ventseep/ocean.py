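"""Synthetic gridded ocean: a semi-enclosed deep trough with a sill.

The generator emulates the oceanographic setting relevant to deep-sea
larval dispersal in a marginal-sea trough: an elongated deep basin
(> 2,000 m) bounded on its ocean side by a ridge whose crest (the
*sill*) blocks lateral exchange below the sill depth, except through a
few deeper gap channels.  A boundary current flows along the ridge and
a weaker cyclonic gyre recirculates inside the trough; both decay with
depth as ``U(z) = U0 * exp(-z/H)`` with ``U0 = 1 m/s`` at the surface
and ``H`` chosen so the speed is 0.1 m/s at 1,000 m.  A stochastic
mesoscale eddy field, built from a smoothed random stream function per
level (hence discretely non-divergent), is superimposed with AR(1)
day-to-day persistence.

Fields live on a regular lat/lon/depth/daily-time grid as an xarray
Dataset with variables ``u``, ``v`` (m/s) and ``bathymetry`` (m,
positive down; land where <= 0).  Velocities are zeroed wherever the
seafloor is shallower than the level depth (topographic constraint).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter

EARTH_RADIUS_M = 6_371_000.0


@dataclass
class GapSpec:
    """A deeper channel through the bounding ridge."""

    lon_min: float
    lon_max: float
    depth: float        # channel floor depth (m); open to levels above it


@dataclass
class OceanConfig:
    # grid
    lon_min: float = 118.0
    lon_max: float = 130.0
    lat_min: float = 20.0
    lat_max: float = 32.0
    dlon: float = 0.25
    dlat: float = 0.25
    levels: tuple[float, ...] = (0, 500, 600, 700, 800, 1000, 1250)
    n_days: int = 1096
    start_date: str = "2011-01-01"
    # bathymetry
    open_ocean_depth: float = 5000.0
    trough_depth: float = 2200.0
    trough_lat: tuple[float, float] = (25.0, 27.5)
    trough_lon: tuple[float, float] = (119.0, 127.0)
    ridge_lat: tuple[float, float] = (24.0, 25.0)
    sill_depth: float = 750.0
    shelf_lat: float = 27.5        # land north of this latitude
    gaps: dict[str, GapSpec] = field(
        default_factory=lambda: {
            "east_of_taiwan": GapSpec(119.0, 119.8, 900.0),
            "kerama_gap": GapSpec(122.8, 123.6, 1100.0),
            "east_of_okinawa": GapSpec(125.6, 126.4, 700.0),
        }
    )
    # currents
    u_surface: float = 1.0         # jet-core speed at the surface (m/s)
    u_1000m: float = 0.1           # jet-core speed at 1,000 m (m/s)
    jet_lat: float = 23.2          # boundary-current axis (ocean side of ridge)
    jet_width: float = 0.75        # Gaussian half-width (degrees)
    gyre_strength: float = 0.8     # in-trough gyre speed relative to U(z)
    eddy_energy: float = 0.3       # eddy velocity scale relative to U(z)
    eddy_length: float = 3.0       # eddy smoothing scale (grid cells)
    eddy_decorrelation_days: float = 10.0

    @property
    def depth_scale(self) -> float:
        return 1000.0 / math.log(self.u_surface / self.u_1000m)

    def speed_at(self, depth: float) -> float:
        return self.u_surface * math.exp(-depth / self.depth_scale)

    def validate(self) -> None:
        if self.sill_depth >= self.trough_depth:
            raise ValueError("sill must be shallower than the trough")
        for name, gap in self.gaps.items():
            if not (self.lon_min <= gap.lon_min < gap.lon_max <= self.lon_max):
                raise ValueError(f"gap {name} outside the domain")
            if not (
                self.trough_lon[0] - 0.5 <= gap.lon_min
                and gap.lon_max <= self.trough_lon[1] + 0.5
            ):
                raise ValueError(f"gap {name} lies outside the ridge span")
            if gap.depth >= self.trough_depth:
                raise ValueError(f"gap {name} deeper than the trough")


def _grid(config: OceanConfig) -> tuple[np.ndarray, np.ndarray]:
    lon = np.arange(config.lon_min, config.lon_max + config.dlon / 2, config.dlon)
    lat = np.arange(config.lat_min, config.lat_max + config.dlat / 2, config.dlat)
    return lat, lon


def make_bathymetry(config: OceanConfig) -> xr.DataArray:
    """Trough + ridge + gaps + shelf on the configured grid."""
    config.validate()
    lat, lon = _grid(config)
    lon2, lat2 = np.meshgrid(lon, lat)
    depth = np.full(lat2.shape, config.open_ocean_depth)
    in_trough = (
        (lat2 >= config.trough_lat[0]) & (lat2 <= config.trough_lat[1])
        & (lon2 >= config.trough_lon[0]) & (lon2 <= config.trough_lon[1])
    )
    depth[in_trough] = config.trough_depth
    on_ridge = (lat2 >= config.ridge_lat[0]) & (lat2 < config.ridge_lat[1])
    depth[on_ridge] = config.sill_depth
    # the ridge wraps the trough's eastern end so the basin is enclosed
    east_cap = (
        (lon2 > config.trough_lon[1])
        & (lon2 <= config.trough_lon[1] + (config.ridge_lat[1] - config.ridge_lat[0]))
        & (lat2 >= config.ridge_lat[0])
        & (lat2 <= config.trough_lat[1])
    )
    depth[east_cap] = config.sill_depth
    for gap in config.gaps.values():
        in_gap = on_ridge & (lon2 >= gap.lon_min) & (lon2 <= gap.lon_max)
        depth[in_gap] = gap.depth
    # continental shelf/land north of the trough and west of it
    depth[lat2 > config.shelf_lat] = 0.0
    depth[(lon2 < config.trough_lon[0]) & (lat2 >= config.ridge_lat[0])] = 0.0
    return xr.DataArray(
        depth, coords={"lat": lat, "lon": lon}, dims=("lat", "lon"),
        name="bathymetry", attrs={"units": "m", "positive": "down"},
    )


def _velocity_from_streamfunction(
    psi: np.ndarray, lat: np.ndarray, lon: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """u = -dpsi/dy, v = dpsi/dx with central differences (non-divergent)."""
    dy = np.deg2rad(lat[1] - lat[0]) * EARTH_RADIUS_M
    dx = (
        np.deg2rad(lon[1] - lon[0])
        * EARTH_RADIUS_M
        * np.cos(np.deg2rad(lat))[:, None]
    )
    u = -np.gradient(psi, axis=0) / dy
    v = np.gradient(psi, axis=1) / dx
    return u, v


def _base_streamfunction(config: OceanConfig, lat, lon) -> np.ndarray:
    """Unit-amplitude stream function: boundary jet + in-trough gyre.

    Each component is scaled so its own maximum speed (from the same
    discrete gradient used at runtime) is exactly 1 resp.
    ``gyre_strength``; the total is later multiplied by ``U(z)``.
    """
    lon2, lat2 = np.meshgrid(lon, lat)
    dy = np.deg2rad(config.dlat) * EARTH_RADIUS_M
    # eastward jet along jet_lat: psi integrates the Gaussian profile
    from scipy.special import erf

    s = config.jet_width
    psi_jet = (
        -s * math.sqrt(math.pi / 2)
        * erf((lat2 - config.jet_lat) / (s * math.sqrt(2)))
        * np.deg2rad(1.0) * EARTH_RADIUS_M
    )
    u, v = _velocity_from_streamfunction(psi_jet, lat, lon)
    psi_jet /= np.hypot(u, v).max()

    xc = 0.5 * (config.trough_lon[0] + config.trough_lon[1])
    yc = 0.5 * (config.trough_lat[0] + config.trough_lat[1])
    a = 0.35 * (config.trough_lon[1] - config.trough_lon[0])
    b = 0.45 * (config.trough_lat[1] - config.trough_lat[0])
    psi_gyre = np.exp(-(((lon2 - xc) / a) ** 2 + ((lat2 - yc) / b) ** 2))
    u, v = _velocity_from_streamfunction(psi_gyre, lat, lon)
    psi_gyre = psi_gyre / np.hypot(u, v).max() * config.gyre_strength
    return psi_jet + psi_gyre


def _eddy_shape(rng: np.random.Generator, shape, config: OceanConfig,
                lat, lon) -> np.ndarray:
    """Smoothed white noise normalized to unit eddy velocity scale."""
    noise = gaussian_filter(rng.standard_normal(shape), config.eddy_length)
    u, v = _velocity_from_streamfunction(noise, lat, lon)
    rms = np.sqrt(np.mean(u**2 + v**2))
    return noise / max(rms, 1e-30)


def make_synthetic_ocean(
    config: OceanConfig | None = None, rng_seed: int = 0
) -> xr.Dataset:
    """Generate daily velocity fields and bathymetry.

    Returns a Dataset with ``u(time, depth, lat, lon)``,
    ``v(time, depth, lat, lon)`` and ``bathymetry(lat, lon)``.  With
    ``eddy_energy = 0`` the daily fields are identical.
    """
    config = config or OceanConfig()
    bathy = make_bathymetry(config)
    lat, lon = _grid(config)
    times = pd.date_range(config.start_date, periods=config.n_days, freq="D")
    rng = np.random.default_rng(rng_seed)

    n_t, n_z = len(times), len(config.levels)
    u = np.zeros((n_t, n_z, lat.size, lon.size), dtype=np.float32)
    v = np.zeros_like(u)
    psi_base = _base_streamfunction(config, lat, lon)
    rho = math.exp(-1.0 / config.eddy_decorrelation_days)

    for zi, depth in enumerate(config.levels):
        amp = config.speed_at(depth)
        mask = (bathy.values >= max(depth, 1e-9)) & (bathy.values > 0)
        eddy = None
        for ti in range(n_t):
            if config.eddy_energy > 0:
                fresh = _eddy_shape(rng, psi_base.shape, config, lat, lon)
                eddy = (
                    fresh if eddy is None
                    else rho * eddy + math.sqrt(1 - rho**2) * fresh
                )
                psi = amp * (psi_base + config.eddy_energy * eddy)
            else:
                psi = amp * psi_base
            uu, vv = _velocity_from_streamfunction(psi, lat, lon)
            u[ti, zi] = np.where(mask, uu, 0.0)
            v[ti, zi] = np.where(mask, vv, 0.0)
            if config.eddy_energy == 0 and ti == 0:
                u[:, zi] = u[0, zi]
                v[:, zi] = v[0, zi]
                break

    ds = xr.Dataset(
        {
            "u": (("time", "depth", "lat", "lon"), u),
            "v": (("time", "depth", "lat", "lon"), v),
            "bathymetry": bathy,
        },
        coords={
            "time": times,
            "depth": np.asarray(config.levels, dtype=float),
            "lat": lat,
            "lon": lon,
        },
        attrs={"title": "ventseep synthetic trough/boundary-current ocean"},
    )
    ds["u"].attrs["units"] = ds["v"].attrs["units"] = "m s-1"
    return ds


_SEASON_MONTHS = {
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "fall": (9, 10, 11),
    "winter": (12, 1, 2),
}


def seasonal_mean(ds: xr.Dataset, season: str, years: list[int]) -> xr.Dataset:
    """Mean over the season's daily slices across an ensemble of years.

    Winter spans December of year ``y`` together with January-February
    of year ``y + 1`` (the meteorological DJF convention).
    """
    if season not in _SEASON_MONTHS:
        raise ValueError(f"unknown season {season!r}")
    months = _SEASON_MONTHS[season]
    t = pd.DatetimeIndex(ds["time"].values)
    if season == "winter":
        sel = (t.month == 12) & np.isin(t.year, years)
        sel |= np.isin(t.month, (1, 2)) & np.isin(t.year, [y + 1 for y in years])
    else:
        sel = np.isin(t.month, months) & np.isin(t.year, years)
    if not sel.any():
        raise ValueError(f"no {season} days for years {years} in the field")
    return ds[["u", "v"]].isel(time=np.flatnonzero(sel)).mean("time")


def write_field(ds: xr.Dataset, path) -> None:
    """Write as NetCDF3 (classic format, CF-style dims)."""
    enc = {v: {"dtype": "float32"} for v in ("u", "v") if v in ds}
    ds.to_netcdf(path, engine="scipy", encoding=enc)


def read_field(path) -> xr.Dataset:
    return xr.open_dataset(path, engine="scipy").load()
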