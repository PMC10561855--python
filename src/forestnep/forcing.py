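"""Seeded synthetic forcing: weather, radiation, soil and grid fixtures.

The generators stand in for the station-interpolated meteorology, soil
maps and satellite NDVI a regional run would normally ingest. They are
deliberately simple but statistically honest: a sinusoidal annual
temperature cycle with first-order autocorrelated anomalies, a two-state
Markov occurrence chain with exponential wet-day amounts for rain,
sunshine fractions conditioned on wet/dry state, and Angström–Prescott
transmittance turning sunshine hours into noon PAR. Every draw flows
from one per-run seed via seed-sequence spawning, so full-grid fixtures
are bit-reproducible.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .core import ForestType, GridCell, SoilState, WeatherDay, species_defaults
from .growth import build_stand, lai_from_ndvi

__all__ = [
    "ClimateArchetype",
    "ARCHETYPES",
    "archetype_for",
    "day_length",
    "noon_par_from_sunshine",
    "derive_daynight_temps",
    "synth_weather",
    "synth_soil",
    "synth_grid",
    "weather_to_frame",
    "forcing_to_netcdf",
    "forcing_from_netcdf",
]

SOLAR_CONSTANT = 1367.0      # W m^-2
PAR_FRACTION = 0.48
ANGSTROM_A = 0.25
ANGSTROM_B = 0.50


@dataclass(frozen=True)
class ClimateArchetype:
    """Statistical description of one climate regime."""

    name: str
    T_mean_annual: float     # °C
    T_amplitude: float       # °C, half peak-to-trough of the seasonal cycle
    precip_annual: float     # mm a^-1
    wet_day_prob: float      # stationary wet-day fraction
    Rh_mean: float           # fraction
    sunshine_mean: float     # h d^-1
    co2_start: float = 370.0     # ppm
    co2_trend: float = 2.0       # ppm a^-1
    lat: float = 35.0            # representative latitude, degrees

    def __post_init__(self) -> None:
        if self.precip_annual <= 0:
            raise ValueError("annual precipitation must be positive")
        if not (0.0 <= self.wet_day_prob < 1.0):
            raise ValueError("wet-day probability must lie in [0, 1)")


ARCHETYPES: dict[str, ClimateArchetype] = {
    "cold-temperate": ClimateArchetype(
        "cold-temperate", T_mean_annual=-2.0, T_amplitude=20.0,
        precip_annual=500.0, wet_day_prob=0.25, Rh_mean=0.65,
        sunshine_mean=6.5, lat=50.0),
    "warm-temperate": ClimateArchetype(
        "warm-temperate", T_mean_annual=10.0, T_amplitude=14.0,
        precip_annual=700.0, wet_day_prob=0.25, Rh_mean=0.65,
        sunshine_mean=6.5, lat=40.0),
    "subtropical": ClimateArchetype(
        "subtropical", T_mean_annual=17.0, T_amplitude=9.0,
        precip_annual=1400.0, wet_day_prob=0.38, Rh_mean=0.75,
        sunshine_mean=5.0, lat=27.0),
    "tropical": ClimateArchetype(
        "tropical", T_mean_annual=22.0, T_amplitude=5.0,
        precip_annual=1800.0, wet_day_prob=0.45, Rh_mean=0.80,
        sunshine_mean=5.5, lat=21.0),
}

_TYPE_ARCHETYPE = {
    ForestType.ECF: "cold-temperate",
    ForestType.DCF: "cold-temperate",
    ForestType.CBF: "warm-temperate",
    ForestType.DBF: "warm-temperate",
    ForestType.EBF: "subtropical",
    ForestType.EDBF: "subtropical",
    ForestType.SRF: "tropical",
    ForestType.RF: "tropical",
}


def archetype_for(forest_type: ForestType) -> ClimateArchetype:
    """The default climate regime of a forest type."""
    return ARCHETYPES[_TYPE_ARCHETYPE[forest_type]]


# ---------------------------------------------------------------------------
# solar geometry and radiation
# ---------------------------------------------------------------------------

def _declination(doy: int) -> float:
    """Solar declination, radians."""
    return math.radians(23.45) * math.sin(2.0 * math.pi * (284 + doy) / 365.0)


def day_length(lat: float, doy: int) -> float:
    """Astronomical day length in hours (sunrise-to-sunset)."""
    phi = math.radians(lat)
    delta = _declination(doy)
    x = -math.tan(phi) * math.tan(delta)
    if x >= 1.0:
        return 0.0
    if x <= -1.0:
        return 24.0
    return 24.0 / math.pi * math.acos(x)


def noon_par_from_sunshine(
    lat: float, doy: int, D: float,
    a: float = ANGSTROM_A, b: float = ANGSTROM_B,
    par_fraction: float = PAR_FRACTION,
) -> float:
    """Canopy-top noon PAR (W m^-2) from sunshine hours.

    Clear-sky noon irradiance is the top-of-atmosphere value scaled by
    the Angström–Prescott transmittance ``a + b D/D0`` with ``D0`` the
    astronomical day length; fully overcast days (``D = 0``) retain the
    diffuse floor ``a``. ``D`` is clamped to ``D0``.
    """
    phi = math.radians(lat)
    delta = _declination(doy)
    cos_zenith_noon = math.sin(phi) * math.sin(delta) + math.cos(phi) * math.cos(delta)
    if cos_zenith_noon <= 0.0:       # polar night
        return 0.0
    D0 = day_length(lat, doy)
    frac = 0.0 if D0 <= 0 else min(max(D, 0.0), D0) / D0
    eccentricity = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    toa_noon = SOLAR_CONSTANT * eccentricity * cos_zenith_noon
    return par_fraction * (a + b * frac) * toa_noon


def derive_daynight_temps(day: WeatherDay, k_d: float = 0.5) -> WeatherDay:
    """Fill ``T_d`` and ``T_n`` on a weather day (in place; returned).

    ``T_d = T_avg + k_d (T_max - T_avg)`` and ``T_n`` closes the
    energy-consistent split ``D T_d + (24-D) T_n = 24 T_avg``. With no
    night (``D = 24``) the day mean is the daily mean.
    """
    if not (0.0 <= day.D <= 24.0):
        raise ValueError("sunshine hours D must lie in [0, 24]")
    if day.T_min > day.T_max:
        raise ValueError("T_min may not exceed T_max")
    if day.D >= 24.0:
        day.T_d = day.T_avg
        day.T_n = day.T_avg
        return day
    T_d = day.T_avg + k_d * (day.T_max - day.T_avg)
    T_n = (24.0 * day.T_avg - day.D * T_d) / (24.0 - day.D)
    day.T_d = T_d
    day.T_n = T_n
    return day


# ---------------------------------------------------------------------------
# weather generator
# ---------------------------------------------------------------------------

def synth_weather(
    archetype: ClimateArchetype,
    n_years: int,
    seed: int | np.random.SeedSequence,
    start_year: int = 2001,
    ar_rho: float = 0.8,
    ar_sigma: float = 3.0,
) -> list[WeatherDay]:
    """Generate a daily weather series for ``n_years`` calendar years.

    Mean temperature is a sinusoid (peak near late July at northern
    mid-latitudes) plus an AR(1) anomaly with lag-1 correlation
    ``ar_rho`` and marginal standard deviation ``ar_sigma``. Rain
    occurrence follows a two-state Markov chain whose stationary wet
    fraction equals ``wet_day_prob``; amounts are exponential. Sunshine
    and humidity are conditioned on the wet/dry state. Identical seeds
    give bitwise-identical series.
    """
    if n_years < 1:
        raise ValueError("n_years must be at least 1")
    rng = np.random.default_rng(seed)

    dates = pd.date_range(
        _dt.date(start_year, 1, 1), _dt.date(start_year + n_years - 1, 12, 31),
        freq="D",
    )
    n = len(dates)
    doy = dates.dayofyear.to_numpy()
    year_index = dates.year.to_numpy() - start_year

    # seasonal cycle + AR(1) anomaly (marginal sd = ar_sigma)
    seasonal = archetype.T_mean_annual - archetype.T_amplitude * np.cos(
        2.0 * np.pi * (doy - 28) / 365.25
    )
    eps = rng.standard_normal(n)
    anom = np.empty(n)
    anom[0] = ar_sigma * eps[0]
    innov_sd = ar_sigma * math.sqrt(1.0 - ar_rho**2)
    for t in range(1, n):
        anom[t] = ar_rho * anom[t - 1] + innov_sd * eps[t]
    T_avg = seasonal + anom

    # two-state occurrence chain with stationary wet fraction pi
    pi = archetype.wet_day_prob
    if pi <= 0.0:
        wet = np.zeros(n, dtype=bool)
    else:
        p_ww = min(0.95, pi + 0.35 * (1.0 - pi))
        p_wd = pi * (1.0 - p_ww) / (1.0 - pi)
        u = rng.random(n)
        wet = np.empty(n, dtype=bool)
        wet[0] = u[0] < pi
        for t in range(1, n):
            wet[t] = u[t] < (p_ww if wet[t - 1] else p_wd)
    mean_amount = archetype.precip_annual / (365.25 * pi) if pi > 0 else 0.0
    amounts = rng.exponential(mean_amount, size=n) if pi > 0 else np.zeros(n)
    precip = np.where(wet, amounts, 0.0)

    # diurnal range, narrower on wet days
    dr = np.clip(rng.normal(10.0, 2.0, size=n), 2.0, None)
    dr = np.where(wet, 0.6 * dr, dr)
    T_max = T_avg + 0.5 * dr
    T_min = T_avg - 0.5 * dr

    # sunshine fraction of the astronomical day, by wet/dry state
    D0 = np.array([day_length(archetype.lat, int(d)) for d in doy])
    f_clear = min(0.95, archetype.sunshine_mean / 12.0 + 0.25)
    f_dry = np.clip(rng.normal(f_clear, 0.15, size=n), 0.0, 1.0)
    f_wet = np.clip(rng.normal(max(f_clear - 0.45, 0.05), 0.12, size=n), 0.0, 1.0)
    D = D0 * np.where(wet, f_wet, f_dry)

    Rh = np.clip(
        np.where(
            wet,
            rng.normal(archetype.Rh_mean + 0.12, 0.05, size=n),
            rng.normal(archetype.Rh_mean - 0.05, 0.08, size=n),
        ),
        0.05, 1.0,
    )

    C_t = archetype.co2_start + archetype.co2_trend * year_index

    days = []
    for t in range(n):
        d = WeatherDay(
            date=dates[t].date(),
            T_max=float(T_max[t]), T_min=float(T_min[t]), T_avg=float(T_avg[t]),
            precip=float(precip[t]), D=float(D[t]), Rh=float(Rh[t]),
            C_t=float(C_t[t]), C_0=float(archetype.co2_start),
        )
        derive_daynight_temps(d)
        d.PAR_noon = noon_par_from_sunshine(archetype.lat, int(doy[t]), d.D)
        days.append(d)
    return days


# ---------------------------------------------------------------------------
# soil and grid fixtures
# ---------------------------------------------------------------------------

#: Fractional split of total soil carbon across the ten pools at t=0.
_INIT_POOL_FRACTIONS = np.array(
    [0.010, 0.020, 0.010, 0.020, 0.015, 0.040, 0.015, 0.050, 0.520, 0.300]
)

#: Plausible mean total soil carbon (kgC m^-2) per forest type.
_SOIL_C_MEAN = {
    ForestType.ECF: 14.0, ForestType.DCF: 15.0, ForestType.CBF: 13.0,
    ForestType.DBF: 12.0, ForestType.EBF: 11.0, ForestType.EDBF: 11.0,
    ForestType.SRF: 10.0, ForestType.RF: 10.0,
}

#: Lognormal dispersion (sd of log total C) of the soil generator.
SOIL_C_LOG_SD = 0.3


def synth_soil(
    forest_type: ForestType,
    seed: int | np.random.SeedSequence,
) -> SoilState:
    """Draw a plausible initial soil state for a forest type.

    Total carbon is lognormal around a per-type mean with log-sd
    ``SOIL_C_LOG_SD`` and is split across the ten pools by fixed
    fractions dominated by slow and resistant organic matter; water
    starts at field capacity.
    """
    rng = np.random.default_rng(seed)
    mean_c = _SOIL_C_MEAN[forest_type]
    total_c = mean_c * math.exp(rng.normal(0.0, SOIL_C_LOG_SD) - 0.5 * SOIL_C_LOG_SD**2)
    pools = total_c * _INIT_POOL_FRACTIONS
    W_f = float(rng.uniform(8.0, 16.0))
    n_pool = total_c / 14.0          # bulk soil C:N near 14
    return SoilState(
        W_s=W_f, W_f=W_f, T_s=10.0,
        N_s=5.0e-4, N_pool=n_pool, C_u=pools,
    )


def synth_grid(
    n_cells: int,
    type_mix: dict[ForestType, float],
    seed: int | np.random.SeedSequence,
    n_trees: int = 36,
    patch_area: float = 900.0,
    lat0: float = 30.0,
    lon0: float = 110.0,
) -> list[GridCell]:
    """Build ``n_cells`` grid cells with NDVI, stands and soil columns.

    Forest types are allocated in proportion to ``type_mix``; NDVI is
    drawn in the upper (forested) part of each type's scene range and
    inverted to the initial stand LAI; per-cell randomness comes from
    spawned seed-sequence streams so any cell is reproducible
    independently of grid size.
    """
    if not type_mix:
        raise ValueError("type_mix must not be empty")
    fracs = np.array(list(type_mix.values()), dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("type_mix fractions must sum to 1")
    types = list(type_mix.keys())

    # largest-remainder allocation of cells to types
    ideal = fracs * n_cells
    counts = np.floor(ideal).astype(int)
    for i in np.argsort(ideal - counts)[::-1][: n_cells - counts.sum()]:
        counts[i] += 1

    root = (seed if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed))
    streams = root.spawn(n_cells)

    ncol = max(1, int(math.ceil(math.sqrt(n_cells))))
    cells: list[GridCell] = []
    k = 0
    for ftype, count in zip(types, counts):
        params = species_defaults(ftype)
        for _ in range(count):
            ss = streams[k]
            rng = np.random.default_rng(ss)
            lo = params.NDVI_min + 0.6 * (params.NDVI_max - params.NDVI_min)
            ndvi = float(rng.uniform(lo, params.NDVI_max))
            lai = lai_from_ndvi(ndvi, params)
            soil = synth_soil(ftype, ss.spawn(1)[0])
            trees = build_stand(
                params, lai, n_trees=n_trees, patch_area=patch_area,
                rng=np.random.default_rng(ss.spawn(1)[0]),
            )
            cells.append(GridCell(
                id=f"cell{k:04d}",
                lat=lat0 + 0.1 * (k // ncol),
                lon=lon0 + 0.1 * (k % ncol),
                forest_type=ftype,
                coverage=float(rng.uniform(0.3, 0.9)),
                trees=trees,
                soil=soil,
                patch_area=patch_area,
                ndvi=ndvi,
            ))
            k += 1
    return cells


# ---------------------------------------------------------------------------
# forcing I/O
# ---------------------------------------------------------------------------

_FRAME_COLUMNS = [
    "cell_id", "date", "T_max", "T_min", "T_avg", "precip", "D", "Rh",
    "T_d", "T_n", "PAR_noon", "C_t", "C_0",
]


def weather_to_frame(weather: dict[str, list[WeatherDay]]) -> pd.DataFrame:
    """Tidy forcing table: one row per cell-day.

    Columns carry units in the docstring of :func:`forcing_to_netcdf`;
    temperatures °C, precip mm·d^-1, D h, Rh fraction, PAR W·m^-2,
    CO2 ppm.
    """
    rows = []
    for cell_id, days in weather.items():
        for d in days:
            rows.append((cell_id, d.date, d.T_max, d.T_min, d.T_avg, d.precip,
                         d.D, d.Rh, d.T_d, d.T_n, d.PAR_noon, d.C_t, d.C_0))
    return pd.DataFrame(rows, columns=_FRAME_COLUMNS)


_VAR_UNITS = {
    "T_max": "degC", "T_min": "degC", "T_avg": "degC",
    "precip": "mm d-1", "D": "h", "Rh": "1",
    "T_d": "degC", "T_n": "degC", "PAR_noon": "W m-2",
    "C_t": "ppm", "C_0": "ppm",
}


def forcing_to_netcdf(
    frame: pd.DataFrame, cells: list[GridCell], path: str
) -> None:
    """Write tidy forcing to a CF-style NetCDF file (time/lat/lon dims)."""
    coord = {c.id: (c.lat, c.lon) for c in cells}
    df = frame.copy()
    df["lat"] = df["cell_id"].map(lambda i: coord[i][0])
    df["lon"] = df["cell_id"].map(lambda i: coord[i][1])
    df["time"] = pd.to_datetime(df["date"])
    ds = df.set_index(["time", "lat", "lon"])[list(_VAR_UNITS)].to_xarray()
    for name, units in _VAR_UNITS.items():
        ds[name].attrs["units"] = units
    ds.attrs["conventions"] = "CF-1.8-style dimensions (time, lat, lon)"
    ds.to_netcdf(path)


def forcing_from_netcdf(path: str) -> pd.DataFrame:
    """Read a forcing NetCDF back into the tidy one-row-per-cell-day frame."""
    with xr.open_dataset(path) as ds:
        df = ds.to_dataframe().dropna(how="all").reset_index()
    df["date"] = df["time"].dt.date
    return df
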