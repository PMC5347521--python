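"""Seeded synthetic geospatial data: grids, climatologies, driver stacks,
a known generative crop-cover function, and future-climate scenarios.

Every generator is a pure function of its inputs and a seed, so each
downstream stage (zonation, forest training, projection, change mapping)
is exercisable on a desk-scale synthetic globe with no downloads.  The
generators mimic the *statistical structure* of the real global drivers —
latitudinal climate gradients with a poleward-growing seasonal cycle,
blockwise-constant regional GDP, spatially autocorrelated categorical
soils, fertiliser correlated with GDP — not their values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np
from scipy import ndimage

__all__ = [
    "RasterGrid",
    "MonthlyClimate",
    "DriverStack",
    "CoverField",
    "ScenarioSpec",
    "ClimateParams",
    "CoverCoeffs",
    "DAYS_PER_MONTH",
    "SOIL_ALPHABET_SIZE",
    "make_grid",
    "generate_climate",
    "generate_drivers",
    "true_cover_function",
    "apply_scenario",
    "default_scenarios",
]

#: Days per calendar month (non-leap year), used for degree-day weighting.
DAYS_PER_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

#: Size of the fixed soil-class alphabet (dominant-soil groups).
SOIL_ALPHABET_SIZE = 12


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RasterGrid:
    """Regular lat-lon grid, cell-centre registered, latitude descending.

    ``origin`` is the (lat, lon) of the north-west cell centre.  ``land_mask``
    flags the cells that carry data; off-mask cells hold ``nodata_value``
    (NaN internally).
    """

    n_lat: int
    n_lon: int
    cell_size_deg: float
    origin: tuple[float, float]
    land_mask: np.ndarray
    nodata_value: float = np.nan

    def __post_init__(self) -> None:
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError(
                f"grid dimensions must be >= 1, got {self.n_lat} x {self.n_lon}"
            )
        if self.cell_size_deg <= 0:
            raise ValueError("cell_size_deg must be positive")
        mask = np.asarray(self.land_mask, dtype=bool)
        if mask.shape != (self.n_lat, self.n_lon):
            raise ValueError(
                f"land_mask shape {mask.shape} != ({self.n_lat}, {self.n_lon})"
            )
        object.__setattr__(self, "land_mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    @property
    def lats(self) -> np.ndarray:
        """Cell-centre latitudes, descending from north."""
        return self.origin[0] - np.arange(self.n_lat) * self.cell_size_deg

    @property
    def lons(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.n_lon) * self.cell_size_deg

    @property
    def n_land(self) -> int:
        return int(self.land_mask.sum())

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.n_lat == other.n_lat
            and self.n_lon == other.n_lon
            and np.isclose(self.cell_size_deg, other.cell_size_deg)
            and np.allclose(self.origin, other.origin)
        )

    def mask_field(self, values: np.ndarray) -> np.ndarray:
        """Return a copy with NoData (NaN) off the land mask."""
        out = np.array(values, dtype=float)
        out[~self.land_mask] = np.nan
        return out


@dataclass(frozen=True)
class MonthlyClimate:
    """Monthly climatology on a grid: (12, n_lat, n_lon) temperature (°C)
    and precipitation (mm/month) fields."""

    grid: RasterGrid
    temp_monthly: np.ndarray
    precip_monthly: np.ndarray

    def __post_init__(self) -> None:
        expect = (12, self.grid.n_lat, self.grid.n_lon)
        for name in ("temp_monthly", "precip_monthly"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != expect:
                raise ValueError(f"{name} shape {arr.shape} != {expect}")
            object.__setattr__(self, name, arr)
        land = self.grid.land_mask
        if np.nanmin(np.where(land, self.precip_monthly, 0.0)) < 0:
            raise ValueError("precip_monthly must be non-negative")

    @property
    def mean_annual_temp(self) -> np.ndarray:
        """Mean of the 12 monthly means, °C."""
        return self.grid.mask_field(self.temp_monthly.mean(axis=0))

    @property
    def annual_precip(self) -> np.ndarray:
        """Sum of the 12 monthly totals, mm/yr."""
        return self.grid.mask_field(self.precip_monthly.sum(axis=0))


@dataclass(frozen=True)
class DriverStack:
    """The explanatory layers, all aligned on one grid.

    ``aez`` is attached after zonation (the zone layer is computed from the
    climatology by the aez module, not generated directly).
    """

    grid: RasterGrid
    mean_annual_temp: np.ndarray
    mean_annual_precip: np.ndarray
    gdp_regional: np.ndarray
    n_fert: np.ndarray
    p_fert: np.ndarray
    soil_class: np.ndarray
    elevation: np.ndarray
    aez: np.ndarray | None = None
    n_soils: int = SOIL_ALPHABET_SIZE

    def with_aez(self, aez: np.ndarray) -> "DriverStack":
        return replace(self, aez=np.asarray(aez, dtype=float))

    def with_climate(self, climate: MonthlyClimate) -> "DriverStack":
        """Swap in annual means derived from another climatology
        (static socio-economic and biophysical layers are kept)."""
        if not self.grid.same_geometry(climate.grid):
            raise ValueError("climate grid does not match driver grid")
        return replace(
            self,
            mean_annual_temp=climate.mean_annual_temp,
            mean_annual_precip=climate.annual_precip,
        )


@dataclass(frozen=True)
class CoverField:
    """Crop-cover fraction per cell in [0, 1] on land; NoData elsewhere."""

    grid: RasterGrid
    cover: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.cover, dtype=float)
        if arr.shape != self.grid.shape:
            raise ValueError(f"cover shape {arr.shape} != {self.grid.shape}")
        on_land = arr[self.grid.land_mask]
        finite = on_land[np.isfinite(on_land)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("cover must lie in [0, 1] on land")
        object.__setattr__(self, "cover", arr)


@dataclass(frozen=True)
class ScenarioSpec:
    """A pseudo-GCM x pseudo-RCP climate perturbation: additive warming and
    multiplicative precipitation scaling (scalars or per-cell fields)."""

    name: str
    delta_temp: Union[float, np.ndarray] = 0.0
    precip_factor: Union[float, np.ndarray] = 1.0
    horizon: str = "2080"
    rcp: str = "4.5"

    def __post_init__(self) -> None:
        pf = np.asarray(self.precip_factor, dtype=float)
        if np.any(pf <= 0):
            raise ValueError("precip_factor must be > 0")


# ---------------------------------------------------------------------------
# Generator parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClimateParams:
    """Shape of the synthetic climatology.

    Temperature falls from ``equator_temp`` to ``pole_temp`` with latitude;
    the seasonal cycle's amplitude grows poleward from ``amp_equator`` to
    ``amp_pole`` and is scaled globally by ``seasonality`` (0 = no seasons).
    Precipitation has a wet equatorial band, dry subtropics and wetter
    mid-latitudes, modulated by smooth seeded noise.
    """

    equator_temp: float = 26.0
    pole_temp: float = -22.0
    lat_exponent: float = 1.7
    amp_equator: float = 1.5
    amp_pole: float = 18.0
    seasonality: float = 1.0
    temp_noise_sd: float = 2.0
    precip_equator: float = 170.0   # mm/month at the equatorial peak
    precip_midlat: float = 70.0     # mm/month mid-latitude storm-track peak
    precip_base: float = 12.0       # mm/month floor before noise
    precip_noise: float = 0.5       # log-scale smooth noise amplitude
    smooth_sigma: float = 3.0       # cells, for the seeded noise fields


@dataclass(frozen=True)
class CoverCoeffs:
    """Coefficients of the known generative cover function.

    The latent suitability is

        z = intercept
            + b_temp * exp(-((T - temp_opt)/temp_width)^2)
            + b_precip * min(P, precip_scale)/precip_scale
            + b_gdp * (GDP - 0.5)
            + soil_amp * sin(1 + soil_class)
            + aez_amp * cos(zone_id)

    and cover = clip((logistic(z) - floor)/(1 - floor), 0, 1) plus truncated
    Gaussian noise.  The floor sends marginal (cold/arid) cells to exactly
    zero cover so that novel-area transitions exist; with all coefficients
    zero (including floor) the latent is 0 and cover sits at the logistic
    midpoint 0.5.  The form is recorded here so recovery tests have a known
    target.
    """

    intercept: float = -2.8
    b_temp: float = 2.0
    temp_opt: float = 16.0
    temp_width: float = 14.0
    b_precip: float = 2.8
    precip_scale: float = 1500.0
    b_gdp: float = 1.2
    soil_amp: float = 0.9
    aez_amp: float = 0.5
    floor: float = 0.08

    def __post_init__(self) -> None:
        if not 0 <= self.floor < 1:
            raise ValueError("floor must be in [0, 1)")

    @classmethod
    def zero(cls) -> "CoverCoeffs":
        return cls(0.0, 0.0, 16.0, 14.0, 0.0, 1500.0, 0.0, 0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _smooth_field(shape: tuple[int, int], sigma: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Standardised smooth Gaussian random field (zero mean, unit sd)."""
    white = rng.standard_normal(shape)
    if sigma > 0:
        f = ndimage.gaussian_filter(white, sigma=sigma, mode="wrap")
    else:
        f = white
    sd = f.std()
    return f / sd if sd > 0 else f


def make_grid(n_lat: int, n_lon: int, land_fraction: float,
              seed: int) -> RasterGrid:
    """Build a grid whose land mask is a set of contiguous blobs covering
    approximately ``land_fraction`` of the cells.

    The mask is the upper ``land_fraction`` quantile of a smoothed seeded
    noise field, which yields continents rather than i.i.d. speckle.
    """
    if n_lat < 1 or n_lon < 1:
        raise ValueError(f"grid dimensions must be >= 1, got {n_lat} x {n_lon}")
    if not 0 < land_fraction <= 1:
        raise ValueError("land_fraction must be in (0, 1]")
    cell = 180.0 / n_lat
    origin = (90.0 - cell / 2.0, -180.0 + cell / 2.0)
    if land_fraction >= 1.0:
        mask = np.ones((n_lat, n_lon), dtype=bool)
    else:
        rng = np.random.default_rng(seed)
        blob = _smooth_field((n_lat, n_lon), sigma=max(2.0, n_lat / 15.0), rng=rng)
        thr = np.quantile(blob, 1.0 - land_fraction)
        mask = blob >= thr
    return RasterGrid(n_lat, n_lon, cell, origin, mask)


def generate_climate(grid: RasterGrid, params: ClimateParams | None = None,
                     seed: int = 0) -> MonthlyClimate:
    """Seeded monthly climatology with latitudinal structure.

    Temperature decreases poleward and carries a seasonal cycle peaking in
    July (January) in the northern (southern) hemisphere.  Precipitation is
    non-negative with wet/dry latitude bands.  Deterministic per seed.
    """
    p = params or ClimateParams()
    rng = np.random.default_rng(seed)
    lat = grid.lats[:, None] * np.ones((1, grid.n_lon))
    absl = np.abs(lat) / 90.0

    t_mean = p.equator_temp - (p.equator_temp - p.pole_temp) * absl ** p.lat_exponent
    t_mean = t_mean + p.temp_noise_sd * _smooth_field(grid.shape, p.smooth_sigma, rng)

    amp = p.seasonality * (p.amp_equator + (p.amp_pole - p.amp_equator) * absl)
    hemi = np.where(lat >= 0, 1.0, -1.0)
    months = np.arange(12)
    # cos term peaks at m=6 (July) in the north, m=0 (January) in the south
    season = np.cos(2 * np.pi * (months[:, None, None] - 6) / 12.0)
    temp_monthly = t_mean[None] + (amp * hemi)[None] * season

    p_profile = (
        p.precip_equator * np.exp(-((lat / 15.0) ** 2))
        + p.precip_midlat * np.exp(-(((np.abs(lat) - 50.0) / 15.0) ** 2))
        + p.precip_base
    )
    p_noise = np.exp(p.precip_noise * _smooth_field(grid.shape, p.smooth_sigma, rng))
    p_season = 1.0 + 0.3 * p.seasonality * hemi[None] * season
    precip_monthly = np.clip(p_profile[None] * p_noise[None] * p_season, 0.0, None)

    return MonthlyClimate(grid, temp_monthly, precip_monthly)


def _contiguous_regions(grid: RasterGrid, n_regions: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Partition the grid into n_regions contiguous patches by nearest seed
    cell (Voronoi in index space)."""
    ii, jj = np.mgrid[0:grid.n_lat, 0:grid.n_lon]
    seeds_i = rng.integers(0, grid.n_lat, n_regions)
    seeds_j = rng.integers(0, grid.n_lon, n_regions)
    d2 = (ii[None] - seeds_i[:, None, None]) ** 2 + (jj[None] - seeds_j[:, None, None]) ** 2
    return np.argmin(d2, axis=0)


def generate_drivers(grid: RasterGrid, climate: MonthlyClimate,
                     n_regions: int = 18, n_soils: int = 8,
                     seed: int = 0) -> DriverStack:
    """Seeded socio-economic and biophysical layers over one grid.

    GDP is normalised to [0, 1] and blockwise-constant over contiguous
    regions (the real study aggregated GDP over 18 world regions); soils are
    spatially autocorrelated categories; fertiliser tracks GDP plus noise;
    elevation is a smooth non-negative surface.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if not 2 <= n_soils <= SOIL_ALPHABET_SIZE:
        raise ValueError(
            f"n_soils must be in [2, {SOIL_ALPHABET_SIZE}], got {n_soils}"
        )
    if not grid.same_geometry(climate.grid):
        raise ValueError("climate grid does not match target grid")
    rng = np.random.default_rng(seed)

    region_id = _contiguous_regions(grid, n_regions, rng)
    gdp_values = rng.random(n_regions)  # normalised GDP in [0, 1] by construction
    gdp = gdp_values[region_id]

    soil_field = _smooth_field(grid.shape, sigma=2.0, rng=rng)
    edges = np.quantile(soil_field, np.linspace(0, 1, n_soils + 1)[1:-1])
    soil = np.digitize(soil_field, edges).astype(float)

    n_fert = np.clip(80.0 * gdp + 10.0 * _smooth_field(grid.shape, 2.0, rng) + 20.0, 0, None)
    p_fert = np.clip(30.0 * gdp + 5.0 * _smooth_field(grid.shape, 2.0, rng) + 8.0, 0, None)

    elevation = np.clip(
        900.0 * np.abs(_smooth_field(grid.shape, 4.0, rng))
        + 300.0 * np.abs(_smooth_field(grid.shape, 1.5, rng)),
        0, None,
    )

    m = grid.mask_field
    return DriverStack(
        grid=grid,
        mean_annual_temp=climate.mean_annual_temp,
        mean_annual_precip=climate.annual_precip,
        gdp_regional=m(gdp),
        n_fert=m(n_fert),
        p_fert=m(p_fert),
        soil_class=m(soil),
        elevation=m(elevation),
        n_soils=n_soils,
    )


def true_cover_function(drivers: DriverStack, aez: np.ndarray,
                        coeffs: CoverCoeffs | None = None,
                        noise_sd: float = 0.02, seed: int = 0) -> CoverField:
    """Known generative crop-cover fraction: logistic squashing of a smooth
    nonlinear suitability in temperature, precipitation, soil, GDP and zone,
    plus seeded Gaussian noise truncated to [0, 1].

    Cover rises with precipitation (log-saturating), peaks at a temperate
    optimum in temperature, and carries categorical soil/zone offsets — the
    documented target that recovery tests measure the emulator against.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    c = coeffs or CoverCoeffs()
    grid = drivers.grid
    T = drivers.mean_annual_temp
    P = np.clip(drivers.mean_annual_precip, 0, None)
    latent = (
        c.intercept
        + c.b_temp * np.exp(-(((T - c.temp_opt) / c.temp_width) ** 2))
        + c.b_precip * np.minimum(P, c.precip_scale) / c.precip_scale
        + c.b_gdp * (drivers.gdp_regional - 0.5)
        + c.soil_amp * np.sin(1.0 + drivers.soil_class)
        + c.aez_amp * np.cos(np.asarray(aez, dtype=float))
    )
    cover = 1.0 / (1.0 + np.exp(-latent))
    cover = np.clip((cover - c.floor) / (1.0 - c.floor), 0.0, 1.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        cover = cover + noise_sd * rng.standard_normal(grid.shape)
    cover = np.clip(cover, 0.0, 1.0)
    return CoverField(grid, grid.mask_field(cover))


def apply_scenario(climate: MonthlyClimate, spec: ScenarioSpec) -> MonthlyClimate:
    """Perturb a climatology: temp' = temp + ΔT, precip' = precip x factor,
    per month per cell.  The grid is unchanged; field-valued deltas must
    match the climate grid."""
    dt = np.asarray(spec.delta_temp, dtype=float)
    pf = np.asarray(spec.precip_factor, dtype=float)
    for name, arr in (("delta_temp", dt), ("precip_factor", pf)):
        if arr.ndim not in (0, 2):
            raise ValueError(f"{name} must be a scalar or a 2-D field")
        if arr.ndim == 2 and arr.shape != climate.grid.shape:
            raise ValueError(
                f"{name} field shape {arr.shape} != grid {climate.grid.shape}"
            )
    return MonthlyClimate(
        climate.grid,
        climate.temp_monthly + dt[None] if dt.ndim == 2 else climate.temp_monthly + dt,
        climate.precip_monthly * (pf[None] if pf.ndim == 2 else pf),
    )


#: Default pseudo-GCM warming offsets for the RCP 4.5 analogue; the 8.5
#: analogue doubles them.  Precip factors are modest and model-specific so
#: the four members disagree in sign in some regions, like a real ensemble.
_DELTA_T_45 = (1.8, 2.2, 2.6, 1.5)
_PRECIP_FACTOR_45 = (1.05, 0.98, 1.03, 1.07)
_PRECIP_FACTOR_85 = (1.10, 0.96, 1.06, 1.14)
_GCM_NAMES = ("GCM-A", "GCM-B", "GCM-C", "GCM-D")


def default_scenarios(horizon: str = "2080") -> list[ScenarioSpec]:
    """The default 4 pseudo-GCM x 2 pseudo-RCP scenario table."""
    out = []
    for rcp, dts, pfs in (
        ("4.5", _DELTA_T_45, _PRECIP_FACTOR_45),
        ("8.5", tuple(2 * d for d in _DELTA_T_45), _PRECIP_FACTOR_85),
    ):
        for name, dt, pf in zip(_GCM_NAMES, dts, pfs):
            out.append(ScenarioSpec(
                name=f"{name}_rcp{rcp}", delta_temp=dt, precip_factor=pf,
                horizon=horizon, rcp=rcp,
            ))
    return out
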