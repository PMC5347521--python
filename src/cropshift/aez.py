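"""Agro-ecological zonation from a monthly climatology.

A zone is the product of a thermal regime — classified from growing degree
days (GDD) and the coldest-month mean temperature — and a moisture regime —
the number of growing months under a Thornthwaite-style monthly water
balance, binned into ordinal classes.  Applying the identical code path to a
perturbed climatology yields the projected zones (PAEZ); the only difference
between baseline and projected zonation is the input climate.

The thresholds here are documented, configurable substitutes in the spirit
of classic global zonation schemes; they are not claimed to match any
particular published parameterisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_data import DAYS_PER_MONTH, MonthlyClimate, RasterGrid

__all__ = [
    "AEZThresholds",
    "AEZMap",
    "THERMAL_LABELS",
    "growing_degree_days",
    "classify_thermal_zone",
    "moisture_class",
    "thornthwaite_pet",
    "compute_aez",
    "zone_legend",
]

#: Thermal-zone integer codes used throughout. 0 is the polar/none class
#: (too little accumulated warmth for any agriculture).
THERMAL_LABELS = {0: "polar/none", 1: "tropical", 2: "temperate", 3: "boreal"}


@dataclass(frozen=True)
class AEZThresholds:
    """Zonation thresholds (all configurable; defaults are substitutes).

    base_temp       °C; GDD base and the floor a growing month must exceed.
    tmin_tropical   °C; coldest-month mean at/above which a cell is tropical.
    gdd_boreal_max  °C·day; below this (and not tropical) a cell is boreal.
    gdd_none_max    °C·day; below this a cell is polar/none (checked first).
    pet_fraction    a growing month needs precip >= pet_fraction x PET.
    n_moisture      number of ordinal moisture classes.
    """

    base_temp: float = 5.0
    tmin_tropical: float = 18.0
    gdd_boreal_max: float = 1200.0
    gdd_none_max: float = 150.0
    pet_fraction: float = 0.5
    n_moisture: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.gdd_none_max < self.gdd_boreal_max:
            raise ValueError(
                "thresholds must satisfy 0 <= gdd_none_max < gdd_boreal_max "
                f"(got {self.gdd_none_max}, {self.gdd_boreal_max})"
            )
        if self.n_moisture < 1:
            raise ValueError("n_moisture must be >= 1")
        if self.pet_fraction < 0:
            raise ValueError("pet_fraction must be >= 0")


@dataclass(frozen=True)
class AEZMap:
    """Per-cell zone ids plus the intermediate agronomic-climatic fields."""

    grid: RasterGrid
    zone_id: np.ndarray        # float with NaN off-mask; integer-valued on land
    gdd: np.ndarray            # °C·day
    tmin: np.ndarray           # coldest-month mean, °C
    moisture_class: np.ndarray # ordinal, 0 = driest
    thresholds: AEZThresholds


def growing_degree_days(temp_monthly: np.ndarray, base_temp: float = 5.0,
                        days_per_month: np.ndarray = DAYS_PER_MONTH) -> np.ndarray:
    """Annual growing degree days from monthly mean temperatures.

    Each monthly mean stands in for its days:
    GDD = sum_m max(0, T_m - base) * days_m.  NaN months propagate NoData.
    """
    t = np.asarray(temp_monthly, dtype=float)
    if t.shape[0] != 12:
        raise ValueError("temp_monthly must have 12 months on axis 0")
    days = np.asarray(days_per_month, dtype=float).reshape(
        (12,) + (1,) * (t.ndim - 1)
    )
    return np.sum(np.maximum(0.0, t - base_temp) * days, axis=0)


def classify_thermal_zone(gdd: np.ndarray, tmin: np.ndarray,
                          thresholds: AEZThresholds) -> np.ndarray:
    """Thermal regime from heat accumulation and winter severity.

    Rules, in order: polar/none where GDD < gdd_none_max; tropical where the
    coldest-month mean >= tmin_tropical; boreal where GDD < gdd_boreal_max;
    temperate otherwise.  Total over all finite inputs; NaN propagates.
    """
    gdd = np.asarray(gdd, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    zone = np.where(
        gdd < thresholds.gdd_none_max, 0.0,
        np.where(
            tmin >= thresholds.tmin_tropical, 1.0,
            np.where(gdd < thresholds.gdd_boreal_max, 3.0, 2.0),
        ),
    )
    return np.where(np.isfinite(gdd) & np.isfinite(tmin), zone, np.nan)


def thornthwaite_pet(temp_monthly: np.ndarray,
                     days_per_month: np.ndarray = DAYS_PER_MONTH) -> np.ndarray:
    """Monthly potential evapotranspiration (mm) by the Thornthwaite formula.

    PET_m = 16 * (10 T_m / I)^a * days_m / 30 for T_m > 0, else 0, with heat
    index I = sum_m (max(0, T_m)/5)^1.514 and the standard cubic exponent
    a(I).  The day-length correction is omitted (documented simplification:
    monthly inputs here carry the latitudinal cycle already).
    """
    t = np.asarray(temp_monthly, dtype=float)
    if t.shape[0] != 12:
        raise ValueError("temp_monthly must have 12 months on axis 0")
    tp = np.maximum(0.0, t)
    heat = np.sum((tp / 5.0) ** 1.514, axis=0)
    a = 6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239
    days = np.asarray(days_per_month, dtype=float).reshape(
        (12,) + (1,) * (t.ndim - 1)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        pet = 16.0 * (10.0 * tp / heat) ** a * days / 30.0
    pet = np.where((tp > 0) & (heat > 0), pet, 0.0)
    return np.where(np.isfinite(t), pet, np.nan)


def moisture_class(temp_monthly: np.ndarray, precip_monthly: np.ndarray,
                   thresholds: AEZThresholds) -> np.ndarray:
    """Ordinal moisture regime from the growing-period length.

    A month counts toward the growing period when its mean temperature
    exceeds base_temp and its precipitation meets pet_fraction x PET
    (Thornthwaite).  The 0..12 month count is binned evenly into
    n_moisture ordinal classes (0 = driest).
    """
    t = np.asarray(temp_monthly, dtype=float)
    p = np.asarray(precip_monthly, dtype=float)
    pet = thornthwaite_pet(t)
    growing = (t > thresholds.base_temp) & (p >= thresholds.pet_fraction * pet)
    g = growing.sum(axis=0).astype(float)
    cls = np.floor(g * thresholds.n_moisture / 13.0)
    valid = np.all(np.isfinite(t) & np.isfinite(p), axis=0)
    return np.where(valid, cls, np.nan)


def encode_zone(thermal: np.ndarray, moisture: np.ndarray,
                n_moisture: int) -> np.ndarray:
    """zone_id = 0 for polar/none, else 1 + (thermal-1)*n_moisture + moisture."""
    zone = np.where(thermal == 0, 0.0,
                    1.0 + (thermal - 1.0) * n_moisture + moisture)
    return np.where(np.isfinite(thermal) & np.isfinite(moisture), zone, np.nan)


def zone_legend(thresholds: AEZThresholds) -> dict[int, str]:
    """Map each zone id to its (thermal, moisture) label."""
    legend = {0: "polar/none"}
    for t_code, t_label in ((1, "tropical"), (2, "temperate"), (3, "boreal")):
        for m in range(thresholds.n_moisture):
            zid = 1 + (t_code - 1) * thresholds.n_moisture + m
            legend[zid] = f"{t_label}/moisture-{m}"
    return legend


def compute_aez(climate: MonthlyClimate,
                thresholds: AEZThresholds | None = None) -> AEZMap:
    """Zonation of a climatology; the same call on a perturbed climatology
    yields the projected zones (PAEZ)."""
    th = thresholds or AEZThresholds()
    grid = climate.grid
    gdd = growing_degree_days(climate.temp_monthly, th.base_temp)
    tmin = climate.temp_monthly.min(axis=0)
    thermal = classify_thermal_zone(gdd, tmin, th)
    moist = moisture_class(climate.temp_monthly, climate.precip_monthly, th)
    zone = encode_zone(thermal, moist, th.n_moisture)
    m = grid.mask_field
    return AEZMap(grid, m(zone), m(gdd), m(tmin), m(moist), th)
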