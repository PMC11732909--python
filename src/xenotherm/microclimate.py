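"""Monthly macroclimate → hourly environments → daily energy budgets.

One representative day (the 15th of each month) stands for the whole
month.  Air temperature follows a piecewise sinusoid anchored with its
minimum at sunrise and its maximum at 14:00 local solar time; solar flux
comes from a clear-sky zenith/airmass model attenuated by cloud; the
effective sky radiant temperature follows the Idso–Jackson clear-sky
emissivity regression with a linear cloud correction.  Each hour the
animal picks whichever of the two microhabitat extremes (minimum or
maximum shade) brings its required heat production closest to basal rate,
emulating behavioural shade-seeking.  Hours whose best option still
demands suppression below zero production integrate as zero and are
flagged as heat load.  The 24-h metabolic trace integrates trapezoidally
(with periodic closure) to kJ day⁻¹ and is classified against the
BMR/FMR-based daily comfort bounds: above the upper bound the animal is
fighting the cold ("cold stress"), below the lower bound it must suppress
metabolism to avoid overheating ("heat stress").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .heatbalance import (
    AnimalGeometry,
    Environment,
    FurLayer,
    geometry_from_mass,
    solve_required_metabolism,
)
from .metabolism import TaxonSpec, daily_bounds, xenarthran_bmr

__all__ = [
    "MonthClimate",
    "Locality",
    "DailyBudget",
    "SOLAR_CONSTANT",
    "solar_declination",
    "sunrise_hour",
    "hourly_temperatures",
    "solar_flux",
    "sky_temperature",
    "build_environment",
    "simulate_day",
    "active_hours",
    "annual_summary",
    "select_best_fur",
]

SOLAR_CONSTANT = 1361.0  # W m-2
KELVIN = 273.15

#: mid-month day-of-year used as the representative day for each month
MID_MONTH_DOY = (15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349)


@dataclass(frozen=True)
class MonthClimate:
    month: int  # 1..12
    t_max: float  # °C
    t_min: float  # °C
    rh: float = 70.0  # %
    cloud: float = 0.3  # [0, 1]
    wind: float = 1.0  # m s-1
    paleo_offset: float = 0.0  # °C, additive paleoclimate delta

    def __post_init__(self) -> None:
        if self.t_max < self.t_min:
            raise ValueError(f"month {self.month}: t_max < t_min")
        if not 0.0 <= self.cloud <= 1.0:
            raise ValueError("cloud fraction must be in [0, 1]")


@dataclass(frozen=True)
class Locality:
    name: str
    latitude: float  # degrees, +N
    months: tuple[MonthClimate, ...]
    min_shade: float = 0.0
    max_shade: float = 0.9

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError("latitude outside [-90, 90]")
        if len(self.months) != 12:
            raise ValueError("need 12 monthly climate entries")


@dataclass
class DailyBudget:
    hourly_M: np.ndarray  # 24 values, W (negative clamped to 0)
    daily_kJ: float
    stress: str  # comfort | cold_stress | heat_stress
    active_hours: float
    heat_flagged_hours: int = 0


def solar_declination(day_of_year: float) -> float:
    """Solar declination (degrees) by the standard cosine approximation."""
    return -23.44 * math.cos(2.0 * math.pi * (day_of_year + 10.0) / 365.0)


def sunrise_hour(latitude: float, day_of_year: float) -> float:
    """Local solar time of sunrise; polar day/night clamp to 0/12 h."""
    decl = math.radians(solar_declination(day_of_year))
    lat = math.radians(latitude)
    x = -math.tan(lat) * math.tan(decl)
    x = min(1.0, max(-1.0, x))
    omega0 = math.degrees(math.acos(x))  # half day-length in degrees
    return 12.0 - omega0 / 15.0


def hourly_temperatures(
    month: MonthClimate, latitude: float, day_of_year: float | None = None
) -> np.ndarray:
    """24 hourly air temperatures (°C), minimum at sunrise, maximum at 14:00.

    Two half-cosine segments join the anchors so both extremes are attained
    exactly on the hourly grid; the paleoclimate offset shifts every hour
    uniformly.
    """
    if day_of_year is None:
        day_of_year = MID_MONTH_DOY[month.month - 1]
    t_max = month.t_max + month.paleo_offset
    t_min = month.t_min + month.paleo_offset
    if t_max == t_min:
        return np.full(24, t_max)
    # anchor the minimum on the hourly grid nearest sunrise, before the peak
    h_min = int(round(sunrise_hour(latitude, day_of_year)))
    h_min = max(0, min(13, h_min))
    h_max = 14
    amp = t_max - t_min
    out = np.empty(24)
    night_len = (h_min + 24) - h_max
    for h in range(24):
        if h_min <= h <= h_max:
            frac = (h - h_min) / (h_max - h_min)
            out[h] = t_min + amp * 0.5 * (1.0 - math.cos(math.pi * frac))
        else:
            since_max = (h - h_max) % 24
            out[h] = t_max - amp * 0.5 * (1.0 - math.cos(math.pi * since_max / night_len))
    return out


def solar_flux(
    latitude: float, day_of_year: float, hour: float, cloud: float
) -> float:
    """Horizontal solar flux (W m⁻²): clear-sky beam × cloud attenuation.

    Flux = S0 · 0.7^airmass · cos(zenith) · (1 − 0.75·cloud), zero below
    the horizon; airmass = sec(zenith) capped at 38 near the horizon.
    """
    if not 0.0 <= cloud <= 1.0:
        raise ValueError("cloud fraction must be in [0, 1]")
    decl = math.radians(solar_declination(day_of_year))
    lat = math.radians(latitude)
    hour_angle = math.radians(15.0 * (hour - 12.0))
    cos_z = (math.sin(lat) * math.sin(decl)
             + math.cos(lat) * math.cos(decl) * math.cos(hour_angle))
    if cos_z <= 0.0:
        return 0.0
    airmass = min(1.0 / cos_z, 38.0)
    return SOLAR_CONSTANT * 0.7**airmass * cos_z * (1.0 - 0.75 * cloud)


def sky_temperature(T_air: float, cloud: float) -> float:
    """Effective radiant sky temperature (°C), Idso–Jackson emissivity.

    Clear-sky emissivity ε = 1 − 0.261·exp(−7.77×10⁻⁴·(273 − T_K)²); cloud
    fills the emissivity gap linearly so an overcast sky radiates at air
    temperature.
    """
    if not -80.0 < T_air < 60.0:
        raise ValueError(f"T_air {T_air} °C outside (-80, 60)")
    t_k = T_air + KELVIN
    eps = 1.0 - 0.261 * math.exp(-7.77e-4 * (273.0 - t_k) ** 2)
    eps_eff = eps + (1.0 - eps) * cloud
    return eps_eff**0.25 * t_k - KELVIN


def build_environment(
    t_air: float,
    solar: float,
    cloud: float,
    wind: float,
    rh: float,
    shade: float,
) -> Environment:
    """Assemble the driving environment for one hour and shade choice.

    The effective radiant temperature mixes sky (view factor 0.5) with
    ground assumed at air temperature; shade replaces the sky view with
    canopy at air temperature.
    """
    t_sky = sky_temperature(t_air, cloud)
    t_rad_open = 0.5 * t_sky + 0.5 * t_air
    t_rad = shade * t_air + (1.0 - shade) * t_rad_open
    return Environment(T_air=t_air, T_rad=t_rad, wind=wind, RH=rh,
                       solar=solar, shade_fraction=shade)


def simulate_day(
    taxon: TaxonSpec,
    fur: FurLayer,
    locality: Locality,
    month: MonthClimate,
    geom: AnimalGeometry | None = None,
    bmr: float | None = None,
    **solver_kw,
) -> DailyBudget:
    """One representative day: hourly shade choice, budget and stress class."""
    geom = geom or geometry_from_mass(taxon.mass)
    bmr = bmr if bmr is not None else xenarthran_bmr(taxon.mass)
    lower, upper = daily_bounds(bmr, taxon.activity_multiplier)
    doy = MID_MONTH_DOY[month.month - 1]
    temps = hourly_temperatures(month, locality.latitude, doy)

    hourly = np.empty(24)
    min_shade_m = np.empty(24)
    flagged = 0
    for h in range(24):
        solar = solar_flux(locality.latitude, doy, h, month.cloud)
        options = []
        for shade in (locality.min_shade, locality.max_shade):
            env = build_environment(temps[h], solar, month.cloud,
                                    month.wind, month.rh, shade)
            try:
                sol = solve_required_metabolism(geom, fur, env, taxon.T_core,
                                                **solver_kw)
            except ArithmeticError as exc:
                raise ArithmeticError(f"hour {h}: {exc}") from exc
            options.append((shade, sol))
        min_shade_m[h] = options[0][1].M_req
        best = min(options, key=lambda p: abs(p[1].M_req - bmr))[1]
        if best.M_req < 0.0:
            flagged += 1
            hourly[h] = 0.0
        else:
            hourly[h] = best.M_req

    daily_kj = trapezoid_daily_kj(hourly)
    if daily_kj > upper:
        stress = "cold_stress"
    elif daily_kj < lower:
        stress = "heat_stress"
    else:
        stress = "comfort"
    return DailyBudget(
        hourly_M=hourly,
        daily_kJ=daily_kj,
        stress=stress,
        active_hours=active_hours(min_shade_m, bmr),
        heat_flagged_hours=flagged,
    )


def trapezoid_daily_kj(hourly_watts: np.ndarray) -> float:
    """Trapezoidal integral of a periodic 24-h trace, in kJ day⁻¹."""
    m = np.asarray(hourly_watts, dtype=float)
    if m.shape != (24,):
        raise ValueError("expected 24 hourly values")
    closed = np.append(m, m[0])  # periodic closure
    return float(np.trapezoid(closed, dx=3600.0) / 1000.0)


def active_hours(min_shade_m: np.ndarray, bmr: float) -> float:
    """Hours per day maintainable at ≥ basal rate without seeking shade.

    An hour counts when the full-sun (minimum shade) requirement is at
    least 0.95 × BMR, i.e. no metabolic suppression would be needed.
    """
    m = np.asarray(min_shade_m, dtype=float)
    if m.shape != (24,):
        raise ValueError("expected 24 hourly solutions")
    return float(np.count_nonzero(m >= 0.95 * bmr))


def annual_summary(
    taxon: TaxonSpec,
    fur_configs: Sequence[FurLayer],
    localities: Sequence[Locality],
    **solver_kw,
) -> tuple[pd.DataFrame, dict[str, FurLayer]]:
    """12 × furs × localities budget table plus the per-locality best fur.

    "Best" = fewest thermally stressed months; ties break toward the
    thinner coat, then the sparser one (the lighter integument wins when
    performance is equal).
    """
    if not fur_configs:
        raise ValueError("need at least one fur configuration")
    records = []
    for loc in localities:
        for fur in fur_configs:
            for month in loc.months:
                budget = simulate_day(taxon, fur, loc, month, **solver_kw)
                records.append(
                    {
                        "taxon": taxon.name,
                        "locality": loc.name,
                        "fur_label": fur.label or f"{fur.depth*1000:.0f}mm@{fur.density:g}",
                        "fur_depth_m": fur.depth,
                        "fur_density": fur.density,
                        "month": month.month,
                        "daily_kJ": budget.daily_kJ,
                        "stress": budget.stress,
                        "active_hours": budget.active_hours,
                        "heat_flagged_hours": budget.heat_flagged_hours,
                    }
                )
    table = pd.DataFrame(records)
    return table, select_best_fur(table, fur_configs)


def select_best_fur(
    table: pd.DataFrame, fur_configs: Sequence[FurLayer]
) -> dict[str, FurLayer]:
    by_label = {f.label or f"{f.depth*1000:.0f}mm@{f.density:g}": f for f in fur_configs}
    best: dict[str, FurLayer] = {}
    for loc, grp in table.groupby("locality", sort=False):
        scores = []
        for label, fgrp in grp.groupby("fur_label", sort=False):
            fur = by_label[label]
            stressed = int((fgrp["stress"] != "comfort").sum())
            scores.append((stressed, fur.depth, fur.density, label))
        scores.sort()
        best[loc] = by_label[scores[0][3]]
    return best
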