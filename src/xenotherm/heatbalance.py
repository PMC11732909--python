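"""Steady-state heat balance of a furred endotherm.

The animal is modelled as a prolate spheroid of uniform density wrapped in
a fur coat.  Metabolic heat produced in the core is conducted through the
coat (a slab whose area is evaluated at mid-depth) and leaves the outer
fur surface by forced/free convection and net thermal infrared exchange;
absorbed solar radiation offsets part of the load.  A small fixed fraction
of heat production is lost evaporatively (respiratory/cutaneous baseline;
active panting or sweating is deliberately not modelled).  Solving the
surface energy balance for the fur-surface temperature yields the
metabolic heat production M_req required to hold the core at its set
point; sweeping chamber air temperature locates the thermoneutral zone
(the band where M_req stays within ±5% of basal rate).

Fur insulation couples two effects: the still-air/keratin mixture
conductivity of the coat, and how much of the coat actually holds still
air.  Sparse coats (a few hairs per cm²) cannot immobilize the air between
hairs, so only a fraction of their depth insulates; that fraction is the
ratio of a ~0.2 mm immobilization length to the mean inter-hair spacing.
Dense coats (≥ ~2,000 hairs cm⁻²) immobilize nearly their full depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "AnimalGeometry",
    "FurLayer",
    "Environment",
    "HeatBalanceSolution",
    "ThermoneutralZone",
    "SIGMA",
    "geometry_from_mass",
    "prolate_spheroid_area",
    "fur_effective_conductivity",
    "fur_immobilized_fraction",
    "skin_conduction_flux",
    "air_conductivity",
    "air_kinematic_viscosity",
    "convection_coefficient",
    "solve_required_metabolism",
    "critical_temperatures",
    "metabolic_chamber_sweep",
    "chamber_environment",
    "heterothermic_solve",
]

SIGMA = 5.670374419e-8  # W m-2 K-4
KELVIN = 273.15

DEFAULT_EMISSIVITY = 0.95
DEFAULT_SOLAR_ABSORPTIVITY = 0.8
DEFAULT_INTERCEPTION = 0.25  # silhouette fraction of total area facing the sun
DEFAULT_EVAP_FRACTION = 0.05
#: inter-hair spacing (m) below which coat air is fully immobilized
IMMOBILIZATION_LENGTH = 2.0e-4


def prolate_spheroid_area(semi_major: float, semi_minor: float) -> float:
    """Closed-form surface area; degenerates smoothly to the sphere."""
    a, b = semi_major, semi_minor
    if a < b:
        raise ValueError("semi-major axis smaller than semi-minor")
    if a == b:
        return 4.0 * math.pi * a * a
    e = math.sqrt(1.0 - (b / a) ** 2)
    return 2.0 * math.pi * b * b * (1.0 + (a / (b * e)) * math.asin(e))


@dataclass(frozen=True)
class AnimalGeometry:
    """Prolate-spheroid body: mass and shape fix every derived dimension."""

    mass: float  # kg
    body_density: float = 1000.0  # kg m-3
    shape_ratio: float = 2.0  # length : diameter

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.body_density <= 0:
            raise ValueError("mass and density must be positive")
        if self.shape_ratio < 1.0:
            raise ValueError("shape_ratio must be >= 1 (prolate)")

    @property
    def volume(self) -> float:
        return self.mass / self.body_density

    @property
    def semi_minor(self) -> float:
        # V = 4/3 pi a b^2 with a = ratio * b
        return (3.0 * self.volume / (4.0 * math.pi * self.shape_ratio)) ** (1.0 / 3.0)

    @property
    def semi_major(self) -> float:
        return self.shape_ratio * self.semi_minor

    @property
    def surface_area(self) -> float:
        return prolate_spheroid_area(self.semi_major, self.semi_minor)

    @property
    def characteristic_dimension(self) -> float:
        """Trunk diameter, the length scale for the convection correlation."""
        return 2.0 * self.semi_minor

    def offset_area(self, offset: float) -> float:
        """Surface area of the spheroid grown outward by ``offset`` metres."""
        return prolate_spheroid_area(self.semi_major + offset, self.semi_minor + offset)


def geometry_from_mass(
    mass: float, density: float = 1000.0, shape_ratio: float = 2.0
) -> AnimalGeometry:
    return AnimalGeometry(mass=mass, body_density=density, shape_ratio=shape_ratio)


@dataclass(frozen=True)
class FurLayer:
    """One fur configuration: depth (m) and areal hair density (hairs cm⁻²)."""

    depth: float
    density: float
    hair_diameter: float = 1.0e-4  # m
    k_hair: float = 0.209  # W m-1 K-1, keratin
    k_air: float = 0.0257  # W m-1 K-1, still air near 20 °C
    label: str = ""

    def __post_init__(self) -> None:
        if self.depth < 0 or self.density < 0:
            raise ValueError("depth and density must be non-negative")
        if not 0.0 <= self.fiber_fraction < 1.0:
            raise ValueError("fiber volume fraction must lie in [0, 1)")

    @property
    def fiber_fraction(self) -> float:
        """Volume fraction of the coat occupied by hair fibres."""
        per_m2 = self.density * 1.0e4
        return per_m2 * math.pi * (self.hair_diameter / 2.0) ** 2


def fur_effective_conductivity(fur: FurLayer) -> float:
    """Linear air/keratin mixture conductivity of the coat (W m⁻¹ K⁻¹)."""
    f = fur.fiber_fraction
    if f >= 1.0:
        raise ValueError("fiber volume fraction >= 1: over-dense fur")
    return fur.k_air + (fur.k_hair - fur.k_air) * f


def fur_immobilized_fraction(fur: FurLayer) -> float:
    """Fraction of coat depth holding still (insulating) air, in [0, 1].

    The mean inter-hair spacing is density^(-1/2); air is taken as fully
    still when that spacing falls below IMMOBILIZATION_LENGTH, and the
    still fraction scales as (immobilization length / spacing) above it.
    Elephant-sparse coats (~0.07 cm⁻²) therefore insulate almost nothing,
    while 2,000 cm⁻² coats insulate over ~90% of their depth.
    """
    if fur.density <= 0:
        return 0.0
    spacing = 1.0 / math.sqrt(fur.density * 1.0e4)
    return min(1.0, IMMOBILIZATION_LENGTH / spacing)


@dataclass(frozen=True)
class Environment:
    T_air: float  # °C
    T_rad: float  # °C, effective radiant temperature of surroundings
    wind: float = 0.1  # m s-1
    RH: float = 50.0  # %
    solar: float = 0.0  # W m-2, horizontal flux
    shade_fraction: float = 0.0  # [0, 1]

    def __post_init__(self) -> None:
        if self.wind < 0 or self.solar < 0:
            raise ValueError("wind and solar must be non-negative")
        if not 0.0 <= self.RH <= 100.0:
            raise ValueError("RH must be in [0, 100] %")
        if not 0.0 <= self.shade_fraction <= 1.0:
            raise ValueError("shade_fraction must be in [0, 1]")


@dataclass
class HeatBalanceSolution:
    M_req: float  # W, required metabolic heat production
    T_skin: float  # °C
    T_fur_surface: float  # °C
    Q_conv: float  # W
    Q_ir: float  # W
    Q_solar_abs: float  # W
    Q_evap: float  # W
    residual: float  # W, energy-closure defect
    feasible: bool = True  # False when M_req < 0 (heat suppression needed)


@dataclass(frozen=True)
class ThermoneutralZone:
    lct: float | None
    uct: float | None
    present: bool


def skin_conduction_flux(
    k_skin: float, thickness: float, T_inner: float, T_skin: float
) -> float:
    """Conductive heat flux density through skin, (k/s)·(T_inner − T_skin)."""
    if thickness <= 0:
        raise ValueError("skin thickness must be positive")
    return (k_skin / thickness) * (T_inner - T_skin)


def air_conductivity(T_celsius: float) -> float:
    """Thermal conductivity of dry air (W m⁻¹ K⁻¹), linear fit to tables."""
    return 0.0243 + 7.2e-5 * T_celsius


def air_kinematic_viscosity(T_celsius: float) -> float:
    """Kinematic viscosity of dry air (m² s⁻¹), linear fit to tables."""
    return 1.338e-5 + 8.5e-8 * T_celsius


def convection_coefficient(
    T_surface: float, env: Environment, characteristic_dimension: float
) -> float:
    """Convective coefficient h (W m⁻² K⁻¹), cylinder in crossflow.

    Nu = 0.35 + 0.56 Re^0.52 with air properties at film temperature,
    floored at the conduction limit Nu = 2 (still air).
    """
    d = characteristic_dimension
    if d <= 0:
        raise ValueError("characteristic dimension must be positive")
    T_film = 0.5 * (T_surface + env.T_air)
    k = air_conductivity(T_film)
    nu = air_kinematic_viscosity(T_film)
    re = env.wind * d / nu
    nusselt = 0.35 + 0.56 * re**0.52 if re > 0 else 0.35
    nusselt = max(nusselt, 2.0)
    return nusselt * k / d


def _external_loss(
    T_surface: float,
    env: Environment,
    geom: AnimalGeometry,
    area_out: float,
    emissivity: float,
    absorptivity: float,
    interception: float,
) -> tuple[float, float, float]:
    """(Q_conv, Q_ir, Q_solar_abs) at a trial outer-surface temperature."""
    h = convection_coefficient(T_surface, env, geom.characteristic_dimension)
    q_conv = h * area_out * (T_surface - env.T_air)
    ts_k = T_surface + KELVIN
    tr_k = env.T_rad + KELVIN
    q_ir = emissivity * SIGMA * area_out * (ts_k**4 - tr_k**4)
    q_solar = (
        absorptivity
        * interception
        * (1.0 - env.shade_fraction)
        * env.solar
        * area_out
    )
    return q_conv, q_ir, q_solar


def solve_required_metabolism(
    geom: AnimalGeometry,
    fur: FurLayer,
    env: Environment,
    T_core: float,
    evap_fraction: float = DEFAULT_EVAP_FRACTION,
    emissivity: float = DEFAULT_EMISSIVITY,
    absorptivity: float = DEFAULT_SOLAR_ABSORPTIVITY,
    interception: float = DEFAULT_INTERCEPTION,
) -> HeatBalanceSolution:
    """Metabolic heat production required to hold T_core in ``env``.

    The fur-surface temperature is found by root-finding on the surface
    balance (fur conduction = convection + net IR − absorbed solar); the
    metabolic requirement then satisfies M_req = Q_fur + Q_evap with
    Q_evap = evap_fraction × M_req.  Negative M_req is returned as-is with
    ``feasible=False``: the environment loads more heat onto the animal
    than its surface can shed at basal production.
    """
    if not math.isfinite(T_core):
        raise ValueError("T_core must be finite")
    if not 0.0 <= evap_fraction < 1.0:
        raise ValueError("evap_fraction must be in [0, 1)")

    depth_eff = fur.depth * fur_immobilized_fraction(fur)
    skin_temp = T_core  # well-perfused skin at the core set point

    if depth_eff <= 0.0:
        # bare skin (or wind-washed coat): surface is the skin itself
        area_out = geom.offset_area(fur.depth)
        q_conv, q_ir, q_solar = _external_loss(
            skin_temp, env, geom, area_out, emissivity, absorptivity, interception
        )
        q_net = q_conv + q_ir - q_solar
        m_req = q_net / (1.0 - evap_fraction)
        q_evap = evap_fraction * m_req
        residual = m_req - q_evap + q_solar - q_conv - q_ir
        return HeatBalanceSolution(
            M_req=m_req, T_skin=skin_temp, T_fur_surface=skin_temp,
            Q_conv=q_conv, Q_ir=q_ir, Q_solar_abs=q_solar, Q_evap=q_evap,
            residual=residual, feasible=(m_req >= 0.0),
        )

    area_out = geom.offset_area(fur.depth)
    area_mid = geom.offset_area(fur.depth - depth_eff / 2.0)
    conductance = fur_effective_conductivity(fur) * area_mid / depth_eff

    def balance(t_s: float) -> float:
        q_conv, q_ir, q_solar = _external_loss(
            t_s, env, geom, area_out, emissivity, absorptivity, interception
        )
        return conductance * (skin_temp - t_s) - (q_conv + q_ir - q_solar)

    lo, hi = T_core - 50.0, T_core + 50.0
    while balance(lo) < 0.0 or balance(hi) > 0.0:
        # balance() is strictly decreasing in t_s; widen until bracketed
        lo -= 50.0
        hi += 50.0
        if hi - T_core > 200.0:
            q = _external_loss(T_core, env, geom, area_out, emissivity,
                               absorptivity, interception)
            raise ArithmeticError(
                "fur-surface balance not bracketed within T_core ± 200 K; "
                f"fluxes at T_core: conv={q[0]:.1f} W, ir={q[1]:.1f} W, "
                f"solar={q[2]:.1f} W"
            )
    t_surf = brentq(balance, lo, hi, xtol=1.0e-6)

    q_conv, q_ir, q_solar = _external_loss(
        t_surf, env, geom, area_out, emissivity, absorptivity, interception
    )
    q_fur = conductance * (skin_temp - t_surf)
    m_req = q_fur / (1.0 - evap_fraction)
    q_evap = evap_fraction * m_req
    residual = m_req - q_evap + q_solar - q_conv - q_ir
    return HeatBalanceSolution(
        M_req=m_req, T_skin=skin_temp, T_fur_surface=t_surf,
        Q_conv=q_conv, Q_ir=q_ir, Q_solar_abs=q_solar, Q_evap=q_evap,
        residual=residual, feasible=(m_req >= 0.0),
    )


def chamber_environment(T_air: float, wind: float = 0.1) -> Environment:
    """Metabolic-chamber convention: walls at air temperature, no sun."""
    return Environment(T_air=T_air, T_rad=T_air, wind=wind, RH=50.0,
                       solar=0.0, shade_fraction=0.0)


def _chamber_m_req(geom, fur, T_core, T_air, wind, **kw) -> float:
    return solve_required_metabolism(
        geom, fur, chamber_environment(T_air, wind), T_core, **kw
    ).M_req


def metabolic_chamber_sweep(
    geom: AnimalGeometry,
    fur: FurLayer,
    T_core: float,
    bmr: float,
    T_range: tuple[float, float] = (-60.0, 50.0),
    step: float = 0.5,
    wind: float = 0.1,
    band: float = 0.05,
    **solver_kw,
) -> ThermoneutralZone:
    """Sweep chamber temperature; TNZ is where |M_req − BMR| ≤ band·BMR."""
    if step <= 0:
        raise ValueError("step must be positive")
    lo, hi = T_range
    temps = np.arange(lo, hi + step / 2.0, step)
    m = np.array([_chamber_m_req(geom, fur, T_core, float(t), wind, **solver_kw)
                  for t in temps])
    in_band = np.abs(m - bmr) <= band * bmr
    if not in_band.any():
        return ThermoneutralZone(lct=None, uct=None, present=False)
    hits = temps[in_band]
    return ThermoneutralZone(lct=float(hits.min()), uct=float(hits.max()), present=True)


def critical_temperatures(
    geom: AnimalGeometry,
    fur: FurLayer,
    T_core: float,
    bmr: float,
    T_range: tuple[float, float] = (-100.0, 60.0),
    wind: float = 0.1,
    band: float = 0.05,
    **solver_kw,
) -> ThermoneutralZone:
    """Continuous LCT/UCT by root-finding on the chamber response curve.

    M_req is strictly decreasing in chamber temperature below T_core, so
    the lower/upper critical temperatures are the unique roots of
    M_req(T) = (1 ± band)·BMR.  Returns present=False when the band is not
    crossed inside T_range.
    """
    lo, hi = T_range

    def f_at(target):
        def f(t):
            return _chamber_m_req(geom, fur, T_core, t, wind, **solver_kw) - target
        return f

    zone = {}
    for name, target in (("lct", (1.0 + band) * bmr), ("uct", (1.0 - band) * bmr)):
        f = f_at(target)
        f_lo, f_hi = f(lo), f(hi)
        if f_lo * f_hi > 0:
            return ThermoneutralZone(lct=None, uct=None, present=False)
        zone[name] = float(brentq(f, lo, hi, xtol=1.0e-4))
    return ThermoneutralZone(lct=zone["lct"], uct=zone["uct"], present=True)


def heterothermic_solve(
    geom: AnimalGeometry,
    fur: FurLayer,
    env: Environment,
    t_core_range: tuple[float, float],
    bmr: float,
    n_grid: int = 7,
    **solver_kw,
) -> HeatBalanceSolution:
    """Relax the core set point within a range, minimizing |M_req − BMR|.

    Emulates heterothermy as used by extant xenarthrans: the animal lets
    its core drift inside a tolerated band when that saves energy.
    """
    lo, hi = t_core_range
    if lo > hi:
        raise ValueError("t_core_range must be ordered")
    best = None
    for t_core in np.linspace(lo, hi, n_grid):
        sol = solve_required_metabolism(geom, fur, env, float(t_core), **solver_kw)
        if best is None or abs(sol.M_req - bmr) < abs(best.M_req - bmr):
            best = sol
    return best
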