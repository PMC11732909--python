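"""xenotherm: thermophysiology of extinct ground sloths.

Clumped-isotope (Δ47) body-temperature estimation with diagenesis
screening, allometric metabolic budgeting, a fur-insulated endotherm
heat-balance model, and microclimate-driven daily energy budgets.
"""

__version__ = "0.1.0"

from .diagenesis import (
    REEProfile,
    load_paas_reference,
    normalize_paas,
    offset_screen,
    ree_index,
)
from .foraging import DietSpec, fit_monthly_quadratic, wet_intake
from .heatbalance import (
    AnimalGeometry,
    Environment,
    FurLayer,
    critical_temperatures,
    fur_effective_conductivity,
    geometry_from_mass,
    metabolic_chamber_sweep,
    solve_required_metabolism,
)
from .isotopes import (
    CalibrationParams,
    aggregate_replicates,
    correct_with_standards,
    delta47_to_temperature,
    estimate_water_d18O,
    flag_d48,
    propagate_temperature_se,
    reduce_samples,
    temperature_to_delta47,
    vpdb_to_vsmow,
)
from .metabolism import (
    TaxonSpec,
    daily_bounds,
    fit_power_law,
    kleiber_bmr,
    placental_fraction,
    xenarthran_bmr,
)
from .microclimate import (
    Locality,
    MonthClimate,
    active_hours,
    annual_summary,
    hourly_temperatures,
    simulate_day,
    sky_temperature,
    solar_flux,
)

#: the four modelled genera: (mass kg, clumped-isotope core temperature °C)
PAPER_TAXA = {
    "Eremotherium": (4490.0, 29.0),
    "Megatherium": (3706.0, 31.0),
    "Mylodon": (1986.0, 23.0),
    "Nothrotheriops": (463.0, 32.0),
}


def default_taxa() -> list[TaxonSpec]:
    """The four study genera as TaxonSpec objects (no fur attached)."""
    return [TaxonSpec(name=n, mass=m, T_core=t) for n, (m, t) in PAPER_TAXA.items()]
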