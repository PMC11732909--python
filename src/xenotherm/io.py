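"""Plain-text input parsing (CSV + YAML) and config validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .heatbalance import FurLayer
from .metabolism import TaxonSpec
from .microclimate import Locality, MonthClimate

__all__ = [
    "RunConfig",
    "load_config",
    "load_replicates_csv",
    "load_standards_csv",
    "load_ree_csv",
    "load_taxa_yaml",
    "load_locality",
]

_REPLICATE_COLS = ["sample_id", "run_index", "d13C_vpdb", "d18O_vpdb", "D47", "D48"]
_STANDARD_COLS = ["name", "run_index", "measured_D47", "accepted_D47"]
_REE_COLS = ["sample_id", "tissue", "element", "ppm"]
_CLIMATE_COLS = ["month", "tmax_c", "tmin_c", "rh_pct", "cloud_frac", "wind_ms",
                 "paleo_offset_c"]

_CONFIG_KEYS = {
    "calibration_slope_a",
    "calibration_intercept_b",
    "d48_threshold",
    "standards_window",
    "water_strategy",
    "oxyjoule",
    "emissivity",
    "solar_absorptivity",
    "interception",
    "evap_fraction",
    "sweep_range",
    "sweep_step",
    "offset_band",
}


@dataclass
class RunConfig:
    """Validated parameter overrides; unknown keys are rejected."""

    calibration_slope_a: float = 0.0391e6
    calibration_intercept_b: float = 0.154
    d48_threshold: float = 1.0
    standards_window: int = 10
    water_strategy: str = "carbonate"
    oxyjoule: float = 20.0
    emissivity: float = 0.95
    solar_absorptivity: float = 0.8
    interception: float = 0.25
    evap_fraction: float = 0.05
    sweep_range: tuple = (-60.0, 50.0)
    sweep_step: float = 0.5
    offset_band: tuple = (7.0, 10.0)


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "sweep_range" in raw:
        raw["sweep_range"] = tuple(raw["sweep_range"])
    if "offset_band" in raw:
        raw["offset_band"] = tuple(raw["offset_band"])
    return RunConfig(**raw)


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return df


def load_replicates_csv(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, _REPLICATE_COLS).rename(columns={})


def load_standards_csv(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, _STANDARD_COLS)


def load_ree_csv(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, _REE_COLS)


def load_taxa_yaml(path: str | Path) -> list[TaxonSpec]:
    """Taxon YAML: a list of {name, mass_kg, t_core_c, activity_multiplier, fur}."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, list) or not raw:
        raise ValueError(f"{path}: expected a non-empty list of taxa")
    taxa = []
    for entry in raw:
        furs = [
            FurLayer(
                depth=f["depth_mm"] / 1000.0,
                density=f["density_per_cm2"],
                label=f.get("label", ""),
            )
            for f in entry.get("fur", [])
        ]
        taxa.append(
            TaxonSpec(
                name=entry["name"],
                mass=entry["mass_kg"],
                T_core=entry["t_core_c"],
                activity_multiplier=entry.get("activity_multiplier", 2.0),
                fur_configs=furs,
            )
        )
    return taxa


def load_locality(yaml_path: str | Path, climate_csv: str | Path) -> Locality:
    """Locality YAML (name, latitude, shade) + 12-row monthly climate CSV."""
    meta = yaml.safe_load(Path(yaml_path).read_text())
    df = _read_csv(climate_csv, _CLIMATE_COLS)
    if len(df) != 12:
        raise ValueError(f"{climate_csv}: expected 12 monthly rows, got {len(df)}")
    months = tuple(
        MonthClimate(
            month=int(r.month),
            t_max=r.tmax_c,
            t_min=r.tmin_c,
            rh=r.rh_pct,
            cloud=r.cloud_frac,
            wind=r.wind_ms,
            paleo_offset=r.paleo_offset_c,
        )
        for r in df.itertuples()
    )
    return Locality(
        name=meta["name"],
        latitude=meta["latitude"],
        months=months,
        min_shade=meta.get("min_shade", 0.0),
        max_shade=meta.get("max_shade", 0.9),
    )
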