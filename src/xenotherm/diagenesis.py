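"""Diagenesis screening of fossil bioapatite.

Two independent screens are provided:

* the shale-normalized rare-earth-element (REE) index — the sum of
  PAAS-normalized lanthanide concentrations in orthodentine divided by the
  same sum in cortical bone of the same (or a co-local) individual.  Bone
  is highly porous and takes up REE aggressively during fossilization,
  while inner orthodentine resists impregnation, so a small ratio indicates
  a tooth tissue that escaped the pore-water REE flux and likely preserves
  its original isotope signal;
* the carbonate–phosphate δ18O offset — the carbonate moiety of bioapatite
  alters more readily than the phosphate moiety, so an offset outside the
  band observed in extant vertebrates points to preferential carbonate
  alteration.

Normalization against Post-Archean Australian Shale (PAAS) removes the
Oddo–Harkins even–odd abundance sawtooth so that element sums are
comparable across the lanthanide series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "LANTHANIDES",
    "REEProfile",
    "REEIndexResult",
    "OffsetScreen",
    "load_paas_reference",
    "normalize_paas",
    "ree_index",
    "classify_ratio",
    "offset_screen",
    "qc_report",
]

logger = logging.getLogger(__name__)

#: the 14 lanthanides, La…Lu, in atomic-number order
LANTHANIDES = (
    "La", "Ce", "Pr", "Nd", "Sm", "Eu", "Gd",
    "Tb", "Dy", "Ho", "Er", "Tm", "Yb", "Lu",
)

#: analytes measured alongside the REE but excluded from the index
NON_REE_ANALYTES = ("Ca", "Sc", "Sr", "Y", "Ba", "Pb", "U", "In")

ALTERATION_CLASSES = ("minimal", "low", "mild_moderate", "significant")


@dataclass(frozen=True)
class REEProfile:
    """Element → concentration (ppm) for one tissue of one specimen."""

    tissue: str  # "orthodentine" or "cortical_bone"
    concentrations: dict[str, float]

    def __post_init__(self) -> None:
        bad = {e: c for e, c in self.concentrations.items() if c < 0}
        if bad:
            raise ValueError(f"negative concentrations: {bad}")


@dataclass(frozen=True)
class REEIndexResult:
    ratio: float
    alteration_class: str
    n_elements: int


@dataclass(frozen=True)
class OffsetScreen:
    d18O_carb_vsmow: float
    d18O_phos_vsmow: float
    offset: float
    within_band: bool


def load_paas_reference() -> dict[str, float]:
    """PAAS REE concentrations (ppm), shipped as a versioned fixture."""
    with resources.files("xenotherm.data").joinpath("paas_reference.csv").open() as fh:
        df = pd.read_csv(fh)
    return dict(zip(df["element"], df["ppm"]))


def normalize_paas(
    profile: REEProfile, ref: dict[str, float] | None = None
) -> dict[str, float]:
    """Elementwise concentration / PAAS reference, dimensionless."""
    ref = ref if ref is not None else load_paas_reference()
    out = {}
    for element, ppm in profile.concentrations.items():
        if element not in ref:
            raise KeyError(f"element {element!r} missing from PAAS reference")
        out[element] = ppm / ref[element]
    return out


def classify_ratio(ratio: float) -> str:
    """Map a dentine:bone REE ratio to an alteration class.

    < 0.35 minimal; 0.35–0.5 low; 0.5–1.0 mild_moderate (1.0 inclusive);
    > 1.0 significant.  Every finite non-negative ratio maps to exactly one
    class.
    """
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    if ratio > 1.0:
        return "significant"
    if ratio > 0.5:
        return "mild_moderate"
    if ratio >= 0.35:
        return "low"
    return "minimal"


def ree_index(
    dentine: REEProfile,
    bone: REEProfile,
    ref: dict[str, float] | None = None,
) -> REEIndexResult:
    """Σ normalized REE (dentine) / Σ normalized REE (bone).

    Elements measured in only one tissue are dropped pairwise (from both
    sums) with a logged count; non-REE analytes are ignored.
    """
    ref = ref if ref is not None else load_paas_reference()
    d_elems = {e for e in dentine.concentrations if e in LANTHANIDES}
    b_elems = {e for e in bone.concentrations if e in LANTHANIDES}
    shared = d_elems & b_elems
    dropped = (d_elems | b_elems) - shared
    if dropped:
        logger.info("ree_index: dropped %d unpaired element(s): %s",
                    len(dropped), sorted(dropped))
    if not shared:
        raise ValueError("no shared REE between dentine and bone profiles")
    d_norm = normalize_paas(
        REEProfile(dentine.tissue, {e: dentine.concentrations[e] for e in shared}), ref
    )
    b_norm = normalize_paas(
        REEProfile(bone.tissue, {e: bone.concentrations[e] for e in shared}), ref
    )
    denom = sum(b_norm.values())
    if denom == 0:
        raise ValueError("bone normalized REE sum is zero: ratio undefined")
    ratio = sum(d_norm.values()) / denom
    return REEIndexResult(ratio=ratio, alteration_class=classify_ratio(ratio),
                          n_elements=len(shared))


def offset_screen(
    d18O_carb_vsmow: float,
    d18O_phos_vsmow: float,
    band: tuple[float, float] = (7.0, 10.0),
) -> OffsetScreen:
    """Carbonate − phosphate δ18O offset against the extant-vertebrate band.

    The default band is a literature-informed placeholder and should be
    configured per reference dataset; the interval is closed at both ends.
    """
    lo, hi = band
    if not lo < hi:
        raise ValueError("band lower bound must be below upper bound")
    offset = d18O_carb_vsmow - d18O_phos_vsmow
    return OffsetScreen(
        d18O_carb_vsmow=d18O_carb_vsmow,
        d18O_phos_vsmow=d18O_phos_vsmow,
        offset=offset,
        within_band=(lo <= offset <= hi),
    )


def qc_report(
    ree_table: pd.DataFrame,
    ref: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-sample REE QC from a long table (sample_id, tissue, element, ppm)."""
    ref = ref if ref is not None else load_paas_reference()
    rows = []
    for sid, grp in ree_table.groupby("sample_id", sort=False):
        profiles = {}
        for tissue, tgrp in grp.groupby("tissue"):
            profiles[tissue] = REEProfile(
                tissue=tissue,
                concentrations=dict(zip(tgrp["element"], tgrp["ppm"])),
            )
        if "orthodentine" not in profiles or "cortical_bone" not in profiles:
            raise ValueError(f"sample {sid!r}: need both orthodentine and cortical_bone")
        res = ree_index(profiles["orthodentine"], profiles["cortical_bone"], ref)
        rows.append(
            {
                "sample_id": sid,
                "ree_ratio": res.ratio,
                "alteration_class": res.alteration_class,
                "n_elements": res.n_elements,
            }
        )
    return pd.DataFrame(rows)
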