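"""Daily energy expenditure → wet-mass forage intake, and monthly trends.

Intake converts an energy requirement through diet quality: gross energy
of the dry matter, digestive efficiency, and the dry-matter fraction of
fresh forage.  Monthly intake series are summarized with second-order
polynomial (quadratic) least-squares fits, the standard way to expose a
seasonal rise-and-fall in a 12-point series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DietSpec", "IntakeCurve", "DEFAULT_LEAF_DIET", "wet_intake",
           "fit_monthly_quadratic"]


@dataclass(frozen=True)
class DietSpec:
    """Nutritional quality of a forage class."""

    gross_energy: float  # MJ per kg dry matter
    digestibility: float  # [0, 1]
    dry_matter_fraction: float  # (0, 1]

    def __post_init__(self) -> None:
        if self.gross_energy <= 0:
            raise ValueError("gross_energy must be positive")
        if not 0.0 <= self.digestibility <= 1.0:
            raise ValueError("digestibility must be in [0, 1]")
        if not 0.0 < self.dry_matter_fraction <= 1.0:
            raise ValueError("dry_matter_fraction must be in (0, 1]")


#: browse-leaf default: 18 MJ/kg DM gross energy, 45% digestible, 30% DM
DEFAULT_LEAF_DIET = DietSpec(gross_energy=18.0, digestibility=0.45,
                             dry_matter_fraction=0.30)


@dataclass(frozen=True)
class IntakeCurve:
    a: float  # quadratic coefficient
    b: float  # linear coefficient
    c: float  # intercept
    r_squared: float

    def predict(self, month: float) -> float:
        return self.a * month**2 + self.b * month + self.c


def wet_intake(daily_kJ: float, diet: DietSpec = DEFAULT_LEAF_DIET) -> float:
    """Wet forage mass (kg day⁻¹) supplying ``daily_kJ`` of usable energy."""
    if daily_kJ < 0:
        raise ValueError("daily_kJ must be non-negative")
    if diet.digestibility == 0:
        raise ValueError("zero digestibility: intake undefined")
    dry = daily_kJ / (diet.gross_energy * 1000.0 * diet.digestibility)
    return dry / diet.dry_matter_fraction


def fit_monthly_quadratic(months: np.ndarray, intake: np.ndarray) -> IntakeCurve:
    """OLS quadratic y = a·x² + b·x + c over month index, with R².

    Constant data (zero total sum of squares) is reported as R² = 0.
    """
    x = np.asarray(months, dtype=float)
    y = np.asarray(intake, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct month values")
    a, b, c = np.polyfit(x, y, 2)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return IntakeCurve(a=0.0, b=0.0, c=float(y.mean()), r_squared=0.0)
    resid = y - (a * x**2 + b * x + c)
    r2 = 1.0 - float(np.sum(resid**2)) / sst
    return IntakeCurve(a=float(a), b=float(b), c=float(c), r_squared=r2)
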