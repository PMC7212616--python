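"""Environmental impact accounting and monetization.

Consumption (kg/year per food group) is converted into five life-cycle impact
indicators — greenhouse-gas emissions (kg CO2-eq), acidification (kg SO2-eq),
fresh-water eutrophication (kg P-eq), salt-water eutrophication (kg N-eq) and
land use (m2a) — via per-kg footprints, scaled by a production-efficiency
trajectory, and monetized with Dutch unit damage costs.

Efficiency gains are linear in percentage points of the base-year intensity
(a 20% decline over 16 years annualizes to 1.25%/yr under this convention),
applied uniformly to every indicator and food group.  Because the same factor
multiplies scenario and reference impacts, relative scenario-vs-reference
changes are efficiency-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ModelInputError

#: indicator order used by every 5-vector in the package
INDICATORS = ("ghg", "acidification", "fresh_eutroph", "salt_eutroph", "land")

INDICATOR_UNITS = {
    "ghg": "kg CO2-eq",
    "acidification": "kg SO2-eq",
    "fresh_eutroph": "kg P-eq",
    "salt_eutroph": "kg N-eq",
    "land": "m2a",
}


@dataclass(frozen=True)
class ImpactVector:
    """Bundle of the five environmental indicators.

    Supports addition, subtraction and scalar multiplication, so impact
    arithmetic reads like vector algebra.
    """

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(INDICATORS),):
            raise ModelInputError(f"ImpactVector needs {len(INDICATORS)} entries, got {v.shape}")
        object.__setattr__(self, "values", v)

    @classmethod
    def zero(cls) -> "ImpactVector":
        return cls(np.zeros(len(INDICATORS)))

    @classmethod
    def from_dict(cls, d: dict) -> "ImpactVector":
        return cls(np.array([float(d[k]) for k in INDICATORS]))

    def as_dict(self) -> dict:
        return {k: float(v) for k, v in zip(INDICATORS, self.values)}

    def __add__(self, other: "ImpactVector") -> "ImpactVector":
        return ImpactVector(self.values + other.values)

    def __sub__(self, other: "ImpactVector") -> "ImpactVector":
        return ImpactVector(self.values - other.values)

    def __mul__(self, c: float) -> "ImpactVector":
        return ImpactVector(self.values * float(c))

    __rmul__ = __mul__

    def __getitem__(self, key: str) -> float:
        return float(self.values[INDICATORS.index(key)])


@dataclass(frozen=True)
class UnitCosts:
    """Monetary damage cost per unit of each indicator (EUR/unit).

    Central estimates for the Dutch situation; ``scaled`` produces the
    high/low variants used in the HEC-LEG / LEC-HEG sensitivity scenarios.
    """

    ghg: float = 0.057        # EUR per kg CO2-eq
    acidification: float = 5.40   # EUR per kg SO2-eq
    fresh_eutroph: float = 3.11   # EUR per kg P-eq
    salt_eutroph: float = 1.90    # EUR per kg N-eq
    land: float = 0.0261      # EUR per m2a

    def __post_init__(self):
        if min(self.as_array()) <= 0:
            raise ModelInputError("unit costs must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in INDICATORS], dtype=float)

    def scaled(self, factor: float) -> "UnitCosts":
        return UnitCosts(*(self.as_array() * factor))


@dataclass(frozen=True)
class EfficiencyTrajectory:
    """Linear decline of footprint intensity relative to the base year."""

    base_year: int = 2018
    annual_gain: float = 0.0125  # fraction of base-year intensity per year

    def factor(self, year: int) -> float:
        return efficiency_factor(year, self)


def efficiency_factor(year: int, trajectory: EfficiencyTrajectory) -> float:
    """Footprint multiplier for ``year``: 1 − gain·(year − base_year).

    Raises if the year precedes the base year or the linear decline has
    exhausted the base-year intensity (factor ≤ 0).
    """
    if year < trajectory.base_year:
        raise ModelInputError(f"year {year} precedes base year {trajectory.base_year}")
    f = 1.0 - trajectory.annual_gain * (year - trajectory.base_year)
    if f <= 0:
        raise ModelInputError(f"efficiency factor non-positive ({f:.3f}) in {year}")
    return f


def annual_impact(
    kg_by_group: dict[str, float],
    footprints,
    year: int,
    trajectory: EfficiencyTrajectory,
) -> ImpactVector:
    """Total impact of one year's consumption.

    ``footprints`` is any mapping-like object with ``per_kg[group] ->
    ImpactVector`` (the synthetic :class:`~foodscba.synthetic.FootprintTable`
    satisfies this).
    """
    table = footprints.per_kg if hasattr(footprints, "per_kg") else footprints
    f = efficiency_factor(year, trajectory)
    total = ImpactVector.zero()
    for group, kg in kg_by_group.items():
        if kg < 0:
            raise ModelInputError(f"negative consumption for {group}")
        if group not in table:
            raise ModelInputError(f"no footprint for food group {group!r}")
        total = total + table[group] * (kg * f)
    return total


def monetize(impact_delta: ImpactVector, costs: UnitCosts) -> float:
    """EUR value of an impact *reduction* vector (avoided burden is positive)."""
    return float(impact_delta.values @ costs.as_array())


def impact_series(
    kg_table: pd.DataFrame,
    footprints,
    trajectory: EfficiencyTrajectory,
    groups: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Impacts per year for a consumption table (index: year, columns: food group).

    Returns a DataFrame indexed by year with one column per indicator.
    """
    groups = tuple(groups) if groups is not None else tuple(kg_table.columns)
    rows = {}
    for year, row in kg_table.iterrows():
        vec = annual_impact({g: float(row[g]) for g in groups}, footprints, int(year), trajectory)
        rows[int(year)] = vec.values
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(INDICATORS))
    out.index.name = "year"
    return out
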