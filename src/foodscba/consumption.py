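"""Consumption projection under price scenarios via own-price elasticities.

Three policy scenarios are compared against a no-policy reference: a 15% or
30% consumer-price increase on total meat (red, processed and poultry) and a
10% price decrease on fruit & vegetables.  Quantity response uses own-price
elasticities (meat −0.60, fruit & vegetables −0.53, with 95% CIs for
sensitivity analysis); cross-price substitution is out of scope.

Two demand forms are supported.  The default, iso-elastic, applies
``q1 = q0 * (1 + dp)**eps`` — constant elasticity along the price path; the
``linear`` option applies ``q1 = q0 * (1 + eps * dp)``.  The policy takes
effect with full pass-through in the first year after the base year and stays
constant; the reference trajectory has no autonomous trend, so reference cell
means are constant and only demography reweights the population average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ModelInputError
from .synthetic import (
    AGES,
    FOOD_GROUPS,
    G_PER_DAY_TO_KG_PER_YEAR,
    MEAT_GROUPS,
    SEXES,
    SyntheticBundle,
)


@dataclass(frozen=True)
class Elasticity:
    """Own-price elasticity of demand with its 95% CI."""

    food_group: str
    point: float
    ci: tuple[float, float]

    def __post_init__(self):
        lo, hi = self.ci
        if not lo <= self.point <= hi:
            raise ModelInputError(f"{self.food_group}: CI must bracket the point elasticity")


MEAT_ELASTICITY = Elasticity("meat", -0.60, (-0.66, -0.54))
FV_ELASTICITY = Elasticity("fruit_vegetables", -0.53, (-0.59, -0.48))


def default_elasticities(bound: str | None = None) -> dict[str, float]:
    """Elasticity per food group; ``bound`` picks a CI endpoint.

    ``bound='high'`` is the larger-magnitude (more negative) endpoint,
    ``bound='low'`` the smaller-magnitude one, ``None`` the point estimate.
    """
    def pick(e: Elasticity) -> float:
        if bound is None:
            return e.point
        if bound == "high":
            return e.ci[0]
        if bound == "low":
            return e.ci[1]
        raise ModelInputError(f"unknown elasticity bound {bound!r}")

    meat = pick(MEAT_ELASTICITY)
    return {
        "red_meat": meat,
        "processed_meat": meat,
        "poultry": meat,
        "fruit_vegetables": pick(FV_ELASTICITY),
    }


@dataclass(frozen=True)
class Scenario:
    """A pricing policy: signed price change per food group."""

    name: str
    price_change: dict = field(default_factory=dict)
    start_year: int = 2018
    horizon_years: int = 30

    def __post_init__(self):
        if self.horizon_years < 1:
            raise ModelInputError("horizon_years must be >= 1")
        if any(dp <= -1 for dp in self.price_change.values()):
            raise ModelInputError("price_change must be > -1")


REFERENCE = Scenario("reference", {})
MEAT15 = Scenario("meat15", {g: 0.15 for g in MEAT_GROUPS})
MEAT30 = Scenario("meat30", {g: 0.30 for g in MEAT_GROUPS})
FV10 = Scenario("fv10", {"fruit_vegetables": -0.10})
SCENARIOS = {s.name: s for s in (REFERENCE, MEAT15, MEAT30, FV10)}


def apply_elasticity(
    q0: float | np.ndarray,
    price_change: float,
    elasticity: float,
    form: str = "iso_elastic",
) -> float | np.ndarray:
    """Quantity after a price change.

    iso_elastic: ``q0 * (1 + dp)**eps``; linear: ``q0 * (1 + eps * dp)``,
    floored at zero.  ``price_change`` must exceed −1 (a 100% price cut is
    outside the demand model's domain).
    """
    if price_change <= -1:
        raise ModelInputError("price_change must be > -1")
    if form == "iso_elastic":
        out = q0 * (1.0 + price_change) ** elasticity
    elif form == "linear":
        out = q0 * np.maximum(0.0, 1.0 + elasticity * price_change)
    else:
        raise ModelInputError(f"unknown elasticity form {form!r}")
    return out


@dataclass
class ConsumptionTrajectory:
    """Projected intake and national consumption per year under one scenario."""

    scenario: Scenario
    years: np.ndarray                # calendar years, base..base+horizon
    population: np.ndarray           # (n_years, 101, 2)
    newborns_per_year: float
    intake: dict                     # food group -> (n_years, 101, 2) g/day
    national_kg: pd.DataFrame        # index year, columns food groups, kg/year

    def population_mean(self, groups, year: int) -> float:
        """Population-weighted mean intake (g/day) of one or more food groups."""
        if isinstance(groups, str):
            groups = (groups,)
        t = int(np.flatnonzero(self.years == year)[0])
        pop = self.population[t]
        total = sum(self.intake[g][t] for g in groups)
        return float((total * pop).sum() / pop.sum())

    def meat_mean(self, year: int) -> float:
        return self.population_mean(MEAT_GROUPS, year)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: year, age, sex, food_group, g_per_day, national kg."""
        recs = []
        for t, year in enumerate(self.years):
            for g in self.intake:
                arr = self.intake[g][t]
                kg = float(self.national_kg.loc[year, g])
                for si, sex in enumerate(SEXES):
                    recs.append(
                        pd.DataFrame(
                            {
                                "year": int(year),
                                "age": AGES,
                                "sex": sex,
                                "food_group": g,
                                "g_per_day": arr[:, si],
                                "national_kg": kg,
                            }
                        )
                    )
        return pd.concat(recs, ignore_index=True)


def project_pyramid(bundle: SyntheticBundle, n_years: int) -> np.ndarray:
    """Population counts per year under the bundle's all-cause mortality.

    Annual cycle: survive, age by one year (100+ is a pooled closed bin),
    add newborns at age 0.  With the default stationary pyramid this returns
    the same age structure every year.
    """
    surv = np.exp(-bundle.total_mortality)
    sex_frac = np.array(
        [1.0 - bundle.config.male_birth_fraction, bundle.config.male_birth_fraction]
    )
    births = bundle.pyramid.newborns_per_year * sex_frac
    pop = np.empty((n_years + 1,) + bundle.pyramid.counts.shape)
    pop[0] = bundle.pyramid.counts
    n_ages = bundle.pyramid.counts.shape[0]
    for t in range(n_years):
        cur = pop[t] * surv
        nxt = np.empty_like(cur)
        nxt[0] = births
        nxt[1 : n_ages - 1] = cur[0 : n_ages - 2]
        nxt[n_ages - 1] = cur[n_ages - 2] + cur[n_ages - 1]
        pop[t + 1] = nxt
    return pop


def project(
    bundle: SyntheticBundle,
    scenario: Scenario,
    elasticities: dict[str, float] | None = None,
    form: str = "iso_elastic",
) -> ConsumptionTrajectory:
    """Project every food group over the horizon under one scenario.

    Reference cell means are held constant; priced groups are scaled by the
    elasticity response from the first post-base year onward.  National
    totals are recomputed each year against the evolving pyramid.
    """
    elas = elasticities if elasticities is not None else default_elasticities()
    for g in scenario.price_change:
        if g not in elas:
            raise ModelInputError(f"no elasticity for priced food group {g!r}")

    n = scenario.horizon_years
    years = scenario.start_year + np.arange(n + 1)
    pop = project_pyramid(bundle, n)

    intake = {}
    kg = {}
    for g in FOOD_GROUPS:
        base = bundle.profiles[g].mean_intake
        dp = scenario.price_change.get(g, 0.0)
        scaled = apply_elasticity(base, dp, elas.get(g, 0.0), form) if dp else base
        arr = np.empty((n + 1,) + base.shape)
        arr[0] = base
        arr[1:] = scaled  # full pass-through from year 1, constant thereafter
        intake[g] = arr
        kg[g] = (arr * pop).sum(axis=(1, 2)) * G_PER_DAY_TO_KG_PER_YEAR

    national = pd.DataFrame(kg, index=pd.Index(years, name="year"))
    return ConsumptionTrajectory(
        scenario=scenario,
        years=years,
        population=pop,
        newborns_per_year=bundle.pyramid.newborns_per_year,
        intake=intake,
        national_kg=national,
    )
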