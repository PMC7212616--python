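"""Monetization of policy effects: consumer surplus, fiscal flows, health costs.

All operations produce nominal (pre-discount) euro streams per calendar year,
tagged with the stakeholder they accrue to (consumers or government).
Monetary sign convention throughout: positive = benefit to the stakeholder.

Consumer surplus after a price change is approximated with the rule of half.
Two variants are provided: ``full_roh`` — the standard ½·Δp·(q0+q1), the
default — and ``as_printed`` — the triangle term ½·Δp·Δq (i.e. only the
deadweight portion), kept because some guideline texts write the formula that
way.  They coincide exactly when quantities do not respond (Δq = 0).

Policy revenue nets the tax take (or subsidy outlay) on the new quantity
against the VAT change on the quantity shifted; food prices follow a CPI
trend.  Productivity is valued per averted working-age prevalent case via
absenteeism/presenteeism costs plus the fiscal participation effect (income
tax and welfare payments); the friction-cost method keeps only a configured
fraction of the participation stream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ModelInputError

EFFECTS = (
    "healthcare_costs",
    "health_qaly",
    "productivity",
    "environment",
    "policy_revenue",
    "consumer_surplus",
    "policy_costs",
)
STAKEHOLDERS = ("consumers", "government")


def consumer_surplus(p0: float, p1: float, q0: float, q1: float, form: str = "full_roh") -> float:
    """Change in consumer surplus (EUR) for one good in one period.

    ``full_roh``: ½(p0−p1)(q0+q1); ``as_printed``: ½(p0−p1)(q0−q1).
    A price rise gives a negative value (consumer loss), a subsidy positive.
    """
    if q0 < 0 or q1 < 0:
        raise ModelInputError("quantities must be non-negative")
    if form == "full_roh":
        return 0.5 * (p0 - p1) * (q0 + q1)
    if form == "as_printed":
        return 0.5 * (p0 - p1) * (q0 - q1)
    raise ModelInputError(f"unknown consumer-surplus form {form!r}")


def _price_path(price0: float, cpi_rate: float, offsets: np.ndarray) -> np.ndarray:
    return price0 * (1.0 + cpi_rate) ** offsets


def consumer_surplus_series(scen_traj, ref_traj, economics, base_year: int, form: str = "full_roh") -> pd.Series:
    """Yearly consumer-surplus change summed over the priced food groups."""
    years = scen_traj.years
    out = pd.Series(0.0, index=pd.Index(years, name="year"))
    offsets = years - base_year
    for g, dp in scen_traj.scenario.price_change.items():
        p0 = _price_path(economics.price_per_kg[g], economics.cpi_rate, offsets)
        p1 = p0 * (1.0 + dp)
        q0 = ref_traj.national_kg[g].to_numpy()
        q1 = scen_traj.national_kg[g].to_numpy()
        cs = np.array(
            [consumer_surplus(a, b, c, d, form) for a, b, c, d in zip(p0, p1, q0, q1)]
        )
        cs[offsets <= 0] = 0.0  # policy starts after the base year
        out += pd.Series(cs, index=out.index)
    return out


def policy_revenue_series(scen_traj, ref_traj, economics, base_year: int) -> pd.Series:
    """Yearly government revenue: tax/subsidy take net of the VAT shift.

    For every priced group: ``dp·p_t·q1_t − vat·p_t·(q0_t − q1_t)`` with
    ``p_t = p_0·(1+cpi)^t``.  The formula covers taxes (dp>0, positive
    revenue) and subsidies (dp<0, negative revenue) alike.
    """
    if any(p <= 0 for p in economics.price_per_kg.values()):
        raise ModelInputError("prices must be positive")
    years = scen_traj.years
    offsets = years - base_year
    out = pd.Series(0.0, index=pd.Index(years, name="year"))
    for g, dp in scen_traj.scenario.price_change.items():
        p_t = _price_path(economics.price_per_kg[g], economics.cpi_rate, offsets)
        q0 = ref_traj.national_kg[g].to_numpy()
        q1 = scen_traj.national_kg[g].to_numpy()
        rev = dp * p_t * q1 - economics.vat_rate_food * p_t * (q0 - q1)
        rev[offsets <= 0] = 0.0
        out += pd.Series(rev, index=out.index)
    return out


def healthcare_savings(health_delta, cost_per_case: dict) -> pd.Series:
    """Yearly healthcare savings: averted prevalent cases x cost per case-year.

    Positive when cases are averted; a disease whose case count rises under
    the policy (the compensatory pattern) contributes negatively.
    """
    if any(v < 0 for v in cost_per_case.values()):
        raise ModelInputError("healthcare costs must be >= 0")
    out = pd.Series(0.0, index=health_delta.averted_cases.index)
    for d in health_delta.averted_cases.columns:
        if d not in cost_per_case:
            raise ModelInputError(f"no healthcare cost for disease {d!r}")
        out += health_delta.averted_cases[d] * cost_per_case[d]
    return out


def qaly_benefit(health_delta, qaly_value: float) -> pd.Series:
    """Yearly QALY gain valued at a constant euro rate (accrues to consumers)."""
    return pd.Series(
        health_delta.qaly_gain * qaly_value, index=health_delta.averted_cases.index
    )


def productivity_series(health_delta, economics, method: str = "human_capital") -> pd.Series:
    """Yearly productivity effect from averted working-age prevalent cases.

    absenteeism/presenteeism stream + participation (fiscal) stream; under
    the friction-cost method the participation stream is multiplied by the
    configured friction fraction.  ``friction_fraction = 1`` reproduces the
    human-capital value exactly.
    """
    if method not in ("human_capital", "friction"):
        raise ModelInputError(f"unknown productivity method {method!r}")
    fric = economics.friction_fraction if method == "friction" else 1.0
    out = pd.Series(0.0, index=health_delta.averted_working.index)
    for d in health_delta.averted_working.columns:
        ap = economics.absenteeism_presenteeism_cost.get(d)
        part = economics.participation_fiscal_effect.get(d)
        if ap is None or part is None:
            raise ModelInputError(f"no productivity costs for disease {d!r}")
        out += health_delta.averted_working[d] * (ap + fric * part)
    return out


def split_productivity(series: pd.Series, consumer_share: float) -> dict[str, pd.Series]:
    """Split the productivity stream between consumers and government."""
    if not 0 <= consumer_share <= 1:
        raise ModelInputError("consumer share must lie in [0, 1]")
    return {
        "consumers": series * consumer_share,
        "government": series * (1.0 - consumer_share),
    }


def cashflow_frame(streams: dict[tuple[str, str], pd.Series]) -> pd.DataFrame:
    """Assemble named (effect, stakeholder) series into one long cash-flow table."""
    recs = []
    for (effect, stakeholder), s in streams.items():
        if effect not in EFFECTS or stakeholder not in STAKEHOLDERS:
            raise ModelInputError(f"unknown effect/stakeholder {(effect, stakeholder)}")
        recs.append(
            pd.DataFrame(
                {
                    "year": s.index.to_numpy(),
                    "effect": effect,
                    "stakeholder": stakeholder,
                    "eur_nominal": s.to_numpy(),
                }
            )
        )
    return pd.concat(recs, ignore_index=True)
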