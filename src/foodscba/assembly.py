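"""Discounted welfare ledgers, the end-to-end pipeline, and sensitivity runs.

The ledger collects every monetized effect — healthcare costs, health
outcomes (QALYs), productivity, environment, policy revenue, consumer
surplus and policy costs — discounts it to base-year euros over the 30-year
horizon, and stratifies it by stakeholder (consumers vs government).
Monte-Carlo uncertainty propagates only through the RR-dependent rows
(health outcomes, healthcare costs, productivity); environment, revenue and
consumer surplus are deterministic given the elasticities.

One-way sensitivity axes: elasticity CI bounds, discount rate (1.5%/4%),
environmental cost/efficiency pairings (HEC-LEG: high unit costs with low
efficiency gains; LEC-HEG: the reverse at 1.75%/yr), friction-cost vs
human-capital productivity, the perfect-information assumption (QALY rows
excluded from welfare), and the QALY value itself.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import economics as econ_ops
from .config import AnalysisConfig, config_hash, config_to_yaml
from .consumption import (
    SCENARIOS,
    ConsumptionTrajectory,
    Scenario,
    default_elasticities,
    project,
)
from .environment import EfficiencyTrajectory, ImpactVector, UnitCosts, impact_series, monetize
from .errors import ModelInputError
from .health import HealthDelta, MonteCarloResult, delta, monte_carlo, simulate
from .synthetic import SyntheticBundle, generate_all

logger = logging.getLogger("foodscba")

__version__ = "0.1.0"


def discount(amount, year_offset, rate: float):
    """Present value of ``amount`` received ``year_offset`` years after base.

    Scalar or vectorized: ``amount / (1 + rate)**year_offset``.
    """
    if rate < 0:
        raise ModelInputError("discount rate must be >= 0")
    off = np.asarray(year_offset)
    if np.any(off < 0):
        raise ModelInputError("year_offset must be >= 0")
    out = np.asarray(amount) / (1.0 + rate) ** off
    return float(out) if np.isscalar(amount) or np.ndim(amount) == 0 else out


# ---------------------------------------------------------------------------
# ledger


@dataclass
class SCBALedger:
    """Discounted 30-year welfare ledger in million base-year euros."""

    scenario: str
    table: pd.DataFrame       # effect, stakeholder, value_meur, ci_low, ci_high
    totals: pd.DataFrame      # stakeholder (+society), qaly_variant, value, ci
    qaly_values: tuple[float, float]

    def societal_total(self, variant: str = "low") -> float:
        row = self.totals[
            (self.totals.stakeholder == "society") & (self.totals.qaly_variant == variant)
        ]
        return float(row["value_meur"].iloc[0])

    def stakeholder_total(self, stakeholder: str, variant: str = "low") -> float:
        row = self.totals[
            (self.totals.stakeholder == stakeholder) & (self.totals.qaly_variant == variant)
        ]
        return float(row["value_meur"].iloc[0])


def assemble(
    cashflows: pd.DataFrame,
    cfg: AnalysisConfig,
    mc: MonteCarloResult | None = None,
    economics=None,
    scenario_name: str = "",
) -> SCBALedger:
    """Discount and aggregate nominal cash flows into the ledger.

    ``cashflows`` is the long table (year, effect, stakeholder, eur_nominal).
    If a Monte-Carlo result and the economic inputs are supplied, 95%
    percentile bounds are attached to the RR-dependent rows and propagated
    into the stakeholder and societal totals; deterministic rows carry their
    point value as both bounds.
    """
    rate = cfg.discount_rate
    base = cfg.base_year

    point: dict[tuple[str, str], float] = {}
    for (effect, stakeholder), grp in cashflows.groupby(["effect", "stakeholder"]):
        off = grp["year"].to_numpy() - base
        point[(effect, stakeholder)] = float(np.sum(discount(grp["eur_nominal"].to_numpy(), off, rate)))

    iters: dict[tuple[str, str], np.ndarray] = {}
    if mc is not None and economics is not None:
        w = (1.0 + rate) ** -(mc.point.years - base)
        hc_cost = np.array([economics.healthcare_cost_per_case[d] for d in mc.diseases])
        fric = economics.friction_fraction if cfg.productivity_method == "friction" else 1.0
        prod_cost = np.array(
            [
                economics.absenteeism_presenteeism_cost[d]
                + fric * economics.participation_fiscal_effect[d]
                for d in mc.diseases
            ]
        )
        iters[("healthcare_costs", "government")] = (mc.averted * hc_cost).sum(axis=2) @ w
        prod_i = (mc.averted_working * prod_cost).sum(axis=2) @ w
        share = cfg.productivity_consumer_share
        iters[("productivity", "consumers")] = prod_i * share
        iters[("productivity", "government")] = prod_i * (1.0 - share)
        if not cfg.perfect_information:
            iters[("health_qaly", "consumers")] = (mc.qaly @ w) * cfg.qaly_value

    rows = []
    for effect in econ_ops.EFFECTS:
        for stakeholder in econ_ops.STAKEHOLDERS:
            key = (effect, stakeholder)
            if key not in point:
                continue
            v = point[key] / 1e6
            if key in iters:
                lo, hi = np.percentile(iters[key], [2.5, 97.5]) / 1e6
            else:
                lo = hi = v
            rows.append(
                {
                    "effect": effect,
                    "stakeholder": stakeholder,
                    "value_meur": v,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    table = pd.DataFrame(rows)

    qaly_ratio = cfg.qaly_value_high / cfg.qaly_value
    totals_rows = []
    for variant, ratio in (("low", 1.0), ("high", qaly_ratio)):
        for stakeholder in ("consumers", "government", "society"):
            keys = [
                k
                for k in point
                if stakeholder in ("society", k[1])
            ]
            def scale(k):
                return ratio if k[0] == "health_qaly" else 1.0

            v = sum(point[k] * scale(k) for k in keys)
            det = sum(point[k] * scale(k) for k in keys if k not in iters)
            if any(k in iters for k in keys):
                it = det + sum(iters[k] * scale(k) for k in keys if k in iters)
                lo, hi = np.percentile(it, [2.5, 97.5]) / 1e6
            else:
                lo = hi = v / 1e6
            totals_rows.append(
                {
                    "stakeholder": stakeholder,
                    "qaly_variant": variant,
                    "value_meur": v / 1e6,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    totals = pd.DataFrame(totals_rows)
    return SCBALedger(
        scenario=scenario_name,
        table=table,
        totals=totals,
        qaly_values=(cfg.qaly_value, cfg.qaly_value_high),
    )


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineResult:
    """Everything one end-to-end run produced."""

    scenario: Scenario
    seed: int
    config: AnalysisConfig
    bundle: SyntheticBundle
    ref_traj: ConsumptionTrajectory
    scen_traj: ConsumptionTrajectory
    health_delta: HealthDelta
    mc: MonteCarloResult | None
    impacts_ref: pd.DataFrame
    impacts_scen: pd.DataFrame
    cashflows: pd.DataFrame
    ledger: SCBALedger


def _resolve_scenario(scenario, cfg: AnalysisConfig) -> Scenario:
    if isinstance(scenario, str):
        if scenario not in SCENARIOS:
            raise ModelInputError(f"unknown scenario {scenario!r}")
        scenario = SCENARIOS[scenario]
    return Scenario(scenario.name, dict(scenario.price_change), cfg.base_year, cfg.horizon_years)


def run_pipeline(
    scenario="meat15",
    seed: int = 0,
    config: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
    elasticity_bound: str | None = None,
) -> PipelineResult:
    """Run the full SCBA for one scenario: inputs to discounted ledger.

    Deterministic for a fixed (scenario, seed, config).  ``elasticity_bound``
    selects a CI endpoint for the sensitivity analysis (None = point).
    """
    cfg = config or AnalysisConfig()
    cfg.validate()
    scen = _resolve_scenario(scenario, cfg)
    is_reference = not scen.price_change

    logger.info("stage=generate seed=%d", seed)
    bundle = generate_all(seed, cfg.generation)

    logger.info("stage=project scenario=%s form=%s", scen.name, cfg.elasticity_form)
    elas = default_elasticities(elasticity_bound)
    reference = Scenario("reference", {}, cfg.base_year, cfg.horizon_years)
    ref_traj = project(bundle, reference, elas, cfg.elasticity_form)
    scen_traj = ref_traj if is_reference else project(bundle, scen, elas, cfg.elasticity_form)

    logger.info("stage=health n_iter=%d", cfg.n_iter)
    ref_state = simulate(ref_traj, ref_traj, bundle)
    scen_state = ref_state if is_reference else simulate(scen_traj, ref_traj, bundle)
    hdelta = delta(scen_state, ref_state, cfg.working_age)
    mc = None
    if not is_reference and cfg.n_iter >= 2:
        mc = monte_carlo(scen_traj, ref_traj, bundle, cfg.n_iter, seed, cfg.working_age)

    logger.info("stage=environment gain=%.4f", cfg.efficiency_gain)
    eff = EfficiencyTrajectory(cfg.base_year, cfg.efficiency_gain)
    impacts_ref = impact_series(ref_traj.national_kg, bundle.footprints, eff)
    impacts_scen = (
        impacts_ref if is_reference else impact_series(scen_traj.national_kg, bundle.footprints, eff)
    )
    unit_costs = UnitCosts().scaled(cfg.unit_cost_factor)
    env_benefit = pd.Series(
        [
            monetize(
                ImpactVector(impacts_ref.loc[y].to_numpy() - impacts_scen.loc[y].to_numpy()),
                unit_costs,
            )
            for y in impacts_ref.index
        ],
        index=impacts_ref.index,
    )

    logger.info("stage=economics method=%s", cfg.productivity_method)
    econ = bundle.economics
    streams = {}
    streams[("consumer_surplus", "consumers")] = econ_ops.consumer_surplus_series(
        scen_traj, ref_traj, econ, cfg.base_year
    )
    streams[("policy_revenue", "government")] = econ_ops.policy_revenue_series(
        scen_traj, ref_traj, econ, cfg.base_year
    )
    streams[("environment", "government")] = env_benefit
    streams[("healthcare_costs", "government")] = econ_ops.healthcare_savings(
        hdelta, econ.healthcare_cost_per_case
    )
    if not cfg.perfect_information:
        streams[("health_qaly", "consumers")] = econ_ops.qaly_benefit(hdelta, cfg.qaly_value)
    prod = econ_ops.productivity_series(hdelta, econ, cfg.productivity_method)
    for stakeholder, s in econ_ops.split_productivity(prod, cfg.productivity_consumer_share).items():
        streams[("productivity", stakeholder)] = s
    policy_costs = pd.Series(0.0, index=pd.Index(scen_traj.years, name="year"))
    if not is_reference:
        policy_costs.loc[cfg.base_year] = -econ.implementation_cost
    streams[("policy_costs", "government")] = policy_costs

    cashflows = econ_ops.cashflow_frame(streams)
    ledger = assemble(cashflows, cfg, mc, econ, scenario_name=scen.name)

    result = PipelineResult(
        scenario=scen,
        seed=seed,
        config=cfg,
        bundle=bundle,
        ref_traj=ref_traj,
        scen_traj=scen_traj,
        health_delta=hdelta,
        mc=mc,
        impacts_ref=impacts_ref,
        impacts_scen=impacts_scen,
        cashflows=cashflows,
        ledger=ledger,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    """Write all CSV artefacts plus a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.scen_traj.national_kg.to_csv(out / "trajectory.csv")
    hd = result.health_delta
    hd_frame = hd.averted_cases.copy()
    hd_frame["qaly_gain"] = hd.qaly_gain
    hd_frame.to_csv(out / "health_delta.csv")
    if result.mc is not None:
        result.mc.summary().to_csv(out / "health_delta_ci.csv", index=False)
    imp = pd.concat(
        {"reference": result.impacts_ref, result.scenario.name: result.impacts_scen},
        names=["scenario"],
    )
    imp.to_csv(out / "impact.csv")
    result.cashflows.to_csv(out / "cashflows.csv", index=False)
    result.ledger.table.to_csv(out / "ledger.csv", index=False)
    result.ledger.totals.to_csv(out / "ledger_by_stakeholder.csv", index=False)
    manifest = {
        "scenario": result.scenario.name,
        "seed": result.seed,
        "config_hash": config_hash(result.config),
        "package_version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    config_to_yaml(result.config, out / "config.yaml")


# ---------------------------------------------------------------------------
# sensitivity analysis


@dataclass(frozen=True)
class SensitivitySpec:
    """One-way variation of a single analysis axis."""

    axis: str
    setting: object

    AXES = (
        "discount_rate",
        "elasticity_bound",
        "environment_scenario",
        "productivity_method",
        "information_assumption",
        "qaly_value",
    )


def default_sensitivity_specs() -> list[SensitivitySpec]:
    """The study's one-way sensitivity set."""
    return [
        SensitivitySpec("elasticity_bound", "high"),
        SensitivitySpec("elasticity_bound", "low"),
        SensitivitySpec("discount_rate", 0.015),
        SensitivitySpec("discount_rate", 0.04),
        SensitivitySpec("environment_scenario", "HEC-LEG"),
        SensitivitySpec("environment_scenario", "LEC-HEG"),
        SensitivitySpec("productivity_method", "friction"),
        SensitivitySpec("information_assumption", "perfect"),
        SensitivitySpec("qaly_value", 100_000.0),
    ]


def _apply_spec(cfg: AnalysisConfig, spec: SensitivitySpec) -> tuple[AnalysisConfig, str | None]:
    cfg2 = dataclasses.replace(cfg)
    bound = None
    if spec.axis == "discount_rate":
        cfg2.discount_rate = float(spec.setting)
    elif spec.axis == "elasticity_bound":
        if spec.setting not in (None, "low", "high"):
            raise ModelInputError(f"unknown elasticity bound {spec.setting!r}")
        bound = spec.setting
    elif spec.axis == "environment_scenario":
        if spec.setting == "HEC-LEG":
            cfg2.unit_cost_factor = cfg.unit_cost_factor_high
            cfg2.efficiency_gain = cfg.efficiency_gain_low
        elif spec.setting == "LEC-HEG":
            cfg2.unit_cost_factor = cfg.unit_cost_factor_low
            cfg2.efficiency_gain = cfg.efficiency_gain_high
        elif spec.setting is not None and spec.setting != "central":
            raise ModelInputError(f"unknown environment scenario {spec.setting!r}")
    elif spec.axis == "productivity_method":
        cfg2.productivity_method = str(spec.setting)
    elif spec.axis == "information_assumption":
        cfg2.perfect_information = spec.setting == "perfect"
    elif spec.axis == "qaly_value":
        cfg2.qaly_value = float(spec.setting)
    else:
        raise ModelInputError(f"unknown sensitivity axis {spec.axis!r}")
    return cfg2, bound


def run_sensitivity(
    scenario="meat15",
    seed: int = 0,
    config: AnalysisConfig | None = None,
    specs: list[SensitivitySpec] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Rerun the pipeline once per one-way variant.

    Returns a tornado-style summary table (societal totals with bounds per
    variant, including the base run) and the full ledger per variant.  A
    variant whose setting equals the base configuration reproduces the base
    ledger exactly.
    """
    cfg = config or AnalysisConfig()
    specs = specs if specs is not None else default_sensitivity_specs()
    ledgers = {}
    rows = []

    base = run_pipeline(scenario, seed, cfg)
    ledgers["base"] = base.ledger
    rows.append(_summary_row("base", "-", "-", base.ledger))

    for spec in specs:
        cfg2, bound = _apply_spec(cfg, spec)
        cfg2.validate()
        name = f"{spec.axis}={spec.setting}"
        logger.info("stage=sensitivity variant=%s", name)
        res = run_pipeline(scenario, seed, cfg2, elasticity_bound=bound)
        ledgers[name] = res.ledger
        rows.append(_summary_row(name, spec.axis, spec.setting, res.ledger))
    return pd.DataFrame(rows), ledgers


def _summary_row(name, axis, setting, ledger: SCBALedger) -> dict:
    soc = ledger.totals[(ledger.totals.stakeholder == "society") & (ledger.totals.qaly_variant == "low")]
    return {
        "variant": name,
        "axis": axis,
        "setting": str(setting),
        "societal_total_meur": float(soc["value_meur"].iloc[0]),
        "ci_low": float(soc["ci_low"].iloc[0]),
        "ci_high": float(soc["ci_high"].iloc[0]),
    }
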