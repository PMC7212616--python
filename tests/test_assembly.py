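"""Discounting, ledger assembly, end-to-end pipeline and sensitivity runs."""

import json

import numpy as np
import pytest
from click.testing import CliRunner
from hypothesis import given, settings
from hypothesis import strategies as st

import foodscba as f
from foodscba.cli import main as cli_main
from foodscba.errors import ModelInputError


class TestDiscount:
    def test_zero_offset_unchanged(self):
        assert f.discount(123.4, 0, 0.03) == 123.4

    def test_hundred_euros_ten_years(self):
        assert f.discount(100.0, 10, 0.03) == pytest.approx(74.41, abs=0.005)

    def test_zero_rate_unchanged_at_any_offset(self):
        assert f.discount(55.0, 17, 0.0) == 55.0

    def test_negative_offset_rejected(self):
        with pytest.raises(ModelInputError):
            f.discount(1.0, -1, 0.03)

    @settings(deadline=None, max_examples=50)
    @given(
        a=st.floats(-1e6, 1e6), b=st.floats(-1e6, 1e6),
        off=st.integers(0, 50), rate=st.floats(0.0, 0.2),
    )
    def test_additivity(self, a, b, off, rate):
        assert f.discount(a + b, off, rate) == pytest.approx(
            f.discount(a, off, rate) + f.discount(b, off, rate), rel=1e-9, abs=1e-6
        )


class TestLedger:
    def test_reference_ledger_is_all_zero(self):
        res = f.run_pipeline("reference", seed=11, config=f.AnalysisConfig(n_iter=0))
        assert np.allclose(res.ledger.table["value_meur"], 0.0)
        assert np.allclose(res.ledger.totals["value_meur"], 0.0)

    def test_accounting_identity(self, m15_result):
        led = m15_result.ledger
        for variant in ("low", "high"):
            ratio = 1.0 if variant == "low" else led.qaly_values[1] / led.qaly_values[0]
            vals = led.table.apply(
                lambda r: r.value_meur * (ratio if r.effect == "health_qaly" else 1.0), axis=1
            )
            society = led.societal_total(variant)
            assert vals.sum() == pytest.approx(society, rel=1e-9)
            assert led.stakeholder_total("consumers", variant) + led.stakeholder_total(
                "government", variant
            ) == pytest.approx(society, rel=1e-9)

    def test_tax_stratification_signs(self, m15_result):
        led = m15_result.ledger
        assert led.stakeholder_total("consumers") < 0
        assert led.stakeholder_total("government") > 0
        assert led.societal_total() > 0  # net welfare gain at the low QALY value

    def test_subsidy_stratification_signs(self, fv10_result):
        led = fv10_result.ledger
        assert led.stakeholder_total("consumers") > 0
        assert led.stakeholder_total("government") < 0

    def test_mc_bounds_only_on_rr_dependent_rows(self, m15_result):
        t = m15_result.ledger.table.set_index(["effect", "stakeholder"])
        for key in [("environment", "government"), ("policy_revenue", "government"),
                    ("consumer_surplus", "consumers"), ("policy_costs", "government")]:
            row = t.loc[key]
            assert row.ci_low == row.value_meur == row.ci_high
        for key in [("healthcare_costs", "government"), ("health_qaly", "consumers")]:
            row = t.loc[key]
            assert row.ci_low < row.ci_high

    def test_policy_cost_booked_once_undiscounted(self, m15_result):
        t = m15_result.ledger.table
        row = t[(t.effect == "policy_costs")]
        assert float(row["value_meur"].iloc[0]) == pytest.approx(-20.0)


class TestPipeline:
    def test_same_seed_reproduces_ledger_bit_for_bit(self):
        cfg = f.AnalysisConfig(n_iter=10)
        a = f.run_pipeline("meat15", seed=5, config=cfg)
        b = f.run_pipeline("meat15", seed=5, config=cfg)
        assert np.array_equal(a.ledger.table["value_meur"], b.ledger.table["value_meur"])
        assert np.array_equal(a.ledger.totals.to_numpy(), b.ledger.totals.to_numpy())

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ModelInputError):
            f.run_pipeline("meat50", seed=1)

    def test_outputs_written_with_manifest(self, tmp_path):
        res = f.run_pipeline("meat15", seed=1, config=f.AnalysisConfig(n_iter=2), out_dir=tmp_path)
        for name in (
            "trajectory.csv", "health_delta.csv", "impact.csv", "cashflows.csv",
            "ledger.csv", "ledger_by_stakeholder.csv", "manifest.json", "config.yaml",
        ):
            assert (tmp_path / name).exists()
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["scenario"] == "meat15" and manifest["seed"] == 1
        cfg = f.config_from_yaml(tmp_path / "config.yaml")
        assert cfg == res.config

    def test_perfect_information_drops_qaly_and_lowers_total(self, m15_result):
        cfg = f.AnalysisConfig(n_iter=30, perfect_information=True)
        res = f.run_pipeline("meat15", seed=11, config=cfg)
        assert "health_qaly" not in set(res.ledger.table["effect"])
        assert res.ledger.societal_total() < m15_result.ledger.societal_total()

    def test_lower_discount_rate_raises_stream_magnitudes(self):
        lo = f.run_pipeline("meat15", seed=11, config=f.AnalysisConfig(n_iter=0, discount_rate=0.015))
        hi = f.run_pipeline("meat15", seed=11, config=f.AnalysisConfig(n_iter=0, discount_rate=0.04))
        a = lo.ledger.table.set_index(["effect", "stakeholder"])["value_meur"]
        b = hi.ledger.table.set_index(["effect", "stakeholder"])["value_meur"]
        for key in a.index:
            if key == ("policy_costs", "government"):  # undiscounted one-off
                assert a[key] == b[key]
            else:
                assert abs(a[key]) >= abs(b[key])


class TestSensitivity:
    def test_base_setting_is_bitwise_noop(self):
        cfg = f.AnalysisConfig(n_iter=5)
        summary, ledgers = f.run_sensitivity(
            "meat15", seed=2, config=cfg,
            specs=[f.SensitivitySpec("discount_rate", 0.03)],
        )
        base, var = ledgers["base"], ledgers["discount_rate=0.03"]
        assert np.array_equal(base.table.to_numpy(), var.table.to_numpy())
        assert np.array_equal(base.totals.to_numpy(), var.totals.to_numpy())

    def test_stronger_elasticity_raises_environment_benefit(self):
        cfg = f.AnalysisConfig(n_iter=0)
        rows = {}
        for bound in ("low", None, "high"):
            res = f.run_pipeline("meat15", seed=2, config=cfg, elasticity_bound=bound)
            t = res.ledger.table
            rows[bound] = float(t.loc[t.effect == "environment", "value_meur"].iloc[0])
        assert rows["low"] < rows[None] < rows["high"]

    def test_environment_axis_settings(self):
        cfg = f.AnalysisConfig(n_iter=0)
        summary, ledgers = f.run_sensitivity(
            "meat15", seed=2, config=cfg,
            specs=[
                f.SensitivitySpec("environment_scenario", "HEC-LEG"),
                f.SensitivitySpec("environment_scenario", "LEC-HEG"),
            ],
        )
        env = {
            k: float(l.table.loc[l.table.effect == "environment", "value_meur"].iloc[0])
            for k, l in ledgers.items()
        }
        assert env["environment_scenario=HEC-LEG"] > env["base"] > env["environment_scenario=LEC-HEG"]

    def test_unknown_axis_rejected(self):
        with pytest.raises(ModelInputError):
            f.run_sensitivity(
                "meat15", seed=2, config=f.AnalysisConfig(n_iter=0),
                specs=[f.SensitivitySpec("vat_rate", 0.21)],
            )

    def test_friction_variant_not_larger_than_base(self):
        cfg = f.AnalysisConfig(n_iter=0)
        _, ledgers = f.run_sensitivity(
            "meat15", seed=2, config=cfg,
            specs=[f.SensitivitySpec("productivity_method", "friction")],
        )
        base = ledgers["base"].societal_total()
        fric = ledgers["productivity_method=friction"].societal_total()
        assert fric < base


class TestCLI:
    def test_run_command_writes_outputs(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "run"
        # tiny config keeps the CLI smoke test fast
        cfg_path = tmp_path / "cfg.yaml"
        f.config_to_yaml(f.AnalysisConfig(n_iter=2), cfg_path)
        result = runner.invoke(
            cli_main,
            ["run", "--scenario", "meat15", "--seed", "1", "--out", str(out),
             "--config", str(cfg_path)],
        )
        assert result.exit_code == 0, result.output
        assert "societal total" in result.output
        assert (out / "ledger.csv").exists()

    def test_generate_command(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["generate", "--seed", "1", "--out", str(tmp_path / "b")])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "b" / "population.csv").exists()
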