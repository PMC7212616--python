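"""Multistate health engine: categories, incidence scaling, dynamics, Monte Carlo."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

import foodscba as f
from foodscba.errors import GridMismatchError, ModelInputError

from conftest import make_toy_bundle


class TestCategorize:
    def test_point_mass_lands_in_its_interval(self):
        assert np.allclose(f.categorize(10.0, np.inf, (50, 100)), [1, 0, 0])
        assert np.allclose(f.categorize(75.0, np.inf, (50, 100)), [0, 1, 0])
        assert np.allclose(f.categorize(120.0, np.inf, (50, 100)), [0, 0, 1])

    def test_gamma_proportions_match_quadrature(self):
        mean, shape = 100.0, 4.0
        scale = mean / shape
        got = f.categorize(mean, shape, (50.0, 100.0))
        pdf = lambda x: gamma_dist.pdf(x, a=shape, scale=scale)
        expected = [
            quad(pdf, 0, 50)[0],
            quad(pdf, 50, 100)[0],
            quad(pdf, 100, np.inf)[0],
        ]
        assert np.allclose(got, expected, atol=1e-8)
        assert got.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_mean_is_point_mass_at_zero(self):
        assert np.allclose(f.categorize(0.0, 4.0, (50.0,)), [1, 0])

    def test_vectorized_over_cells(self):
        means = np.array([[10.0, 75.0], [120.0, 60.0]])
        out = f.categorize(means, np.inf, (50, 100))
        assert out.shape == (2, 2, 3)
        assert np.allclose(out.sum(axis=-1), 1.0)

    def test_non_monotone_boundaries_rejected(self):
        with pytest.raises(ModelInputError):
            f.categorize(100.0, 4.0, (100.0, 50.0))


class TestTransitions:
    def test_identical_distributions_give_zero_flow(self):
        assert np.allclose(f.estimate_transitions([0.2, 0.3, 0.5], [0.2, 0.3, 0.5]), 0.0)

    def test_cumulative_difference_solution(self):
        flows = f.estimate_transitions([0.5, 0.5, 0.0], [0.3, 0.6, 0.1])
        assert np.allclose(flows, [0.2, 0.1])

    def test_not_a_distribution_rejected(self):
        with pytest.raises(ModelInputError):
            f.estimate_transitions([0.5, 0.2], [0.5, 0.5])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.01, 1.0), min_size=3, max_size=6), st.data())
    def test_flows_conserve_mass(self, raw0, data):
        p0 = np.array(raw0) / np.sum(raw0)
        raw1 = data.draw(st.lists(st.floats(0.01, 1.0), min_size=len(raw0), max_size=len(raw0)))
        p1 = np.array(raw1) / np.sum(raw1)
        flows = f.estimate_transitions(p0, p1)
        padded = np.concatenate([[0.0], flows, [0.0]])
        recon = p0 - padded[1:] + padded[:-1]  # inflow - outflow per category
        assert np.allclose(recon, p1, atol=1e-9)


class TestScaledIncidence:
    def test_all_rr_one_leaves_incidence_unchanged(self):
        out = f.scaled_incidence(0.01, [0.5, 0.5], [0.9, 0.1], [1.0, 1.0])
        assert out == pytest.approx(0.01, rel=1e-12)

    def test_hand_computed_shift(self):
        out = f.scaled_incidence(1.0, [0.5, 0.5], [1.0, 0.0], [1.0, 2.0])
        assert out == pytest.approx(1.0 / 1.5, rel=1e-12)

    def test_identity_when_distributions_match(self):
        p = [0.3, 0.7]
        assert f.scaled_incidence(0.02, p, p, [1.0, 1.7]) == pytest.approx(0.02, rel=1e-15)

    def test_empty_reference_rejected(self):
        with pytest.raises(ModelInputError):
            f.scaled_incidence(0.01, [0.0, 0.0], [1.0, 0.0], [1.0, 2.0])


def _toy_runs(horizon=5, **kwargs):
    """Toy scenario/reference pair with a point-mass intake distribution.

    The reference meat exposure (80 g/day) sits above the single 75 g/day
    boundary; the 15% tax moves it to ~73.6, into the low-RR category, so
    the scenario incidence factor is exactly RR1/RR2 from year 1 onward.
    """
    bundle = make_toy_bundle(gamma_shape=np.inf, boundaries=(75.0,), rr=(1.0, 2.0), **kwargs)
    ref = f.project(bundle, f.Scenario("reference", {}, 2018, horizon))
    scen = f.project(bundle, f.Scenario("meat15", {g: 0.15 for g in f.MEAT_GROUPS}, 2018, horizon))
    return bundle, ref, scen


def _cohort_oracle(bundle, factor_from_year1, n_years):
    """Hand-rolled scalar-loop cohort iteration for the single-disease toy."""
    d = bundle.diseases["diabetes_type_2"]
    n_ages, n_sex = bundle.pyramid.counts.shape
    N = bundle.pyramid.counts.copy()
    prev = d.prevalence.copy()
    pops, prevs, qalys = [N.copy()], [prev.copy()], []
    qalys.append(float((N * (1 - prev * d.disability_weight)).sum()))
    births_each = bundle.pyramid.newborns_per_year / 2.0
    for t in range(n_years):
        factor = 1.0 if t == 0 else factor_from_year1
        newN = np.zeros_like(N)
        new_cases = np.zeros_like(N)
        surv_store = np.zeros_like(N)
        pnew_store = np.zeros_like(N)
        for a in range(n_ages):
            for s in range(n_sex):
                m_bg = bundle.background_mortality[a, s]
                em = d.excess_mortality[a, s]
                pi = prev[a, s]
                m_tot = m_bg + pi * em
                m_other = m_tot - pi * em
                a_prev = pi * np.exp(-(m_other + em))
                a_non = (1 - pi) * np.exp(-m_other)
                inc = d.incidence[a, s] * factor
                newly = a_non * (1 - np.exp(-inc))
                pnew = (a_prev + newly) / (a_prev + a_non)
                surv_store[a, s] = N[a, s] * np.exp(-m_tot)
                pnew_store[a, s] = pnew
        for s in range(n_sex):
            newN[0, s] = births_each
            new_cases[0, s] = births_each * d.prevalence[0, s]
            for a in range(1, n_ages - 1):
                newN[a, s] = surv_store[a - 1, s]
                new_cases[a, s] = surv_store[a - 1, s] * pnew_store[a - 1, s]
            newN[-1, s] = surv_store[-2, s] + surv_store[-1, s]
            new_cases[-1, s] = (
                surv_store[-2, s] * pnew_store[-2, s] + surv_store[-1, s] * pnew_store[-1, s]
            )
        N = newN
        prev = np.where(N > 0, new_cases / N, 0.0)
        pops.append(N.copy())
        prevs.append(prev.copy())
        qalys.append(float((N * (1 - prev * d.disability_weight)).sum()))
    return pops, prevs, qalys


class TestSimulate:
    def test_matches_hand_rolled_cohort_oracle(self):
        bundle, ref, scen = _toy_runs(horizon=4, newborns=20.0)
        state = f.simulate(scen, ref, bundle)
        pops, prevs, qalys = _cohort_oracle(bundle, factor_from_year1=0.5, n_years=4)
        for t in range(5):
            assert np.allclose(state.population[t], pops[t], rtol=1e-12)
            assert np.allclose(state.prevalence["diabetes_type_2"][t], prevs[t], rtol=1e-12)
            assert state.qalys[t] == pytest.approx(qalys[t], rel=1e-12)

    def test_disease_free_world_qalys_equal_person_years(self):
        bundle = make_toy_bundle(incidence=0.0, prevalence=0.0)
        ref = f.project(bundle, f.Scenario("reference", {}, 2018, 5))
        state = f.simulate(ref, ref, bundle)
        assert np.allclose(state.qalys, state.person_years, rtol=1e-12)

    def test_deterministic_rerun(self, bundle, ref_traj, m15_traj):
        a = f.simulate(m15_traj, ref_traj, bundle)
        b = f.simulate(m15_traj, ref_traj, bundle)
        assert np.array_equal(a.population, b.population)
        assert np.array_equal(a.qalys, b.qalys)

    def test_population_conservation_each_cycle(self, bundle, ref_traj):
        state = f.simulate(ref_traj, ref_traj, bundle)
        for t in range(len(state.years) - 1):
            expected = (
                state.population[t].sum()
                - state.deaths[t + 1]
                + bundle.pyramid.newborns_per_year
            )
            assert state.population[t + 1].sum() == pytest.approx(expected, rel=1e-12)

    def test_prevalence_bounded_and_qalys_below_person_years(self, bundle, ref_traj, m15_traj):
        state = f.simulate(m15_traj, ref_traj, bundle)
        for d, arr in state.prevalence.items():
            assert np.all((arr >= 0) & (arr <= 1))
        assert np.all(state.qalys <= state.person_years + 1e-9)

    def test_year_grid_mismatch_rejected(self, bundle, ref_traj):
        short = f.project(bundle, f.Scenario("reference", {}, 2018, 10))
        with pytest.raises(GridMismatchError):
            f.simulate(short, ref_traj, bundle)


class TestDelta:
    def test_reference_vs_itself_is_zero(self, bundle, ref_traj):
        state = f.simulate(ref_traj, ref_traj, bundle)
        d = f.delta(state, state)
        assert np.allclose(d.averted_cases.to_numpy(), 0.0)
        assert np.allclose(d.qaly_gain, 0.0)

    def test_all_rr_one_gives_zero_delta(self, bundle, ref_traj, m15_traj):
        # poultry-style behaviour: an exposure with RR 1 everywhere is inert
        neutral = copy.deepcopy(bundle)
        for r in neutral.rr_sets:
            r.rr_mean[:] = 1.0
            r.rr_ci[:] = 1.0
        scen = f.simulate(m15_traj, ref_traj, neutral)
        ref = f.simulate(ref_traj, ref_traj, neutral)
        d = f.delta(scen, ref)
        assert np.allclose(d.averted_cases.to_numpy(), 0.0, atol=1e-6)
        assert np.allclose(d.qaly_gain, 0.0, atol=1e-6)

    def test_tax_averts_diabetes_every_year(self, bundle, ref_traj, m15_traj):
        d = f.delta(
            f.simulate(m15_traj, ref_traj, bundle), f.simulate(ref_traj, ref_traj, bundle)
        )
        averted = d.averted_cases["diabetes_type_2"].to_numpy()
        assert np.all(averted[2:] > 0)

    def test_risk_free_disease_cases_rise_with_survival(self):
        # averting a lethal disease leaves more survivors to carry a second,
        # risk-free disease: its absolute case count must rise
        bundle = make_toy_bundle(
            gamma_shape=np.inf,
            boundaries=(75.0,),
            rr=(1.0, 3.0),
            excess_mortality=0.5,
            extra_disease={"excess_mortality": 0.0},
            newborns=20.0,
        )
        ref_t = f.project(bundle, f.Scenario("reference", {}, 2018, 10))
        scen_t = f.project(bundle, f.Scenario("meat15", {g: 0.15 for g in f.MEAT_GROUPS}, 2018, 10))
        d = f.delta(
            f.simulate(scen_t, ref_t, bundle), f.simulate(ref_t, ref_t, bundle)
        )
        assert d.averted_cases["diabetes_type_2"].iloc[-1] > 0
        assert d.averted_cases["coronary_heart_disease"].iloc[-1] < 0

    def test_default_run_shows_compensatory_chd_increase(self, m15_result):
        assert m15_result.health_delta.averted_cases["coronary_heart_disease"].iloc[-1] < 0

    def test_default_run_diabetes_ranks_first(self, m15_result):
        final = m15_result.health_delta.averted_cases.iloc[-1]
        assert final.idxmax() == "diabetes_type_2"


class TestMonteCarlo:
    def test_seeded_rerun_is_identical(self, bundle, ref_traj, m15_traj):
        a = f.monte_carlo(m15_traj, ref_traj, bundle, n_iter=10, seed=3)
        b = f.monte_carlo(m15_traj, ref_traj, bundle, n_iter=10, seed=3)
        assert np.array_equal(a.qaly, b.qaly)
        assert np.array_equal(a.averted, b.averted)

    def test_zero_width_ci_collapses_to_point_run(self, bundle, ref_traj, m15_traj):
        frozen = copy.deepcopy(bundle)
        for r in frozen.rr_sets:
            r.rr_ci[:, 0] = r.rr_mean
            r.rr_ci[:, 1] = r.rr_mean
        mc = f.monte_carlo(m15_traj, ref_traj, frozen, n_iter=5, seed=0)
        lo, hi = mc.ci_qaly()
        assert np.allclose(lo, mc.point.qaly_gain, atol=1e-9)
        assert np.allclose(hi, mc.point.qaly_gain, atol=1e-9)

    def test_too_few_iterations_rejected(self, bundle, ref_traj, m15_traj):
        with pytest.raises(ModelInputError):
            f.monte_carlo(m15_traj, ref_traj, bundle, n_iter=1, seed=0)

    def test_ci_covers_point_estimate_across_seeds(self, bundle):
        ref = f.project(bundle, f.Scenario("reference", {}, 2018, 10))
        scen = f.project(bundle, f.Scenario("meat15", {g: 0.15 for g in f.MEAT_GROUPS}, 2018, 10))
        covered = 0
        n_seeds = 10
        for s in range(n_seeds):
            mc = f.monte_carlo(scen, ref, bundle, n_iter=40, seed=s)
            lo, hi = mc.ci_qaly()
            if lo[-1] <= mc.point.qaly_gain[-1] <= hi[-1]:
                covered += 1
        assert covered / n_seeds >= 0.9
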