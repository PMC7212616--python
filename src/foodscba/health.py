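"""Dynamic multistate health-impact model.

A proportion-based (macro) implementation of a Markov-type state-transition
model: each (age, sex) cell carries a population count and, per disease, a
prevalence proportion.  Intake categories drive disease incidence through
relative risks; annual cycles over the life table produce disease cases,
deaths and quality-adjusted life years (QALYs), and comparing a policy
scenario against the reference yields averted cases and QALYs gained.
Parameter (relative-risk) uncertainty is propagated by Monte Carlo.

Cycle structure (1-year steps)
------------------------------
1. Intake category proportions per cell follow from the gamma within-cell
   intake distribution and the category boundaries.
2. Scenario incidence is baseline incidence scaled by the ratio of
   RR-weighted category prevalences, scenario vs reference (a potential-
   impact-fraction style rescaling); with identical distributions or all
   RR = 1 the factor is exactly 1.
3. Mortality: background rate plus, for prevalent cases, a disease-specific
   excess rate (additive on the rate scale); rates convert to probabilities
   as ``1 - exp(-rate)``.
4. Survivors age by one year (100+ pooled), newborns enter at age 0.
5. Cell utility is ``1 - sum(prevalence * disability weight)``, floored at 0;
   QALYs are population-weighted utility.

Poultry ("white meat") carries no relative risks, so a poultry-only price
change leaves health untouched.  Because averted disease lowers mortality,
an unassociated disease's absolute case count can *rise* under an effective
policy — longer-lived survivors acquire it — which is the expected
compensatory pattern, not an accounting error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .consumption import ConsumptionTrajectory
from .errors import GridMismatchError, ModelInputError
from .synthetic import SyntheticBundle

_TRUNC = 1e-6  # lower truncation of sampled relative risks


# ---------------------------------------------------------------------------
# category machinery


def categorize(mean, shape, boundaries) -> np.ndarray:
    """Proportions of a cell's population in each intake category.

    Within-cell intake is gamma distributed with the given mean and shape
    (variance = mean^2/shape); proportions are CDF increments over the
    category intervals.  ``shape=inf`` (or ``None``) degenerates to a point
    mass at the mean.  Returns an array of shape ``mean.shape + (K,)`` for K
    categories; proportions sum to 1.
    """
    b = np.asarray(boundaries, dtype=float)
    if b.ndim != 1 or b.size == 0 or np.any(np.diff(b) <= 0):
        raise ModelInputError("boundaries must be a non-empty strictly increasing sequence")
    mean = np.asarray(mean, dtype=float)
    if np.any(mean < 0):
        raise ModelInputError("intake mean must be non-negative")
    k = b.size + 1
    out = np.empty(mean.shape + (k,))
    if shape is None or np.isinf(shape):
        idx = np.searchsorted(b, mean, side="right")
        out[...] = 0.0
        np.put_along_axis(out, idx[..., None], 1.0, axis=-1)
        return out
    if shape <= 0:
        raise ModelInputError("gamma shape must be positive")
    scale = mean / shape
    with np.errstate(divide="ignore", invalid="ignore"):
        cdf = gamma_dist.cdf(b, a=shape, scale=scale[..., None])
    cdf = np.where(scale[..., None] > 0, cdf, (b >= 0).astype(float))  # zero mean: point mass at 0
    cdf_full = np.concatenate(
        [np.zeros(mean.shape + (1,)), cdf, np.ones(mean.shape + (1,))], axis=-1
    )
    out = np.diff(cdf_full, axis=-1)
    return out


def estimate_transitions(dist_t: np.ndarray, dist_t1: np.ndarray) -> np.ndarray:
    """Minimal net annual flows between adjacent categories.

    Returns ``flows`` of length K−1 where ``flows[c]`` is the net mass moving
    from category c to c+1 (negative = downward).  This is the unique
    adjacent-flow solution: ``flows[c] = cumsum(dist_t - dist_t1)[c]``, and it
    conserves total mass by construction.
    """
    p0 = np.asarray(dist_t, dtype=float)
    p1 = np.asarray(dist_t1, dtype=float)
    if p0.shape != p1.shape:
        raise GridMismatchError("distributions must share the category grid")
    for p in (p0, p1):
        if abs(p.sum() - 1.0) > 1e-8:
            raise ModelInputError("category distribution must sum to 1")
    return np.cumsum(p0 - p1)[:-1]


def scaled_incidence(baseline, p_ref, p_scen, rr) -> np.ndarray:
    """Incidence under a shifted category distribution.

    ``baseline * (p_scen @ rr) / (p_ref @ rr)`` — equals baseline when the
    scenario distribution matches the reference or all RRs are 1.
    """
    rr = np.asarray(rr, dtype=float)
    if np.any(rr <= 0):
        raise ModelInputError("relative risks must be > 0")
    p_ref = np.asarray(p_ref, dtype=float)
    p_scen = np.asarray(p_scen, dtype=float)
    if p_ref.shape[-1] != rr.size or p_scen.shape[-1] != rr.size:
        raise ModelInputError("category count mismatch between proportions and RRs")
    denom = p_ref @ rr
    if np.any(denom <= 0):
        raise ModelInputError("reference category distribution is empty")
    return np.asarray(baseline) * (p_scen @ rr) / denom


# ---------------------------------------------------------------------------
# state containers


@dataclass
class HealthState:
    """Annual population, disease and utility state of one scenario run."""

    years: np.ndarray
    population: np.ndarray        # (Y, 101, 2)
    prevalence: dict              # disease -> (Y, 101, 2) proportion
    incident_cases: dict          # disease -> (Y,) new cases during year ending at t
    deaths: np.ndarray            # (Y,) deaths during year ending at t
    utility: np.ndarray           # (Y, 101, 2)
    qalys: np.ndarray             # (Y,)
    person_years: np.ndarray      # (Y,)

    def prevalent_cases(self, disease: str) -> np.ndarray:
        """Prevalent case counts per year, summed over the grid."""
        return (self.prevalence[disease] * self.population).sum(axis=(1, 2))

    def prevalent_cases_ages(self, disease: str, lo: int, hi: int) -> np.ndarray:
        """Prevalent cases per year in the age band [lo, hi)."""
        sl = slice(lo, hi)
        return (self.prevalence[disease][:, sl] * self.population[:, sl]).sum(axis=(1, 2))

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for d in self.prevalence:
            recs.append(
                pd.DataFrame(
                    {
                        "year": self.years,
                        "disease": d,
                        "prevalent_cases": self.prevalent_cases(d),
                        "incident_cases": self.incident_cases[d],
                    }
                )
            )
        out = pd.concat(recs, ignore_index=True)
        return out


@dataclass
class HealthDelta:
    """Scenario-versus-reference differences per year."""

    years: np.ndarray
    averted_cases: pd.DataFrame      # (year x disease), positive = averted
    averted_working: pd.DataFrame    # same, restricted to working ages
    qaly_gain: np.ndarray            # (Y,)
    working_age: tuple[int, int]

    def to_frame(self) -> pd.DataFrame:
        long = self.averted_cases.reset_index().melt(
            id_vars="year", var_name="disease", value_name="averted_cases"
        )
        return long


# ---------------------------------------------------------------------------
# the engine


def _category_props(traj: ConsumptionTrajectory, bundle: SyntheticBundle) -> list[np.ndarray]:
    """Per RR set: category proportions per (year, age, sex).

    Exposure means are piecewise constant over the horizon, so proportions
    are computed once per distinct year-state and tiled.
    """
    props = []
    for rr_set in bundle.rr_sets:
        shape = bundle.profiles[rr_set.exposure_groups[0]].dispersion
        mean = sum(traj.intake[g] for g in rr_set.exposure_groups)  # (Y, A, S)
        out = np.empty(mean.shape + (rr_set.n_categories,))
        cache: dict[bytes, np.ndarray] = {}
        for t in range(mean.shape[0]):
            key = mean[t].tobytes()
            if key not in cache:
                cache[key] = categorize(mean[t], shape, rr_set.category_boundaries)
            out[t] = cache[key]
        props.append(out)
    return props


def _rr_values(bundle: SyntheticBundle, override=None) -> list[np.ndarray]:
    if override is None:
        return [r.rr_mean for r in bundle.rr_sets]
    return [np.asarray(v, dtype=float) for v in override]


def simulate(
    traj: ConsumptionTrajectory,
    ref_traj: ConsumptionTrajectory,
    bundle: SyntheticBundle,
    rr_values=None,
    props: list[np.ndarray] | None = None,
    ref_props: list[np.ndarray] | None = None,
) -> HealthState:
    """Run the multistate model for one scenario trajectory.

    ``ref_traj`` supplies the reference category distribution against which
    incidence is rescaled; passing the same trajectory twice yields the
    reference run itself (scaling factor identically 1).  ``rr_values``
    optionally overrides the RR means per RR set (Monte Carlo); ``props`` /
    ``ref_props`` accept precomputed category proportions.
    """
    if not np.array_equal(traj.years, ref_traj.years):
        raise GridMismatchError("scenario and reference trajectories disagree on years")
    rr_list = _rr_values(bundle, rr_values)
    for rr_set, rr in zip(bundle.rr_sets, rr_list):
        if np.any(rr <= 0):
            raise ModelInputError(f"{rr_set.disease}: sampled RR must be > 0")
    p_scen = props if props is not None else _category_props(traj, bundle)
    p_ref = ref_props if ref_props is not None else _category_props(ref_traj, bundle)

    years = traj.years
    n_years = len(years)
    grid_shape = bundle.pyramid.counts.shape
    diseases = list(bundle.diseases)

    sex_frac = np.array(
        [1.0 - bundle.config.male_birth_fraction, bundle.config.male_birth_fraction]
    )
    births = bundle.pyramid.newborns_per_year * sex_frac
    bg = bundle.background_mortality
    em = {d: bundle.diseases[d].excess_mortality for d in diseases}
    dw = {d: bundle.diseases[d].disability_weight for d in diseases}
    inc0 = {d: bundle.diseases[d].incidence for d in diseases}

    pop = np.empty((n_years,) + grid_shape)
    prev = {d: np.empty((n_years,) + grid_shape) for d in diseases}
    incident = {d: np.zeros(n_years) for d in diseases}
    deaths = np.zeros(n_years)

    pop[0] = bundle.pyramid.counts
    for d in diseases:
        prev[d][0] = bundle.diseases[d].prevalence

    # incidence scaling factor per disease and year (product over RR sets)
    def factor(d: str, t: int) -> np.ndarray:
        f = np.ones(grid_shape)
        for rr_set, rr, ps, pr in zip(bundle.rr_sets, rr_list, p_scen, p_ref):
            if rr_set.disease != d:
                continue
            f = f * (ps[t] @ rr) / (pr[t] @ rr)
        return f

    for t in range(n_years - 1):
        n_t = pop[t]
        prev_t = {d: prev[d][t] for d in diseases}

        excess_load = sum(prev_t[d] * em[d] for d in diseases)
        m_total = bg + excess_load
        surv_total = np.exp(-m_total)
        deaths[t + 1] = float((n_t * (1.0 - surv_total)).sum())

        new_prev = {}
        for d in diseases:
            inc = inc0[d] * factor(d, t)
            if np.any(inc < 0):
                raise ModelInputError(f"{d}: negative incidence")
            m_other = m_total - prev_t[d] * em[d]
            a_prev = prev_t[d] * np.exp(-(m_other + em[d]))
            a_non = (1.0 - prev_t[d]) * np.exp(-m_other)
            newly = a_non * (1.0 - np.exp(-inc))
            alive = a_prev + a_non
            with np.errstate(invalid="ignore", divide="ignore"):
                p_new = np.where(alive > 0, (a_prev + newly) / alive, 0.0)
            new_prev[d] = np.clip(p_new, 0.0, 1.0)
            incident[d][t + 1] = float((newly * n_t).sum())

        n_surv = n_t * surv_total
        n_ages = grid_shape[0]
        nxt = np.empty_like(n_surv)
        nxt[0] = births
        nxt[1 : n_ages - 1] = n_surv[0 : n_ages - 2]
        nxt[n_ages - 1] = n_surv[n_ages - 2] + n_surv[n_ages - 1]
        pop[t + 1] = nxt

        for d in diseases:
            cases = new_prev[d] * n_surv
            c_nxt = np.empty_like(cases)
            c_nxt[0] = births * bundle.diseases[d].prevalence[0]
            c_nxt[1 : n_ages - 1] = cases[0 : n_ages - 2]
            c_nxt[n_ages - 1] = cases[n_ages - 2] + cases[n_ages - 1]
            with np.errstate(invalid="ignore", divide="ignore"):
                prev[d][t + 1] = np.where(nxt > 0, c_nxt / nxt, 0.0)

    decrement = sum(prev[d] * dw[d] for d in diseases)
    utility = np.clip(1.0 - decrement, 0.0, 1.0)
    qalys = (pop * utility).sum(axis=(1, 2))
    person_years = pop.sum(axis=(1, 2))

    return HealthState(
        years=years,
        population=pop,
        prevalence=prev,
        incident_cases=incident,
        deaths=deaths,
        utility=utility,
        qalys=qalys,
        person_years=person_years,
    )


def delta(
    scenario_state: HealthState,
    reference_state: HealthState,
    working_age: tuple[int, int] = (15, 75),
) -> HealthDelta:
    """Scenario-vs-reference differences: averted prevalent cases and QALYs.

    Averted counts are reference minus scenario (positive = cases avoided);
    QALY gain is scenario minus reference.  The working-age restriction uses
    the half-open band [lo, hi).
    """
    if not np.array_equal(scenario_state.years, reference_state.years):
        raise GridMismatchError("states disagree on years")
    years = scenario_state.years
    lo, hi = working_age
    averted = {}
    averted_w = {}
    for d in scenario_state.prevalence:
        averted[d] = reference_state.prevalent_cases(d) - scenario_state.prevalent_cases(d)
        averted_w[d] = reference_state.prevalent_cases_ages(d, lo, hi) - scenario_state.prevalent_cases_ages(d, lo, hi)
    idx = pd.Index(years, name="year")
    return HealthDelta(
        years=years,
        averted_cases=pd.DataFrame(averted, index=idx),
        averted_working=pd.DataFrame(averted_w, index=idx),
        qaly_gain=scenario_state.qalys - reference_state.qalys,
        working_age=working_age,
    )


# ---------------------------------------------------------------------------
# Monte Carlo over relative risks


@dataclass
class MonteCarloResult:
    """Point run plus per-iteration delta streams and 95% CI summaries."""

    point: HealthDelta
    averted: np.ndarray           # (n_iter, Y, D)
    averted_working: np.ndarray   # (n_iter, Y, D)
    qaly: np.ndarray              # (n_iter, Y)
    diseases: tuple

    def ci_averted(self, q=(2.5, 97.5)) -> dict:
        return {
            d: np.percentile(self.averted[:, :, i], q, axis=0)
            for i, d in enumerate(self.diseases)
        }

    def ci_qaly(self, q=(2.5, 97.5)) -> np.ndarray:
        return np.percentile(self.qaly, q, axis=0)

    def summary(self) -> pd.DataFrame:
        """Per-year, per-disease averted cases with 95% CI, plus QALY row."""
        years = self.point.years
        recs = []
        ci = self.ci_averted()
        for i, d in enumerate(self.diseases):
            recs.append(
                pd.DataFrame(
                    {
                        "year": years,
                        "effect": d,
                        "value": self.point.averted_cases[d].to_numpy(),
                        "ci_low": ci[d][0],
                        "ci_high": ci[d][1],
                    }
                )
            )
        qci = self.ci_qaly()
        recs.append(
            pd.DataFrame(
                {
                    "year": years,
                    "effect": "qaly_gain",
                    "value": self.point.qaly_gain,
                    "ci_low": qci[0],
                    "ci_high": qci[1],
                }
            )
        )
        return pd.concat(recs, ignore_index=True)


def sample_rr(bundle: SyntheticBundle, rng: np.random.Generator) -> list[np.ndarray]:
    """One Monte Carlo draw of every RR set.

    Each category RR is drawn from a normal with mean ``rr_mean`` and
    sd ``(ci_high - ci_low)/3.92``, truncated below at 10^-6; the reference
    category has a degenerate CI and therefore stays exactly 1.
    """
    draws = []
    for r in bundle.rr_sets:
        sd = (r.rr_ci[:, 1] - r.rr_ci[:, 0]) / 3.92
        draws.append(np.maximum(rng.normal(r.rr_mean, sd), _TRUNC))
    return draws


def monte_carlo(
    traj: ConsumptionTrajectory,
    ref_traj: ConsumptionTrajectory,
    bundle: SyntheticBundle,
    n_iter: int = 100,
    seed: int = 0,
    working_age: tuple[int, int] = (15, 75),
) -> MonteCarloResult:
    """Propagate RR uncertainty through the health model.

    Runs the scenario ``n_iter`` times with RRs resampled per iteration (the
    reference state is RR-invariant, so it is computed once) and reports the
    2.5th/97.5th percentile bands across iterations.  Fully reproducible for
    a fixed seed.
    """
    if n_iter < 2:
        raise ModelInputError("n_iter must be >= 2")
    rng = np.random.default_rng(seed)
    props = _category_props(traj, bundle)
    ref_props = _category_props(ref_traj, bundle)

    ref_state = simulate(ref_traj, ref_traj, bundle, props=ref_props, ref_props=ref_props)
    point_state = simulate(traj, ref_traj, bundle, props=props, ref_props=ref_props)
    point = delta(point_state, ref_state, working_age)

    diseases = tuple(bundle.diseases)
    n_years = len(traj.years)
    averted = np.empty((n_iter, n_years, len(diseases)))
    averted_w = np.empty_like(averted)
    qaly = np.empty((n_iter, n_years))
    for i in range(n_iter):
        rr_i = sample_rr(bundle, rng)
        st = simulate(traj, ref_traj, bundle, rr_values=rr_i, props=props, ref_props=ref_props)
        d_i = delta(st, ref_state, working_age)
        averted[i] = d_i.averted_cases[list(diseases)].to_numpy()
        averted_w[i] = d_i.averted_working[list(diseases)].to_numpy()
        qaly[i] = d_i.qaly_gain
    return MonteCarloResult(point, averted, averted_w, qaly, diseases)
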