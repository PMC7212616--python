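import numpy as np
import pandas as pd
import pytest

import foodscba as f
from foodscba.config import GenerationConfig
from foodscba.environment import ImpactVector
from foodscba.synthetic import (
    ConsumptionProfile,
    DiseaseSpec,
    EconomicInputs,
    FootprintTable,
    PopulationPyramid,
    RelativeRiskSet,
    SyntheticBundle,
)


@pytest.fixture(scope="session")
def bundle():
    return f.generate_all(7)


@pytest.fixture(scope="session")
def ref_traj(bundle):
    return f.project(bundle, f.Scenario("reference", {}, 2018, 30))


@pytest.fixture(scope="session")
def m15_traj(bundle):
    return f.project(bundle, f.MEAT15)


@pytest.fixture(scope="session")
def m15_result():
    return f.run_pipeline("meat15", seed=11, config=f.AnalysisConfig(n_iter=30))


@pytest.fixture(scope="session")
def fv10_result():
    return f.run_pipeline("fv10", seed=11, config=f.AnalysisConfig(n_iter=30))


def make_toy_bundle(
    n_ages=3,
    counts=100.0,
    newborns=0.0,
    bg_mortality=0.01,
    incidence=0.08,
    prevalence=0.10,
    excess_mortality=0.20,
    disability_weight=0.30,
    meat_intake=80.0,
    rr=(1.0, 2.0),
    boundaries=(50.0,),
    gamma_shape=4.0,
    extra_disease=None,
):
    """Hand-sized bundle on an n_ages x 2 grid with one meat-linked disease.

    ``extra_disease``: optional dict of DiseaseSpec kwargs for a second,
    risk-free disease (no RR set), used for compensation checks.
    """
    shape = (n_ages, 2)
    cfg = GenerationConfig(male_birth_fraction=0.5, gamma_shape=gamma_shape)
    pyramid = PopulationPyramid(2018, np.full(shape, counts, dtype=float), newborns)
    profiles = {
        "red_meat": ConsumptionProfile("red_meat", np.full(shape, meat_intake * 0.6), gamma_shape),
        "processed_meat": ConsumptionProfile(
            "processed_meat", np.full(shape, meat_intake * 0.4), gamma_shape
        ),
        "poultry": ConsumptionProfile("poultry", np.full(shape, 20.0), gamma_shape),
        "fruit_vegetables": ConsumptionProfile("fruit_vegetables", np.full(shape, 200.0), gamma_shape),
    }
    diseases = {
        "diabetes_type_2": DiseaseSpec(
            "diabetes_type_2",
            np.full(shape, incidence),
            np.full(shape, prevalence),
            np.full(shape, excess_mortality),
            disability_weight,
        )
    }
    rr_mean = np.asarray(rr, dtype=float)
    half = 0.4 * np.abs(rr_mean - 1.0)
    rr_sets = [
        RelativeRiskSet(
            "diabetes_type_2",
            ("red_meat", "processed_meat"),
            tuple(boundaries),
            rr_mean,
            np.stack([rr_mean - half, rr_mean + half], axis=1),
        )
    ]
    if extra_disease is not None:
        kw = dict(
            incidence=0.05, prevalence=0.08, excess_mortality=0.0, disability_weight=0.1
        )
        kw.update(extra_disease)
        diseases["coronary_heart_disease"] = DiseaseSpec(
            "coronary_heart_disease",
            np.full(shape, kw["incidence"]),
            np.full(shape, kw["prevalence"]),
            np.full(shape, kw["excess_mortality"]),
            kw["disability_weight"],
        )
    footprints = FootprintTable(
        {
            "red_meat": ImpactVector(np.array([25, 0.3, 0.005, 0.05, 30.0])),
            "processed_meat": ImpactVector(np.array([20, 0.3, 0.004, 0.04, 25.0])),
            "poultry": ImpactVector(np.array([6, 0.1, 0.002, 0.02, 8.0])),
            "fruit_vegetables": ImpactVector(np.array([1, 0.01, 0.0004, 0.003, 0.8])),
        }
    )
    economics = EconomicInputs(
        price_per_kg={g: 10.0 for g in profiles},
        healthcare_cost_per_case={d: 2000.0 for d in diseases},
        absenteeism_presenteeism_cost={d: 1000.0 for d in diseases},
        participation_fiscal_effect={d: 1000.0 for d in diseases},
    )
    return SyntheticBundle(
        seed=0,
        config=cfg,
        pyramid=pyramid,
        background_mortality=np.full(shape, bg_mortality),
        profiles=profiles,
        diseases=diseases,
        rr_sets=tuple(rr_sets),
        economics=economics,
        footprints=footprints,
    )


@pytest.fixture
def toy_bundle():
    return make_toy_bundle()
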