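"""Shared fixtures: default parameters and a cache of scenario simulations.

The behavioural tests and the acceptance suite probe the same canonical
scenarios (growth-factor boluses, sustained forcing, chemotherapy pulses),
so those simulations are run once per session.
"""

from __future__ import annotations

from dataclasses import replace

import pytest

import hemosim as hs
from hemosim.chemo import regimen_library
from hemosim.params import steepened_stem_feedback_overrides


@pytest.fixture(scope="session")
def pset():
    return hs.default_parameters()


@pytest.fixture(scope="session")
def model(pset):
    return hs.build_model_params(pset)


@pytest.fixture(scope="session")
def epo_bolus_result(model):
    scenario = hs.TreatmentScenario(
        injections=[hs.InjectionEvent(0.0, "epo_alfa", 150.0, "IU/kg", "iv")],
        horizon=150.0,
        name="epo_150iukg_iv",
    )
    return hs.simulate(scenario, model)


@pytest.fixture(scope="session")
def filgrastim_result(model):
    scenario = hs.TreatmentScenario(
        injections=[
            hs.InjectionEvent(0.0, "filgrastim", 300.0, "ug", "sc", site="gcsf_default")
        ],
        horizon=160.0,
        name="filgrastim_300ug_sc",
    )
    return hs.simulate(scenario, model)


@pytest.fixture(scope="session")
def pegfilgrastim_result(model):
    scenario = hs.TreatmentScenario(
        injections=[
            hs.InjectionEvent(0.0, "pegfilgrastim", 300.0, "ug", "sc", site="gcsf_default")
        ],
        horizon=160.0,
        name="pegfilgrastim_300ug_sc",
    )
    return hs.simulate(scenario, model)


@pytest.fixture(scope="session")
def sustained_gcsf_result(model):
    scenario = hs.TreatmentScenario(
        infusions=[hs.ConstantInfusion("FIL", 20000.0)], horizon=400.0
    )
    return hs.simulate(scenario, model)


@pytest.fixture(scope="session")
def sustained_epo_result(model):
    scenario = hs.TreatmentScenario(
        infusions=[hs.ConstantInfusion("EPO", 5.0)], horizon=300.0
    )
    return hs.simulate(scenario, model)


@pytest.fixture(scope="session")
def single_chop_regimen():
    return replace(regimen_library()["CHOP-21"], n_cycles=1, support=())


@pytest.fixture(scope="session")
def single_chop_result(model, single_chop_regimen):
    return hs.simulate(hs.TreatmentScenario(chemo=single_chop_regimen, horizon=150.0), model)


@pytest.fixture(scope="session")
def steepened_feedback_result(pset, single_chop_regimen):
    steep = hs.build_model_params(pset.with_values(steepened_stem_feedback_overrides()))
    return hs.simulate(
        hs.TreatmentScenario(chemo=single_chop_regimen, horizon=500.0, grid_dt=0.5), steep
    )
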