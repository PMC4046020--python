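"""Tests of steady-state construction, scenario integration and analysis."""

import numpy as np
import pytest

import hemosim as hs
from hemosim.simulate import (
    SteadyStateError,
    _derive_homeostasis,
    build_steady_state,
    oscillation_metrics,
    sensitivity_scan,
)
from hemosim.state import IDX, N_STATES


class TestSteadyState:
    def test_constructed_state_is_fixed_point(self, model):
        y0, _ = build_steady_state(model)
        assert y0.shape == (N_STATES,)
        assert np.all(y0[:11] == 1.0)

    def test_inconsistent_regulator_raises_with_report(self, pset):
        # an amplification regulator whose normal value is not 1 breaks the
        # influx/efflux balance and must be caught at construction
        bad = hs.build_model_params(
            pset.with_values({"erythroid.CE.amp.nor": 1.3, "erythroid.CE.amp.max": 4.0})
        )
        with pytest.raises(SteadyStateError, match="CE"):
            build_steady_state(bad)

    def test_stem_efflux_at_homeostasis(self, model):
        home = _derive_homeostasis(model)
        assert home.stem_efflux_nor == pytest.approx(model.prolif_s.a_nor / model.tau_s)

    def test_pk_states_at_endogenous_fixed_points(self, model):
        y0, home = build_steady_state(model)
        assert y0[IDX["FIL_CENT"]] == 1.0
        assert y0[IDX["EPO_CENT"]] == 1.0
        assert y0[IDX["PEG_CENT"]] == 0.0
        assert y0[IDX["EPO_RB"]] == pytest.approx(home.rb_nor)
        assert y0[IDX["EPO_INT"]] == pytest.approx(home.int_nor)


class TestSimulate:
    def test_empty_scenario_stays_at_baseline(self, model):
        result = hs.simulate(
            hs.TreatmentScenario(horizon=1000.0, grid_dt=1.0), model
        )
        obs = result.observables()
        assert np.max(np.abs(obs["ANC"] / 4000.0 - 1.0)) < 1e-3
        assert np.max(np.abs(obs["WBC"] / 7000.0 - 1.0)) < 1e-3
        assert np.max(np.abs(result.y[:, :11] - 1.0)) < 1e-3

    def test_deterministic_given_inputs(self, model):
        scenario = hs.TreatmentScenario(
            injections=[hs.InjectionEvent(0.0, "filgrastim", 300.0, "ug", "sc",
                                          site="gcsf_default")],
            horizon=30.0,
        )
        r1 = hs.simulate(scenario, model)
        r2 = hs.simulate(scenario, model)
        assert np.array_equal(r1.t, r2.t)
        assert np.array_equal(r1.y, r2.y)

    def test_event_file_order_irrelevant_across_days(self, model):
        e1 = hs.InjectionEvent(2.0, "filgrastim", 300.0, "ug", "sc", site="gcsf_default")
        e2 = hs.InjectionEvent(5.0, "filgrastim", 300.0, "ug", "sc", site="gcsf_default")
        r12 = hs.simulate(hs.TreatmentScenario(injections=[e1, e2], horizon=20.0), model)
        r21 = hs.simulate(hs.TreatmentScenario(injections=[e2, e1], horizon=20.0), model)
        assert np.array_equal(r12.y, r21.y)

    def test_solver_tolerance_convergence(self, model):
        scenario = hs.TreatmentScenario(
            injections=[hs.InjectionEvent(0.0, "filgrastim", 300.0, "ug", "sc",
                                          site="gcsf_default")],
            horizon=30.0,
        )
        coarse = hs.simulate(scenario, model, rtol=1e-8, atol=1e-10)
        fine = hs.simulate(scenario, model, rtol=1e-9, atol=1e-11)
        anc_c = coarse.observable("ANC")
        anc_f = fine.observable("ANC")
        assert np.max(np.abs(anc_c - anc_f) / anc_f) < 1e-3

    def test_non_negativity_under_combined_forcing(self, single_chop_result,
                                                   filgrastim_result, pegfilgrastim_result):
        for result in (single_chop_result, filgrastim_result, pegfilgrastim_result):
            assert np.all(result.y >= 0.0)

    def test_injection_outside_horizon_rejected(self, model):
        scenario = hs.TreatmentScenario(
            injections=[hs.InjectionEvent(50.0, "filgrastim", 300.0, "ug", "sc",
                                          site="gcsf_default")],
            horizon=20.0,
        )
        with pytest.raises(ValueError):
            hs.simulate(scenario, model)

    def test_mixed_sc_sites_for_one_species_rejected(self, model):
        scenario = hs.TreatmentScenario(
            injections=[
                hs.InjectionEvent(0.0, "epo_alfa", 100.0, "IU/kg", "sc", site="epo_alfa_thigh"),
                hs.InjectionEvent(7.0, "epo_alfa", 100.0, "IU/kg", "sc", site="epo_alfa_forearm"),
            ],
            horizon=30.0,
        )
        with pytest.raises(Exception, match="site group"):
            hs.simulate(scenario, model)

    def test_tidy_frame_covers_states_and_observables(self, filgrastim_result):
        frame = filgrastim_result.to_frame()
        assert set(["time", "variable", "value"]) == set(frame.columns)
        assert "GRA" in set(frame["variable"])
        assert "ANC" in set(frame["variable"])


class TestOscillationMetrics:
    def test_decaying_sinusoid_matches_closed_form(self):
        """For e^(-t/tau) sin(w t), successive |extrema| decay by
        exp(-pi/(w tau)) per half period."""
        tau, omega = 20.0, 2.0 * np.pi / 10.0
        t = np.linspace(0.0, 80.0, 4000)
        series = 1.0 + np.exp(-t / tau) * np.sin(omega * t)
        m = oscillation_metrics(t, series, baseline=1.0, smooth_window=1)
        expected = np.exp(-np.pi / (omega * tau))
        assert m.n_extrema >= 6
        np.testing.assert_allclose(m.ratios[:6], expected, rtol=0.05)
        assert m.period == pytest.approx(10.0, rel=0.05)

    def test_constant_series_has_no_extrema(self):
        t = np.linspace(0, 10, 100)
        m = oscillation_metrics(t, np.ones_like(t))
        assert m.n_extrema == 0
        assert m.damping_ratio is None

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            oscillation_metrics(np.arange(3.0), np.arange(3.0))


class TestSensitivityScan:
    def test_deteriorations_non_negative_at_optimum(self, pset):
        """Objective built from data generated by the same parameters: any
        perturbation can only worsen the fit."""
        scenario = hs.TreatmentScenario(
            injections=[hs.InjectionEvent(0.0, "filgrastim", 300.0, "ug", "sc",
                                          site="gcsf_default")],
            horizon=12.0, grid_dt=0.5,
        )
        spec = hs.FixtureSpec(
            scenario=scenario, sampling_days=np.arange(0.0, 11.0, 1.0),
            outcomes=("ANC",), n_patients=1, seed=0,
        )
        series = hs.generate_fixture(spec, pset)

        def objective(p):
            sim = hs.simulate(scenario, hs.build_model_params(p), rtol=1e-6, atol=1e-9)
            return sum(hs.fitness(sim, obs) for obs in series)

        names = ["granulo.CG.amp.fil.max", "granulo.MGB.t.fil.b", "pk.darbe.k_el"]
        table = sensitivity_scan(pset, objective, names)
        assert list(table["parameter"]) == names
        # fitted-parameter perturbations deteriorate the fit; small numerical
        # slack for the fixture interpolation residual
        for col in ("minus", "plus"):
            assert (table[col] >= -1e-6).all()
        # Darbepoetin PK is inert in a Filgrastim-only scenario
        inert = table.set_index("parameter").loc["pk.darbe.k_el"]
        assert inert["minus"] == 0.0 and inert["plus"] == 0.0

    def test_scan_reproducible(self, pset):
        objective = lambda p: (p["stem.tau_s"] - 2.0) ** 2
        t1 = sensitivity_scan(pset, objective, ["stem.tau_s"])
        t2 = sensitivity_scan(pset, objective, ["stem.tau_s"])
        assert t1.equals(t2)
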