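"""Tests of the G-CSF and EPO pharmacokinetic subsystems."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import hemosim as hs
from hemosim.params import ScAbsorptionParams
from hemosim.pk import (
    ConfigurationError,
    EpoPkState,
    GcsfPkState,
    InjectionEvent,
    apply_injection,
    epo_pk_rhs,
    epo_production,
    gcsf_pk_rhs,
    gcsf_production,
    sc_absorption_rhs,
)
from hemosim.simulate import _derive_homeostasis
from hemosim.state import IDX


@pytest.fixture(scope="module")
def home(model):
    return _derive_homeostasis(model)


class TestGcsfPk:
    def test_endogenous_fixed_point(self, model, home):
        state = GcsfPkState(
            sc1=0.0, sc2=0.0, cent=1.0,
            peri=model.pk_fil.k_cp / model.pk_fil.k_pc,
        )
        d = gcsf_pk_rhs(state, gra_rel=1.0, production=home.gcsf_prod_nor, params=model.pk_fil)
        assert max(abs(v) for v in (d.sc1, d.sc2, d.cent, d.peri)) < 1e-12

    def test_aplasia_raises_central_equilibrium(self, model, home):
        def equilibrium(gra_rel):
            def rhs(t, y):
                d = gcsf_pk_rhs(GcsfPkState(*y), gra_rel, home.gcsf_prod_nor, model.pk_fil)
                return [d.sc1, d.sc2, d.cent, d.peri]

            y0 = [0.0, 0.0, 1.0, model.pk_fil.k_cp / model.pk_fil.k_pc]
            sol = solve_ivp(rhs, (0.0, 200.0), y0, method="LSODA", rtol=1e-9)
            return sol.y[2, -1]

        assert equilibrium(0.0) > 2.0 * equilibrium(1.0)

    def test_saturable_sc_loss_spares_large_doses(self, model):
        """The bioavailability sink is Michaelis-Menten, so the FRACTION of a
        subcutaneous dose lost in sc1 decreases as the dose grows."""
        pk = model.pk_fil

        def fraction_lost(dose):
            # sc1 only: first-order transit out competes with the MM sink;
            # y[1] accumulates the transited (absorbed) amount
            def rhs(t, y):
                sc1 = y[0]
                loss = pk.vmax_sc * sc1 / (pk.km_sc + sc1)
                return [-pk.k_sc12 * sc1 - loss, pk.k_sc12 * sc1]

            sol = solve_ivp(rhs, (0.0, 60.0), [dose, 0.0], method="LSODA",
                            rtol=1e-10, atol=1e-12)
            return 1.0 - sol.y[1, -1] / dose

        small, large = fraction_lost(10.0), fraction_lost(5000.0)
        assert 0.0 < large < small < 1.0

    def test_production_normal_at_homeostasis(self, model):
        assert gcsf_production(1.0, 1.0, model.gcsf_prod_reg) == pytest.approx(1.0)

    def test_production_maximal_in_aplasia(self, model):
        assert gcsf_production(0.0, 0.0, model.gcsf_prod_reg) == pytest.approx(
            model.gcsf_prod_reg.y_min
        )

    def test_production_monotone_in_granulocyte_demand(self, model):
        grid = np.linspace(0.0, 3.0, 40)
        rates = [gcsf_production(1.0, g, model.gcsf_prod_reg) for g in grid]
        assert all(b <= a + 1e-12 for a, b in zip(rates, rates[1:]))


class TestEpoPk:
    def test_endogenous_fixed_point(self, model, home):
        site = model.sc_sites["epo_alfa_thigh"]
        state = EpoPkState(
            cent=1.0, peri=model.pk_epo.k_cp / model.pk_epo.k_pc, rb=home.rb_nor
        )
        d, internalised = epo_pk_rhs(
            state, home.epo_prod_nor, model.r_tot - home.rb_nor, model.pk_epo, site
        )
        assert max(abs(v) for v in (d.cent, d.peri, d.rb)) < 1e-12
        assert internalised == pytest.approx(model.k_deg_int * home.int_nor)

    def test_no_binding_empties_receptor_pool(self, model):
        from dataclasses import replace

        pk = replace(model.pk_epo, k_on=0.0)
        site = model.sc_sites["epo_alfa_thigh"]

        def rhs(t, y):
            d, _ = epo_pk_rhs(EpoPkState(*y), 0.0, model.r_tot - y[6], pk, site)
            return [d.d1, d.d2, d.l1, d.l2, d.cent, d.peri, d.rb]

        y0 = [0, 0, 0, 0, 1.0, 0.2, 0.2]
        sol = solve_ivp(rhs, (0.0, 50.0), y0, method="LSODA", rtol=1e-9)
        assert sol.y[6, -1] < 1e-6

    def test_receptor_occupancy_never_exceeds_total(self, model):
        site = model.sc_sites["epo_alfa_thigh"]

        def rhs(t, y):
            d, _ = epo_pk_rhs(
                EpoPkState(*y), 0.0, model.r_tot - y[6], model.pk_epo, site
            )
            return [d.d1, d.d2, d.l1, d.l2, d.cent, d.peri, d.rb]

        y0 = [0, 0, 0, 0, 500.0, 0.0, 0.0]  # large bolus
        sol = solve_ivp(rhs, (0.0, 30.0), y0, method="LSODA", rtol=1e-9,
                        t_eval=np.linspace(0, 30, 200))
        assert np.all(sol.y[6] <= model.r_tot + 1e-9)

    def test_production_monotone_decreasing_in_erythrocytes(self, model):
        assert epo_production(1.0, model.epo_prod_reg) == pytest.approx(1.0)
        assert epo_production(0.5, model.epo_prod_reg) > 1.0
        assert epo_production(1.5, model.epo_prod_reg) < 1.0


class TestScAbsorption:
    lossless = ScAbsorptionParams(
        f_direct=0.6, k_direct=1.5, k_lymph=0.8, loss_site=0.0, loss_lymph=0.0
    )

    def _integrate(self, site, dose=100.0, horizon=400.0):
        def rhs(t, y):
            dd1, dd2, dl1, dl2, efflux = sc_absorption_rhs(*y[:4], site)
            return [dd1, dd2, dl1, dl2, efflux]  # y[4] accumulates delivery

        y0 = [site.f_direct * dose, 0.0, (1 - site.f_direct) * dose, 0.0, 0.0]
        return solve_ivp(rhs, (0.0, horizon), y0, method="LSODA",
                         rtol=1e-10, atol=1e-12, t_eval=np.linspace(0, horizon, 2000))

    def test_lossless_chain_delivers_entire_dose(self):
        sol = self._integrate(self.lossless)
        assert sol.y[4, -1] == pytest.approx(100.0, rel=1e-9)

    def test_slower_chain_same_mass_later_peak(self):
        slow = ScAbsorptionParams(0.6, 0.75, 0.4, 0.0, 0.0)
        fast_sol = self._integrate(self.lossless)
        slow_sol = self._integrate(slow)
        assert slow_sol.y[4, -1] == pytest.approx(fast_sol.y[4, -1], rel=1e-9)
        rate_fast = np.gradient(fast_sol.y[4], fast_sol.t)
        rate_slow = np.gradient(slow_sol.y[4], slow_sol.t)
        assert slow_sol.t[rate_slow.argmax()] > fast_sol.t[rate_fast.argmax()]

    def test_losses_reduce_bioavailability(self):
        lossy = ScAbsorptionParams(0.6, 1.5, 0.8, 0.3, 0.2)
        sol = self._integrate(lossy)
        assert sol.y[4, -1] < 100.0


class TestInjections:
    def test_iv_epo_bolus_enters_central(self, model):
        y0, _ = hs.build_steady_state(model)
        event = InjectionEvent(0.0, "epo_alfa", 150.0, "IU/kg", "iv")
        y1 = apply_injection(y0, event, model)
        added = y1[IDX["EPO_CENT"]] - y0[IDX["EPO_CENT"]]
        assert added == pytest.approx(150.0 * model.pk_epo.dose_to_conc)
        changed = np.nonzero(y1 != y0)[0]
        assert list(changed) == [IDX["EPO_CENT"]]

    def test_sc_filgrastim_targets_first_subcompartment(self, model):
        y0, _ = hs.build_steady_state(model)
        event = InjectionEvent(0.0, "filgrastim", 300.0, "ug", "sc", site="gcsf_default")
        y1 = apply_injection(y0, event, model)
        assert y1[IDX["FIL_SC1"]] == pytest.approx(300.0 * model.pk_fil.dose_to_conc)

    def test_sc_epo_splits_between_routes(self, model):
        y0, _ = hs.build_steady_state(model)
        event = InjectionEvent(0.0, "epo_beta", 100.0, "IU/kg", "sc", site="epo_beta_thigh")
        y1 = apply_injection(y0, event, model)
        site = model.sc_sites["epo_beta_thigh"]
        total = 100.0 * model.pk_epo.dose_to_conc
        assert y1[IDX["EPO_D1"]] == pytest.approx(site.f_direct * total)
        assert y1[IDX["EPO_L1"]] == pytest.approx((1 - site.f_direct) * total)

    def test_pegfilgrastim_updates_its_own_species(self, model):
        y0, _ = hs.build_steady_state(model)
        event = InjectionEvent(0.0, "pegfilgrastim", 6000.0, "ug", "sc", site="gcsf_default")
        y1 = apply_injection(y0, event, model)
        assert y1[IDX["PEG_SC1"]] > 0
        assert y1[IDX["FIL_SC1"]] == y0[IDX["FIL_SC1"]]

    def test_zero_dose_rejected(self):
        with pytest.raises(ConfigurationError):
            InjectionEvent(0.0, "filgrastim", 0.0)

    def test_unknown_derivative_rejected(self):
        with pytest.raises(ConfigurationError):
            InjectionEvent(0.0, "espresso", 1.0)

    def test_sc_epo_without_site_rejected(self):
        with pytest.raises(ConfigurationError):
            InjectionEvent(0.0, "epo_alfa", 100.0, "IU/kg", "sc")

    def test_unknown_site_group_rejected(self, model):
        y0, _ = hs.build_steady_state(model)
        event = InjectionEvent(0.0, "epo_alfa", 100.0, "IU/kg", "sc", site="nowhere")
        with pytest.raises(ConfigurationError):
            apply_injection(y0, event, model)


class TestMassBalance:
    def test_gcsf_species_conserves_mass_without_losses(self, model):
        from dataclasses import replace

        pk = replace(model.pk_fil, vmax_sc=0.0, k_ren=0.0, vmax_gra=0.0)

        def rhs(t, y):
            d = gcsf_pk_rhs(GcsfPkState(*y), 1.0, 0.0, pk)
            return [d.sc1, d.sc2, d.cent, d.peri]

        sol = solve_ivp(rhs, (0.0, 100.0), [300.0, 0, 0, 0], method="LSODA",
                        rtol=1e-11, atol=1e-12, t_eval=np.linspace(0, 100, 500))
        totals = sol.y.sum(axis=0)
        assert np.max(np.abs(totals - 300.0)) / 300.0 < 1e-9

    def test_epo_species_conserves_mass_without_losses(self, model):
        from dataclasses import replace

        pk = replace(model.pk_epo, k_el=0.0)
        site = ScAbsorptionParams(0.6, 1.5, 0.8, 0.0, 0.0)

        def rhs(t, y):
            # y: d1 d2 l1 l2 cent peri rb internal
            d, internalised = epo_pk_rhs(
                EpoPkState(*y[:7]), 0.0, model.r_tot - y[6], pk, site
            )
            return [d.d1, d.d2, d.l1, d.l2, d.cent, d.peri, d.rb, internalised]

        dose = 500.0
        y0 = [0.6 * dose, 0, 0.4 * dose, 0, 0, 0, 0, 0]
        sol = solve_ivp(rhs, (0.0, 100.0), y0, method="LSODA", rtol=1e-11,
                        atol=1e-12, t_eval=np.linspace(0, 100, 500))
        totals = sol.y.sum(axis=0)
        assert np.max(np.abs(totals - dose)) / dose < 1e-9

    def test_pegfilgrastim_outlasts_filgrastim(self, model):
        """Equal i.v. doses: the Pegfilgrastim central concentration decays
        slower than Filgrastim's (long-half-life derivative)."""

        def central_after(pk, t_end):
            def rhs(t, y):
                d = gcsf_pk_rhs(GcsfPkState(*y), 1.0, 0.0, pk)
                return [d.sc1, d.sc2, d.cent, d.peri]

            sol = solve_ivp(rhs, (0.0, t_end), [0, 0, 100.0, 0], method="LSODA",
                            rtol=1e-10, atol=1e-12)
            return sol.y[2, -1] + sol.y[3, -1]

        for t_end in (1.0, 3.0, 7.0):
            assert central_after(model.pk_peg, t_end) > central_after(model.pk_fil, t_end)
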