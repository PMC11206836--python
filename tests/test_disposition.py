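"""Whole-body disposition: MM kinetics, mass balance, linear-PK oracle."""

import numpy as np
import pytest

from cbzpbpk.clearance import InvalidParameterError
from cbzpbpk.disposition import (
    SimulationOptions,
    effective_cl_int_liver,
    hepatic_elimination_rates,
    liver_pathway_table,
    michaelis_menten_rate,
    simulate_pbpk,
)
from cbzpbpk.metrics import nca
from cbzpbpk.parameters import Regimen


class TestMichaelisMenten:
    def test_half_saturation(self):
        assert michaelis_menten_rate(248.0, 248.0, 10.0, 1.0) == pytest.approx(5.0)

    def test_fold_scales_rate(self):
        base = michaelis_menten_rate(50.0, 248.0, 10.0, 1.0)
        assert michaelis_menten_rate(50.0, 248.0, 10.0, 3.0) \
            == pytest.approx(3 * base)

    def test_linear_limit(self):
        cu = 1e-4
        rate = michaelis_menten_rate(cu, 248.0, 10.0, 1.0)
        assert rate == pytest.approx(10.0 / 248.0 * cu, rel=1e-3)

    def test_per_enzyme_rate_at_km(self):
        # per-unit-enzyme basis: at Cu = Km the rate is Vmax/2 = 0.375
        assert michaelis_menten_rate(248.0, 248.0, 0.75, 1.0) \
            == pytest.approx(0.375)

    def test_invalid_km(self):
        with pytest.raises(InvalidParameterError):
            michaelis_menten_rate(1.0, 0.0, 1.0)


class TestHepaticElimination:
    def test_zero_concentration_zero_rates(self, cbz, phys):
        lps = liver_pathway_table(cbz, phys)
        rates = hepatic_elimination_rates(0.0, cbz.MW_g_mol, lps, {}, 3.316)
        assert all(v == 0.0 for v in rates.values())

    def test_fold_affects_only_its_enzyme(self, cbz, phys):
        lps = liver_pathway_table(cbz, phys)
        base = hepatic_elimination_rates(10.0, cbz.MW_g_mol, lps, {}, 3.316)
        doubled = hepatic_elimination_rates(
            10.0, cbz.MW_g_mol, lps, {"CYP3A4": 2.0}, 3.316)
        for label in base:
            if label.startswith("CYP3A4"):
                assert doubled[label] == pytest.approx(2 * base[label])
            else:
                assert doubled[label] == pytest.approx(base[label])

    def test_low_concentration_shares_match_intrinsic_clearances(self, cbz, phys):
        """At Cu << Km each pathway's share equals its Vmax/Km (or CL_int)
        share - recomputed here by hand from the same primitives."""
        lps = liver_pathway_table(cbz, phys)
        cu = 1e-3
        rates = hepatic_elimination_rates(cu, cbz.MW_g_mol, lps, {}, 3.316)
        total = sum(rates.values())
        cl_ints = {lp.label: lp.vmax_organ_mg_h / (lp.pathway.Km_uM
                                                   * cbz.MW_g_mol / 1000.0)
                   for lp in lps}
        cl_ints["CL_int"] = 3.316
        cl_total = sum(cl_ints.values())
        for label, rate in rates.items():
            assert rate / total == pytest.approx(cl_ints[label] / cl_total,
                                                 rel=1e-4)

    def test_epoxide_intrinsic_from_organ_clearance(self, cbze, phys):
        cl_int = effective_cl_int_liver(cbze, phys)
        fu_b = cbze.fu_p / cbze.Rbp
        qh = phys.hepatic_blood_flow_L_h
        assert qh * fu_b * cl_int / (qh + fu_b * cl_int) \
            == pytest.approx(4.86, rel=1e-9)


@pytest.fixture(scope="module")
def iv_low_dose(cbz, phys):
    reg = Regimen(route="iv_infusion", dose_mg=10.0, infusion_duration_h=0.5,
                  simulation_horizon_h=400.0)
    opts = SimulationOptions(induction=False, track_metabolite=False)
    return simulate_pbpk(reg, cbz, None, phys, opts)


class TestWholeBodySimulation:
    def test_iv_linear_auc_matches_well_stirred_closed_form(
            self, iv_low_dose, cbz, phys):
        """At sub-saturating concentrations the whole-body model must collapse
        to dose / CL with CL from the well-stirred liver plus renal filtration."""
        r = nca(iv_low_dose.times_h[1:],
                np.maximum(iv_low_dose.profile("parent_plasma")[1:], 1e-15),
                dose_mg=10.0)
        cl_int = 6.083  # sum of pathway Vmax/Km plus linear CL_int (L/h)
        qh = phys.hepatic_blood_flow_L_h
        fu_b = cbz.fu_p / cbz.Rbp
        cl_hep_blood = qh * fu_b * cl_int / (qh + fu_b * cl_int)
        cl_plasma = cl_hep_blood * cbz.Rbp + cbz.CL_renal_filt_L_h * cbz.fu_p
        assert r.CL_over_F == pytest.approx(cl_plasma, rel=0.01)

    def test_states_stay_nonnegative(self, iv_low_dose):
        for series in iv_low_dose.profiles.values():
            assert series.min() >= -1e-8

    def test_iv_mass_balance(self, iv_low_dose):
        assert iv_low_dose.mass_balance_error() < 1e-3

    def test_systemic_entry_equals_dose_for_iv(self, iv_low_dose):
        assert iv_low_dose.percentages["F_pct"] == pytest.approx(100.0, abs=0.01)


@pytest.fixture(scope="module")
def oral_with_metabolite(cbz, cbze, phys):
    reg = Regimen(route="oral", dose_mg=100.0, formulation="IR_tablet",
                  simulation_horizon_h=96.0)
    opts = SimulationOptions(induction=False)
    return simulate_pbpk(reg, cbz, cbze, phys, opts)


class TestParentMetaboliteCoupling:
    def test_parent_mass_balance(self, oral_with_metabolite):
        assert oral_with_metabolite.mass_balance_error() < 1e-3

    def test_metabolite_mass_balance(self, oral_with_metabolite):
        assert oral_with_metabolite.metabolite_balance_error() < 1e-3

    def test_formed_epoxide_matches_parent_pathway_flux(self, oral_with_metabolite):
        led = oral_with_metabolite.ledger
        mw_ratio = 252.27 / 236.27
        parent_flux = sum(v for k, v in led.items()
                          if "->CBZ-E" in k and k.startswith("parent_hepatic"))
        assert led["metabolite_formed_hepatic_mg"] \
            == pytest.approx(parent_flux * mw_ratio, rel=1e-6)

    def test_metabolite_profile_present_and_positive(self, oral_with_metabolite):
        cp = oral_with_metabolite.profile("metabolite_plasma")
        assert cp.max() > 0
        # the epoxide is a minor circulating species relative to parent
        assert cp.max() < oral_with_metabolite.profile("parent_plasma").max()

    def test_liver_unbound_concentration_below_km(self, oral_with_metabolite):
        cu = oral_with_metabolite.profile("parent_liver_unbound_uM")
        assert cu.max() < 248.0  # epoxide-pathway Km
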