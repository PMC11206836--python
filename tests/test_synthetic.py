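"""Synthetic study generation and parameter recovery."""

import numpy as np
import pytest

from cbzpbpk.disposition import SimulationOptions
from cbzpbpk.metrics import aafe
from cbzpbpk.parameters import Regimen
from cbzpbpk.synthetic import (
    apply_parameter_updates,
    generate_synthetic_study,
    recover_parameters,
)

FAST_OPTS = SimulationOptions(induction=False, track_metabolite=False,
                              rtol=1e-6, atol=1e-8, output_dt_h=0.25)


@pytest.fixture(scope="module")
def iv_protocol():
    return Regimen(route="iv_infusion", dose_mg=100.0, infusion_duration_h=0.5,
                   simulation_horizon_h=96.0)


class TestStudyGeneration:
    def test_zero_noise_reproduces_model(self, iv_protocol, cbz, phys):
        study = generate_synthetic_study(
            iv_protocol, 0.0, seed=7, parent=cbz, physiology=phys,
            options=FAST_OPTS)
        assert np.allclose(study.observed["concentration"], study.truth)

    def test_same_seed_same_study(self, iv_protocol, cbz, phys):
        kw = dict(parent=cbz, physiology=phys, options=FAST_OPTS)
        a = generate_synthetic_study(iv_protocol, 0.2, seed=11, **kw)
        b = generate_synthetic_study(iv_protocol, 0.2, seed=11, **kw)
        assert np.array_equal(a.observed["concentration"], b.observed["concentration"])
        c = generate_synthetic_study(iv_protocol, 0.2, seed=12, **kw)
        assert not np.array_equal(a.observed["concentration"],
                                  c.observed["concentration"])

    def test_noise_matches_lognormal_aafe_expectation(self, iv_protocol, cbz, phys):
        """At CV 20% the expected AAFE against truth is
        10^(sigma sqrt(2/pi)/ln 10) ~ 1.17."""
        dense = np.linspace(0.5, 96.0, 400)
        study = generate_synthetic_study(
            iv_protocol, 0.2, seed=3, schedule_h=dense, parent=cbz,
            physiology=phys, options=FAST_OPTS)
        observed = study.observed["concentration"].to_numpy()
        value = aafe(study.truth, observed)
        sigma = np.sqrt(np.log1p(0.2 ** 2))
        expected = 10.0 ** (sigma * np.sqrt(2.0 / np.pi) / np.log(10.0))
        assert value == pytest.approx(expected, abs=0.02)
        assert value == pytest.approx(1.17, abs=0.03)

    def test_lloq_censoring_keeps_only_quantifiable(self, iv_protocol, cbz, phys):
        study = generate_synthetic_study(
            iv_protocol, 0.2, seed=5, lloq=0.05, parent=cbz, physiology=phys,
            options=FAST_OPTS)
        assert (study.observed["concentration"] >= 0.05).all()
        assert (study.observed["concentration"] > 0).all()


class TestParameterUpdates:
    def test_top_level_field(self, cbz):
        updated = apply_parameter_updates(cbz, {"CL_int_liver_unbound_L_h": 5.0})
        assert updated.CL_int_liver_unbound_L_h == 5.0
        assert cbz.CL_int_liver_unbound_L_h == pytest.approx(3.316)

    def test_induction_field(self, cbz):
        updated = apply_parameter_updates(cbz, {"Emax_CYP3A4": 7.0})
        assert updated.induction["CYP3A4"].Emax == 7.0
        assert updated.induction["CYP3A4"].EC50_uM == 22.0

    def test_unknown_parameter_raises(self, cbz):
        with pytest.raises(KeyError):
            apply_parameter_updates(cbz, {"not_a_parameter": 1.0})


class TestRecovery:
    def test_recovers_linear_hepatic_clearance_from_noise_free_iv(
            self, iv_protocol, cbz, phys):
        """Self-consistency: refitting CL_int,liver,unbound on a noise-free
        synthetic iv study must return the generating value 3.316 L/h
        within 1%."""
        study = generate_synthetic_study(
            iv_protocol, 0.0, seed=1, parent=cbz, physiology=phys,
            options=FAST_OPTS)
        fit = recover_parameters(
            study, ["CL_int_liver_unbound_L_h"],
            {"CL_int_liver_unbound_L_h": (0.5, 15.0)},
            parent=cbz, physiology=phys, options=FAST_OPTS,
            starts={"CL_int_liver_unbound_L_h": 1.5})
        assert fit.converged
        assert fit.identifiable["CL_int_liver_unbound_L_h"]
        assert fit.estimates["CL_int_liver_unbound_L_h"] \
            == pytest.approx(3.316, rel=0.01)

    def test_emax_not_identifiable_from_single_dose(self, cbz, phys):
        """A low single dose carries no autoinduction signal, so an Emax fit
        must be flagged non-identifiable instead of silently succeeding."""
        opts = SimulationOptions(induction=True, track_metabolite=False,
                                 rtol=1e-6, atol=1e-8, output_dt_h=0.25)
        protocol = Regimen(route="iv_infusion", dose_mg=10.0,
                           infusion_duration_h=0.5, simulation_horizon_h=96.0)
        study = generate_synthetic_study(
            protocol, 0.0, seed=2, parent=cbz, physiology=phys, options=opts)
        fit = recover_parameters(
            study, ["Emax_CYP3A4"], {"Emax_CYP3A4": (0.0, 30.0)},
            parent=cbz, physiology=phys, options=opts,
            starts={"Emax_CYP3A4": 10.0})
        assert not fit.identifiable["Emax_CYP3A4"]
        assert fit.warn_if_nonidentifiable() == ["Emax_CYP3A4"]
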