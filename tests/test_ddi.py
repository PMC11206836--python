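"""DDI ratios, Guest acceptance limits, and victim co-simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cbzpbpk.clearance import InvalidParameterError
from cbzpbpk.ddi import (
    BUILTIN_VICTIMS,
    DDIStudyProtocol,
    VictimModel,
    ddi_ratios,
    guest_limits,
    simulate_victim_ddi,
    within_guest_limits,
)
from cbzpbpk.disposition import SimulationResult
from cbzpbpk.parameters import Regimen


class TestGuestLimits:
    def test_unity_ratio_gives_default_bioequivalence_band(self):
        lo, hi = guest_limits(1.0)
        assert (lo, hi) == (pytest.approx(0.8), pytest.approx(1.25))

    def test_strong_induction_ratio(self):
        # observed midazolam Cmax ratio 0.318 -> acceptance band 0.18-0.56
        lo, hi = guest_limits(0.318)
        assert lo == pytest.approx(0.18, abs=0.005)
        assert hi == pytest.approx(0.56, abs=0.005)

    def test_ratio_two(self):
        lo, hi = guest_limits(2.0)
        assert lo == pytest.approx(2.0 / 1.625)
        assert hi == pytest.approx(3.25)

    def test_rejects_nonpositive(self):
        with pytest.raises(InvalidParameterError):
            guest_limits(0.0)

    @given(st.floats(min_value=0.02, max_value=50.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_reciprocal_symmetry_and_geometry(self, r_obs):
        lo, hi = guest_limits(r_obs)
        lo_inv, hi_inv = guest_limits(1.0 / r_obs)
        assert lo_inv == pytest.approx(1.0 / hi, rel=1e-9)
        assert hi_inv == pytest.approx(1.0 / lo, rel=1e-9)
        assert lo * hi == pytest.approx(r_obs ** 2, rel=1e-9)
        limit = hi / r_obs
        assert limit >= 1.25 - 1e-12
        if abs(r_obs - 1.0) > 1e-6:
            assert limit > 1.25


class TestDDIRatios:
    def test_identical_profiles(self):
        t = np.linspace(0, 24, 100)
        c = np.exp(-0.1 * t)
        assert ddi_ratios(t, c, c) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_pointwise_halving(self):
        t = np.linspace(0, 24, 100)
        c = 10 * np.exp(-0.2 * t)
        auc_r, cmax_r = ddi_ratios(t, c, 0.5 * c)
        assert auc_r == pytest.approx(0.5)
        assert cmax_r == pytest.approx(0.5)

    def test_faster_elimination_exponential_oracle(self):
        """alone C=10 e^{-0.1t}, combo C=10 e^{-0.2t} over 48 h:
        AUC_last ratio = (1-e^-9.6)/ (2 (1-e^-4.8)) ~ 0.503, Cmax ratio 1."""
        t = np.linspace(0.0, 48.0, 2000)
        alone = 10 * np.exp(-0.1 * t)
        combo = 10 * np.exp(-0.2 * t)
        auc_r, cmax_r = ddi_ratios(t, alone, combo)
        expected = ((1 - np.exp(-0.2 * 48)) / 0.2) / ((1 - np.exp(-0.1 * 48)) / 0.1)
        assert auc_r == pytest.approx(expected, rel=1e-4)
        assert auc_r == pytest.approx(0.503, abs=0.002)
        assert cmax_r == pytest.approx(1.0)

    def test_zero_alone_auc_is_an_error(self):
        t = np.linspace(0, 10, 10)
        with pytest.raises(InvalidParameterError):
            ddi_ratios(t, np.zeros(10), np.ones(10))


def _fake_perpetrator(fold_3a4: float, horizon: float = 600.0) -> SimulationResult:
    """Minimal perpetrator result carrying constant enzyme folds."""
    t = np.linspace(0.0, horizon, 50)
    folds = {"liver:CYP3A4": np.full_like(t, fold_3a4),
             "liver:CYP2C9": np.ones_like(t),
             "gut:CYP3A4": np.full_like(t, fold_3a4)}
    reg = Regimen(route="iv_infusion", dose_mg=0.0, simulation_horizon_h=horizon)
    return SimulationResult(
        times_h=t, profiles={}, enzyme_folds=folds, ledger={},
        percentages={}, regimen=reg, options=None,  # type: ignore[arg-type]
        parent_name="perpetrator")


class TestVictimCoSimulation:
    def _victim(self, fm_3a4: float, gut_extraction: float = 0.0) -> VictimModel:
        return VictimModel(name="test", V_L=50.0, ka_1_h=2.0, F_baseline=1.0,
                           CL_total_baseline_L_h=5.0, fm={"CYP3A4": fm_3a4},
                           gut_extraction_baseline=gut_extraction)

    def test_null_perpetrator_changes_nothing(self):
        protocol = DDIStudyProtocol(victim_dose_mg=100, victim_dose_time_h=24,
                                    observation_window_h=72)
        t, alone, combo = simulate_victim_ddi(
            self._victim(0.9), _fake_perpetrator(1.0), protocol)
        assert np.allclose(alone, combo, rtol=1e-10, atol=1e-12)

    def test_full_fm_constant_double_fold_halves_auc(self):
        """Linear one-compartment victim, fm = 1 for the induced enzyme,
        constant fold 2: AUC_0-inf halves exactly (AUC = F D / CL)."""
        protocol = DDIStudyProtocol(victim_dose_mg=100, victim_dose_time_h=24,
                                    observation_window_h=500)
        t, alone, combo = simulate_victim_ddi(
            self._victim(1.0), _fake_perpetrator(2.0), protocol)
        auc_r, _ = ddi_ratios(t, alone, combo)
        assert auc_r == pytest.approx(0.5, rel=1e-3)

    def test_analytic_induced_auc_ratio(self):
        """AUC ratio = 1/(1 + fm (fold - 1)) for a linear victim."""
        fm, fold = 0.7, 3.0
        protocol = DDIStudyProtocol(victim_dose_mg=100, victim_dose_time_h=0,
                                    observation_window_h=800)
        t, alone, combo = simulate_victim_ddi(
            self._victim(fm), _fake_perpetrator(fold), protocol)
        auc_r, _ = ddi_ratios(t, alone, combo)
        assert auc_r == pytest.approx(1.0 / (1.0 + fm * (fold - 1.0)), rel=1e-2)

    def test_independent_victim_unaffected(self):
        victim = VictimModel(name="indep", V_L=50.0, ka_1_h=2.0, F_baseline=1.0,
                             CL_total_baseline_L_h=5.0, fm={"CYP2C9": 0.0})
        protocol = DDIStudyProtocol(victim_dose_mg=100, victim_dose_time_h=24,
                                    observation_window_h=48)
        t, alone, combo = simulate_victim_ddi(
            victim, _fake_perpetrator(5.0), protocol)
        auc_r, cmax_r = ddi_ratios(t, alone, combo)
        assert auc_r == pytest.approx(1.0, rel=1e-9)

    def test_induction_only_ratios_do_not_exceed_unity(self):
        protocol = DDIStudyProtocol(victim_dose_mg=100, victim_dose_time_h=24,
                                    observation_window_h=96)
        for fold in (1.5, 4.0, 10.0):
            t, alone, combo = simulate_victim_ddi(
                self._victim(0.8, gut_extraction=0.4),
                _fake_perpetrator(fold), protocol)
            auc_r, cmax_r = ddi_ratios(t, alone, combo)
            assert auc_r <= 1.0 + 1e-9
            assert cmax_r <= 1.0 + 1e-9

    def test_builtin_victims_have_consistent_fractions(self):
        for victim in BUILTIN_VICTIMS.values():
            assert sum(victim.fm.values()) + victim.fm_other \
                == pytest.approx(1.0)


def test_within_guest_limits_helper():
    assert within_guest_limits(0.3, 0.318)
    assert not within_guest_limits(0.9, 0.318)
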