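"""Victim-drug co-simulation and DDI ratio evaluation.

The perpetrator (carbamazepine, titrated to steady state) supplies enzyme
amount time courses; a victim drug is simulated twice, once at baseline enzyme
amounts and once under the induced, time-varying amounts scaling the fractions
of its clearance carried by each enzyme (and its gut extraction for
high-gut-extraction CYP3A4 substrates).  Exposure change is summarized by
AUC_last and Cmax ratios and judged against the variability-corrected Guest
acceptance limits.

The victims are deliberately generic one-compartment models with literature-
style parameters; the ratio and acceptance-limit machinery, not any specific
victim parameterization, is the tested surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .clearance import InvalidParameterError
from .disposition import SimulationResult
from .metrics import auc_trapezoid
from .parameters import ConfigurationError


@dataclass(frozen=True)
class VictimModel:
    """One-compartment victim PK model with enzyme-fractional clearance."""

    name: str
    V_L: float                    # central volume
    ka_1_h: float                 # first-order absorption rate
    F_baseline: float             # oral availability at baseline enzymes
    CL_total_baseline_L_h: float
    fm: dict[str, float] = field(default_factory=dict)  # enzyme -> fraction
    gut_extraction_baseline: float = 0.0
    gut_enzyme: str = "CYP3A4"
    Vmax_mg_h: Optional[float] = None   # optional saturable elimination
    Km_mg_L: Optional[float] = None

    def __post_init__(self):
        total = sum(self.fm.values())
        if not np.isclose(total + self.fm_other, 1.0):
            raise ConfigurationError("victim fm fractions must sum to 1")
        if not 0.0 <= self.gut_extraction_baseline < 1.0:
            raise ConfigurationError("gut extraction must be in [0, 1)")

    @property
    def fm_other(self) -> float:
        return max(1.0 - sum(self.fm.values()), 0.0)


@dataclass(frozen=True)
class DDIStudyProtocol:
    """Timing of the victim dose relative to the perpetrator time axis."""

    victim_dose_mg: float
    victim_dose_time_h: float     # on the perpetrator clock (after titration)
    observation_window_h: float = 48.0
    sampling_dt_h: float = 0.1


BUILTIN_VICTIMS = {
    # literature-style generic parameterizations (fm values approximate)
    "midazolam": VictimModel(
        name="midazolam", V_L=80.0, ka_1_h=3.0, F_baseline=0.35,
        CL_total_baseline_L_h=25.0, fm={"CYP3A4": 0.92},
        gut_extraction_baseline=0.45),
    "quinidine": VictimModel(
        name="quinidine", V_L=190.0, ka_1_h=1.5, F_baseline=0.8,
        CL_total_baseline_L_h=17.0, fm={"CYP3A4": 0.76}),
    "dolutegravir": VictimModel(
        name="dolutegravir", V_L=17.4, ka_1_h=1.0, F_baseline=0.8,
        CL_total_baseline_L_h=0.9, fm={"CYP3A4": 0.15, "UGT1A1": 0.0},
        gut_extraction_baseline=0.0),
    "tolbutamide": VictimModel(
        name="tolbutamide", V_L=9.0, ka_1_h=1.0, F_baseline=0.9,
        CL_total_baseline_L_h=0.85, fm={"CYP2C9": 0.85}),
    "phenytoin": VictimModel(
        name="phenytoin", V_L=45.0, ka_1_h=0.8, F_baseline=0.9,
        CL_total_baseline_L_h=2.0, fm={"CYP2C9": 0.9},
        Vmax_mg_h=30.0, Km_mg_L=5.0),
}


def _fold_interpolators(perpetrator: SimulationResult):
    t = perpetrator.times_h
    folds = {}
    for key, series in perpetrator.enzyme_folds.items():
        site, enz = key.split(":")
        if site == "liver":
            folds[enz] = (t, series)
        elif site == "gut":
            folds[f"gut:{enz}"] = (t, series)
    return folds


def _simulate_victim(victim: VictimModel, protocol: DDIStudyProtocol,
                     fold_tables, induced: bool) -> tuple[np.ndarray, np.ndarray]:
    t0 = protocol.victim_dose_time_h
    t_end = t0 + protocol.observation_window_h

    def fold_at(enz: str, t: float) -> float:
        if not induced:
            return 1.0
        tab = fold_tables.get(enz)
        if tab is None:
            if enz in victim.fm and victim.fm[enz] > 0:
                raise ConfigurationError(
                    f"perpetrator provides no enzyme states for {enz}")
            return 1.0
        tt, ff = tab
        return float(np.interp(t, tt, ff))

    for enz, frac in victim.fm.items():
        if frac > 0 and induced and enz not in fold_tables:
            raise ConfigurationError(
                f"victim clearance fraction references enzyme {enz} missing "
                "from the perpetrator's enzyme states")

    def gut_escape(t: float) -> float:
        eg0 = victim.gut_extraction_baseline
        if eg0 <= 0:
            return 1.0
        # gut intrinsic clearance scales with the gut enzyme amount
        k0 = eg0 / (1.0 - eg0)
        k = k0 * fold_at(f"gut:{victim.gut_enzyme}", t)
        return 1.0 / (1.0 + k)

    fg0 = 1.0 - victim.gut_extraction_baseline

    def rhs(t, y):
        a_gut, a_c = y
        cl_scale = victim.fm_other
        for enz, frac in victim.fm.items():
            cl_scale += frac * fold_at(enz, t)
        conc = max(a_c, 0.0) / victim.V_L
        if victim.Vmax_mg_h is not None and victim.Km_mg_L is not None:
            elim = (victim.Vmax_mg_h * cl_scale * conc
                    / (victim.Km_mg_L + conc))
        else:
            elim = victim.CL_total_baseline_L_h * cl_scale * conc
        absorbed = victim.ka_1_h * max(a_gut, 0.0)
        f_t = victim.F_baseline * gut_escape(t) / fg0
        return [-absorbed, absorbed * f_t - elim]

    n = int(round(protocol.observation_window_h / protocol.sampling_dt_h))
    t_eval = np.linspace(t0, t_end, n + 1)
    sol = solve_ivp(rhs, (t0, t_end), [protocol.victim_dose_mg, 0.0],
                    method="LSODA", t_eval=t_eval, rtol=1.0e-8, atol=1.0e-10)
    if not sol.success:
        raise RuntimeError(f"victim simulation failed: {sol.message}")
    return sol.t - t0, sol.y[1] / victim.V_L


def simulate_victim_ddi(victim: VictimModel, perpetrator_result: SimulationResult,
                        protocol: DDIStudyProtocol):
    """Simulate the victim alone and under the perpetrator's enzyme states.

    Returns ``(times_h, profile_alone, profile_combo)`` as concentration in
    mg/L on a shared grid starting at the victim dose.
    """
    fold_tables = _fold_interpolators(perpetrator_result)
    t, alone = _simulate_victim(victim, protocol, fold_tables, induced=False)
    _, combo = _simulate_victim(victim, protocol, fold_tables, induced=True)
    return t, alone, combo


def ddi_ratios(times_h: np.ndarray, profile_alone: np.ndarray,
               profile_combo: np.ndarray) -> tuple[float, float]:
    """(AUC_last ratio, Cmax ratio), combination over alone."""
    auc_alone = auc_trapezoid(times_h, profile_alone)
    if auc_alone <= 0:
        raise InvalidParameterError("alone-arm AUC is zero; ratio undefined")
    auc_ratio = auc_trapezoid(times_h, profile_combo) / auc_alone
    cmax_alone = float(np.max(profile_alone))
    if cmax_alone <= 0:
        raise InvalidParameterError("alone-arm Cmax is zero; ratio undefined")
    cmax_ratio = float(np.max(profile_combo)) / cmax_alone
    return auc_ratio, cmax_ratio


def guest_limits(r_obs: float) -> tuple[float, float]:
    """Variability-corrected acceptance bounds for an observed DDI ratio.

    With R = max(Robs, 1/Robs), Limit = (1.25 + 2 (R - 1)) / R (the 1.25
    factor carries the 20% intraindividual variability allowance); the bounds
    are (Robs / Limit, Robs x Limit).  Reciprocal-symmetric: the limits of
    1/Robs are the reciprocals of the limits of Robs.  At Robs = 1 the band is
    the conventional (0.8, 1.25).
    """
    if r_obs <= 0:
        raise InvalidParameterError("observed ratio must be positive")
    r = max(r_obs, 1.0 / r_obs)
    limit = (1.25 + 2.0 * (r - 1.0)) / r
    return r_obs / limit, r_obs * limit


def within_guest_limits(r_pred: float, r_obs: float) -> bool:
    lo, hi = guest_limits(r_obs)
    return lo <= r_pred <= hi
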