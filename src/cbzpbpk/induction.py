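"""Emax enzyme induction with first-order enzyme turnover.

Induction is modeled as a fold increase of enzyme synthesis,
fold(C) = 1 + Emax * C / (EC50 + C), realized dynamically through enzyme
turnover d(E*)/dt = kdeg * (fold(C) - E*), where E* is the enzyme amount
relative to baseline.  The steady-state enzyme level at a constant inducer
concentration equals fold(C) for any kdeg > 0; kdeg only sets the onset and
washout kinetics.
"""

from __future__ import annotations

from .clearance import InvalidParameterError
from .parameters import InductionParams

#: enzymes whose synthesis carbamazepine upregulates
INDUCIBLE_ENZYMES = ("CYP3A4", "CYP3A5", "CYP2C8", "CYP2B6", "CYP2C9")


def induction_fold(conc_uM: float, emax: float, ec50_uM: float) -> float:
    """Steady-state induction fold at inducer concentration ``conc_uM``."""
    if ec50_uM <= 0:
        raise InvalidParameterError("EC50 must be positive")
    if conc_uM < 0:
        raise InvalidParameterError("inducer concentration must be non-negative")
    return 1.0 + emax * conc_uM / (ec50_uM + conc_uM)


def induction_fold_params(conc_uM: float, params: InductionParams) -> float:
    return induction_fold(conc_uM, params.Emax, params.EC50_uM)


def enzyme_turnover_rhs(e_star: float, conc_uM: float,
                        params: InductionParams, kdeg_1_h: float) -> float:
    """d(E*)/dt for the relative enzyme amount under turnover."""
    if kdeg_1_h <= 0:
        raise InvalidParameterError("kdeg must be positive")
    if e_star <= 0:
        raise InvalidParameterError("relative enzyme amount must be positive")
    return kdeg_1_h * (induction_fold_params(conc_uM, params) - e_star)
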