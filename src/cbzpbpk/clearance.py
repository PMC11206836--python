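"""Clearance arithmetic, unit conversions, and the epoxide dose correction.

The metabolite model is parameterized from clinical data by back-calculating
its hepatic organ clearance from an NCA-derived CL_sys/F: systemic availability
after oral dosing is F = F_pre = (1 - CL_h/(Qh*Rbp)) * Fa, which closes a
linear fixed point in CL_h that is solved here exactly.
"""

from __future__ import annotations


class InvalidParameterError(ValueError):
    """A numeric input is outside its physical domain."""


def convert_concentration(value_uM: float, MW_g_mol: float) -> float:
    """Convert a molar concentration (uM) to a mass concentration (ug/mL)."""
    if MW_g_mol <= 0:
        raise InvalidParameterError("molecular weight must be positive")
    if value_uM < 0:
        raise InvalidParameterError("concentration must be non-negative")
    return value_uM * MW_g_mol / 1000.0


def convert_concentration_to_uM(value_ug_ml: float, MW_g_mol: float) -> float:
    """Inverse conversion: ug/mL to uM."""
    if MW_g_mol <= 0:
        raise InvalidParameterError("molecular weight must be positive")
    if value_ug_ml < 0:
        raise InvalidParameterError("concentration must be non-negative")
    return value_ug_ml * 1000.0 / MW_g_mol


def pre_systemic_availability(cl_hepatic: float, fa: float, rbp: float, qh: float) -> float:
    """F_pre = (1 - CL_h/(Qh*Rbp)) * Fa: oral availability before systemic entry."""
    return (1.0 - cl_hepatic / (qh * rbp)) * fa


def back_calculate_hepatic_clearance(cl_sys_over_f: float, cl_renal_filt: float,
                                     fa: float, rbp: float, qh: float) -> float:
    """Hepatic organ clearance (L/h) from an oral-dose CL_sys/F.

    Solves CL_h = CL_sys/F * (1 - CL_h/(Qh*Rbp)) * Fa - CL_renal,filt, which is
    linear in CL_h:

        CL_h = (CL_sys/F * Fa - CL_renal,filt) / (1 + CL_sys/F * Fa / (Qh*Rbp))
    """
    if cl_sys_over_f <= 0:
        raise InvalidParameterError("CL_sys/F must be positive")
    if not 0 < fa <= 1:
        raise InvalidParameterError("Fa must be in (0, 1]")
    if qh <= 0 or rbp <= 0:
        raise InvalidParameterError("Qh and Rbp must be positive")
    numerator = cl_sys_over_f * fa - cl_renal_filt
    if numerator <= 0:
        raise InvalidParameterError(
            "parameters imply non-positive hepatic clearance (renal clearance "
            "exceeds absorbed systemic clearance)"
        )
    cl_h = numerator / (1.0 + cl_sys_over_f * fa / (qh * rbp))
    # linear solution is always below the flow limit; keep the guard explicit
    if cl_h >= qh * rbp:
        raise InvalidParameterError("parameters imply hepatic extraction > 1")
    return cl_h


def intrinsic_from_hepatic(cl_hepatic: float, fu_p: float, rbp: float, qh: float) -> float:
    """Unbound hepatic intrinsic clearance from a well-stirred organ clearance.

    Inverts CL_h = Qh * fu_b * CLint / (Qh + fu_b * CLint) with fu_b = fu_p/Rbp.
    """
    if cl_hepatic >= qh:
        raise InvalidParameterError("organ clearance cannot exceed organ blood flow")
    fu_b = fu_p / rbp
    return qh * cl_hepatic / ((qh - cl_hepatic) * fu_b)


def correct_dose_for_gastric_degradation(dose_mg: float,
                                         oral_availability: float = 0.81) -> float:
    """Scale an epoxide dose for pre-absorption gastric degradation.

    The default factor 0.81 is the literature oral-availability ratio of the
    epoxide given without vs with antacid protection.
    """
    if dose_mg < 0:
        raise InvalidParameterError("dose must be non-negative")
    return dose_mg * oral_availability
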