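"""Model-evaluation statistics: NCA, fold errors, AAFE, local sensitivity.

The exposure metrics mirror standard non-compartmental analysis: linear
trapezoid AUC to the last observation, terminal slope from a log-linear
least-squares fit, and extrapolation to infinity by C_last/Ke.  Prediction
quality is summarized by the absolute average-fold error
AAFE = 10^(mean |log10(pred/obs)|) with the conventional 2-fold adequacy
threshold, and by symmetric 1.25-fold / 2-fold accuracy flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

AAFE_ADEQUATE_LIMIT = 2.0


class NCAError(ValueError):
    """Profile unsuitable for non-compartmental analysis."""


@dataclass(frozen=True)
class NCAResult:
    AUC_last: float      # ug*h/mL
    AUC_0_inf: float     # ug*h/mL
    Cmax: float          # ug/mL
    Tmax: float          # h
    Ke: float            # 1/h
    CL_over_F: float     # L/h (dose-normalized, NaN when dose unknown)

    def __post_init__(self):
        if self.AUC_0_inf + 1e-12 < self.AUC_last:
            raise NCAError("AUC_0-inf cannot be below AUC_last")


def auc_trapezoid(times_h: np.ndarray, conc: np.ndarray) -> float:
    """Linear-trapezoid area under the curve."""
    times_h = np.asarray(times_h, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if times_h.ndim != 1 or times_h.shape != conc.shape:
        raise NCAError("time and concentration arrays must be 1-D and equal length")
    if np.any(np.diff(times_h) <= 0):
        raise NCAError("time grid must be strictly increasing")
    return float(np.trapezoid(conc, times_h))


def terminal_rate_constant(times_h: np.ndarray, conc: np.ndarray,
                           n_points: int = 3) -> float:
    """Ke (1/h) from log-linear least squares on the last ``n_points`` samples."""
    if n_points < 2:
        raise NCAError("terminal regression needs at least 2 points")
    t = np.asarray(times_h, dtype=float)[-n_points:]
    c = np.asarray(conc, dtype=float)[-n_points:]
    if np.any(c <= 0):
        raise NCAError("non-positive terminal concentrations; cannot estimate Ke")
    slope = np.polyfit(t, np.log(c), 1)[0]
    ke = -slope
    if ke <= 0:
        raise NCAError("terminal phase is not declining; Ke estimation failed")
    return float(ke)


def nca(times_h: Sequence[float], conc: Sequence[float], dose_mg: float | None = None,
        terminal_points: int = 3) -> NCAResult:
    """Non-compartmental analysis of one concentration-time profile."""
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(conc, dtype=float)
    auc_last = auc_trapezoid(t, c)
    ke = terminal_rate_constant(t, c, terminal_points)
    auc_inf = auc_last + float(c[-1]) / ke
    cmax_idx = int(np.argmax(c))
    cl_over_f = dose_mg / auc_inf if dose_mg is not None and auc_inf > 0 else float("nan")
    return NCAResult(
        AUC_last=auc_last, AUC_0_inf=auc_inf, Cmax=float(c[cmax_idx]),
        Tmax=float(t[cmax_idx]), Ke=ke, CL_over_F=cl_over_f)


def aafe(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Absolute average-fold error, 10^(mean |log10(pred/obs)|); always >= 1."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or len(p) == 0:
        raise ValueError("predicted and observed must be equal-length 1-D arrays")
    if np.any(p <= 0) or np.any(o <= 0):
        raise ValueError("AAFE requires strictly positive concentrations")
    return float(10.0 ** np.mean(np.abs(np.log10(p / o))))


def aafe_adequate(value: float) -> bool:
    return value < AAFE_ADEQUATE_LIMIT


def fold_error_flags(pred_value: float, obs_value: float) -> tuple[bool, bool]:
    """(within 1.25-fold, within 2-fold) symmetric accuracy flags."""
    if pred_value <= 0 or obs_value <= 0:
        raise ValueError("fold errors need positive values")
    r = max(pred_value / obs_value, obs_value / pred_value)
    return (r <= 1.25, r <= 2.0)


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    sensitivity: float
    multipliers: np.ndarray
    auc_values: np.ndarray


def local_sensitivity(model_runner: Callable[[float], float], parameter_name: str,
                      base_value: float, *, span: tuple[float, float] = (0.8, 1.2),
                      n_steps: int = 9) -> SensitivityResult:
    """Log-log local sensitivity of AUC to one parameter.

    Evaluates ``model_runner`` (parameter value -> AUC_0-inf) at ``n_steps``
    logarithmically spaced multipliers of the base value and returns the
    least-squares slope of log(AUC) against log(parameter): S = +1 means a 10%
    parameter increase raises AUC by 10%.
    """
    mults = np.logspace(np.log10(span[0]), np.log10(span[1]), n_steps)
    aucs = np.empty(n_steps)
    for i, m in enumerate(mults):
        try:
            aucs[i] = model_runner(base_value * m)
        except Exception as exc:
            raise RuntimeError(
                f"sensitivity evaluation failed for {parameter_name} "
                f"x{m:.3f}") from exc
        if aucs[i] <= 0:
            raise RuntimeError(
                f"non-positive AUC for {parameter_name} x{m:.3f}")
    slope = np.polyfit(np.log(mults * base_value), np.log(aucs), 1)[0]
    return SensitivityResult(parameter=parameter_name, sensitivity=float(slope),
                             multipliers=mults, auc_values=aucs)
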