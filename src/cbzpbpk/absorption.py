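"""Compartmental absorption-and-transit (CAT) gut model.

Nine serial luminal compartments (stomach, duodenum, two jejunal, three ileal,
caecum, ascending colon) carry unreleased drug, polydisperse solid particles,
and dissolved drug.  Controlled-release forms release by a Weibull profile;
solids dissolve by a Noyes-Whitney spherical-particle law against the local
bile-salt-dependent solubility; dissolved drug is absorbed through an
effective-permeability flux into enterocyte compartments, where gut CYP3A4 and
UGT2B7 metabolize part of it before basolateral transfer into the portal
blood.  A cumulative mass ledger tracks the dissolved (Dis%), absorbed (Fa%)
and portal-entry (FDp%) fractions of dose.

Conventions: amounts in mg, fluid volumes in mL for luminal concentrations
(so concentrations are mg/mL), enterocyte concentrations in mg/L, time in h.
Gut metabolism is driven by the total enterocyte concentration; the
basolateral exit is villous-blood-flow limited with tissue partitioning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .clearance import InvalidParameterError
from .parameters import (
    ABSORBING_SEGMENTS,
    CompoundParameters,
    ConfigurationError,
    FormKind,
    Formulation,
    GUT_SEGMENTS,
    GutCompartment,
    Physiology,
    WeibullParams,
)

#: diffusion-layer thickness cap, cm (30 um convention)
H_EFF_CAP_CM = 30.0e-4
#: first-order rate used to relax supersaturated solutions back to solubility
PRECIPITATION_RATE_1_H = 50.0
#: radius floor to keep the shrinking-particle law finite, cm
_R_FLOOR_CM = 1.0e-6
#: cap on the per-bin dissolution rate constant (1/h per unit driving conc);
#: sub-micron particles dissolve effectively instantaneously, and bounding the
#: rate keeps the ODE system well conditioned as bins empty
_K_DISS_CAP = 200.0
#: cap on the Weibull release hazard (1/h); shape parameters b < 1 make the
#: hazard integrably singular at the lag time, and the cap (reached only
#: within ~1e-4 h of the lag) bounds the stiffness at negligible mass error
_RELEASE_HAZARD_CAP = 50.0


def weibull_release_fraction(t_h: float, params: WeibullParams, fed: bool = False) -> float:
    """Fraction of the dose released at time ``t_h`` after administration.

    Zero before the lag time T; approaches Max/100 with the stretched
    exponential (1 - exp(-(t-T)^b / A)).
    """
    if params.A_hb <= 0 or params.b <= 0:
        raise ConfigurationError("Weibull parameters A and b must be positive")
    if t_h <= params.T_h:
        return 0.0
    b = params.shape(fed)
    return params.Max_pct / 100.0 * (1.0 - math.exp(-((t_h - params.T_h) ** b) / params.A_hb))


def luminal_solubility(compartment: GutCompartment, compound: CompoundParameters,
                       fed: bool = False) -> float:
    """Local solubility (mg/mL) from the compound's measured anchor points.

    Gastric compartments (pH < 3) use the lowest-pH anchor; intestinal
    compartments interpolate linearly in bile-salt concentration between the
    remaining anchors, clamped at the outermost anchors.
    """
    points = sorted(compound.solubility_points, key=lambda p: (p.pH, p.bile_salt_mM))
    if not points:
        raise ConfigurationError(f"{compound.name} has no solubility anchors")
    if len(points) == 1:
        return points[0].solubility_mg_ml
    if compartment.pH < 3.0:
        return points[0].solubility_mg_ml
    intestinal = sorted((p for p in points if p.pH >= 3.0), key=lambda p: p.bile_salt_mM)
    if not intestinal:
        return points[-1].solubility_mg_ml
    bs = compartment.bile_salt_mM(fed)
    xs = [p.bile_salt_mM for p in intestinal]
    ys = [p.solubility_mg_ml for p in intestinal]
    return float(np.interp(bs, xs, ys))


def dissolution_rate(mass_mg: float, radius_cm: float, diffusion_cm2_h: float,
                     density_mg_cm3: float, solubility_mg_ml: float,
                     dissolved_conc_mg_ml: float) -> float:
    """Noyes-Whitney dissolution rate (mg/h) for one particle bin.

    rate = 3 D / (rho r h_eff) * m * (Cs - C), with the diffusion layer
    h_eff = min(r, 30 um).  Negative rates (precipitation) are handled by the
    transit model itself, not here.
    """
    if mass_mg <= 0.0 or radius_cm <= 0.0:
        return 0.0
    h_eff = min(radius_cm, H_EFF_CAP_CM)
    k = 3.0 * diffusion_cm2_h / (density_mg_cm3 * radius_cm * h_eff)
    return k * mass_mg * (solubility_mg_ml - dissolved_conc_mg_ml)


def sink_dissolution_time_h(radius_cm: float, diffusion_cm2_h: float,
                            density_mg_cm3: float, solubility_mg_ml: float) -> float:
    """Closed-form complete-dissolution time under sink conditions (r <= h cap)."""
    return density_mg_cm3 * radius_cm ** 2 / (2.0 * diffusion_cm2_h * solubility_mg_ml)


@dataclass
class GutLedger:
    """End-of-simulation cumulative mass ledger, all in mg."""

    dose_mg: float
    released_mg: float
    dissolved_mg: float
    absorbed_mg: float
    portal_mg: float
    gut_metabolized_mg: float
    fecal_mg: float
    residual_lumen_mg: float
    residual_enterocyte_mg: float

    @property
    def dis_pct(self) -> float:
        return 100.0 * self.dissolved_mg / self.dose_mg if self.dose_mg else 0.0

    @property
    def fa_pct(self) -> float:
        return 100.0 * self.absorbed_mg / self.dose_mg if self.dose_mg else 0.0

    @property
    def fdp_pct(self) -> float:
        return 100.0 * self.portal_mg / self.dose_mg if self.dose_mg else 0.0

    def mass_balance_error(self) -> float:
        """Relative closure error of the gut mass accounting."""
        if self.dose_mg == 0.0:
            return 0.0
        accounted = (self.residual_lumen_mg + self.residual_enterocyte_mg
                     + self.fecal_mg + self.portal_mg + self.gut_metabolized_mg)
        return abs(accounted - self.dose_mg) / self.dose_mg


class GutModel:
    """State layout and right-hand side of the luminal/enterocyte submodel."""

    N_SEG = len(GUT_SEGMENTS)
    N_ENT = len(ABSORBING_SEGMENTS)
    N_LEDGER = 6  # released, dissolved, absorbed, portal, gut-metabolized, fecal

    def __init__(self, compound: CompoundParameters, physiology: Physiology,
                 formulation: Formulation, *, fed: bool = False,
                 kp_gut: float = 1.0) -> None:
        self.compound = compound
        self.physiology = physiology
        self.formulation = formulation
        self.fed = fed
        self.kp_gut = kp_gut

        segs = [physiology.gut(name) for name in GUT_SEGMENTS]
        self.fluid_ml = np.array([s.fluid_volume_ml for s in segs])
        gastric_k = math.log(2.0) / physiology.gastric_half_time_h(fed)
        self.k_transit = np.array(
            [gastric_k] + [1.0 / s.transit_time_h for s in segs[1:]])
        peff_cm_h = compound.Peff_cm_s * 3600.0
        self.k_abs = np.array(
            [2.0 * peff_cm_h * s.asf / s.radius_cm for s in segs])  # 1/h
        self.solubility = np.array(
            [luminal_solubility(s, compound, fed) for s in segs])  # mg/mL
        self.ent_volume_L = np.array(
            [(s.enterocyte_volume_ml or 1.0) / 1000.0 for s in segs[1:]])
        self.villous_flow = np.array([(s.villous_flow_L_h or 0.0) for s in segs[1:]])
        self.ent_dist = np.array(
            [physiology.gut_enzyme_distribution.get(name, 0.0)
             for name in ABSORBING_SEGMENTS])

        if formulation.form in (FormKind.suspension, FormKind.IR_tablet):
            radii_um, weights = formulation.particle_bins()
            order = np.argsort(radii_um)
            self.bin_r0_cm = np.array(radii_um)[order] * 1.0e-4
            self.bin_weights = np.array(weights)[order]
            self.n_bins = len(radii_um)
            self.dose_to_bins = True
            self.density = formulation.particle_density_g_ml * 1000.0  # mg/cm^3
        else:
            # solutions and release-controlled forms still need one bin so
            # precipitated drug can redissolve downstream
            self.bin_r0_cm = np.array([10.0e-4])
            self.bin_weights = np.array([1.0])
            self.n_bins = 1
            self.dose_to_bins = False
            self.density = (formulation.particle_density_g_ml or 1.2) * 1000.0
        self.diffusion_cm2_h = compound.diffusion_coeff_cm2_s * 3600.0

        # gut metabolic capacity per pathway, split across segments
        self.gut_pathways = []
        for pw in compound.pathways:
            if "gut" not in pw.sites:
                continue
            pool = physiology.enzyme_pool("gut", pw.enzyme)
            vmax_organ = (pw.Vmax * pool.amount(pw.vmax_unit) * 60.0
                          * compound.MW_g_mol * 1.0e-9)  # mg/h whole-gut
            km_mg_L = pw.Km_uM * compound.MW_g_mol / 1000.0
            self.gut_pathways.append((pw, vmax_organ, km_mg_L))

        n = self.N_SEG
        self.i_unrel = slice(0, n)
        self.i_diss = slice(n, 2 * n)
        self.i_solid = slice(2 * n, 2 * n + n * self.n_bins)
        self.i_nref = slice(2 * n + n * self.n_bins, 2 * n + 2 * n * self.n_bins)
        base = 2 * n + 2 * n * self.n_bins
        self.i_ent = slice(base, base + self.N_ENT)
        self.i_ledger = slice(base + self.N_ENT, base + self.N_ENT + self.N_LEDGER)
        self.n_states = base + self.N_ENT + self.N_LEDGER

    # -- dosing ------------------------------------------------------------
    def initial_state(self) -> np.ndarray:
        return np.zeros(self.n_states)

    def apply_dose(self, y: np.ndarray, dose_mg: float) -> None:
        """Add one oral dose to the stomach, in place."""
        if dose_mg < 0:
            raise InvalidParameterError("dose must be non-negative")
        form = self.formulation.form
        if form == FormKind.solution:
            y[self.i_diss.start] += dose_mg
            y[self.i_ledger.start + 0] += dose_mg  # released
            y[self.i_ledger.start + 1] += dose_mg  # dissolved
        elif self.dose_to_bins:
            solid = y[self.i_solid].reshape(self.N_SEG, self.n_bins)
            nref = y[self.i_nref].reshape(self.N_SEG, self.n_bins)
            solid[0, :] += dose_mg * self.bin_weights
            nref[0, :] += dose_mg * self.bin_weights
            y[self.i_ledger.start + 0] += dose_mg  # released (disintegrated)
        else:
            y[self.i_unrel.start] += dose_mg

    # -- dynamics ----------------------------------------------------------
    def rhs(self, t_since_dose: float, y: np.ndarray, dy: np.ndarray,
            gut_cyp3a4_fold: float = 1.0):
        """Accumulate luminal/enterocyte derivatives into ``dy``.

        Returns (portal_flux_mg_h, gut_formed_by_product, ent_conc_mg_L) where
        ``gut_formed_by_product`` maps product name -> per-segment formation
        rate in mg-of-parent/h.
        """
        unrel = y[self.i_unrel]
        diss = y[self.i_diss]
        ent = y[self.i_ent]

        d_unrel = np.zeros(self.N_SEG)
        d_diss = np.zeros(self.N_SEG)
        d_ent = np.zeros(self.N_ENT)
        led = np.zeros(self.N_LEDGER)

        conc = np.maximum(diss, 0.0) / self.fluid_ml  # mg/mL

        # Weibull release of unreleased drug (controlled-release forms)
        if self.formulation.weibull is not None and unrel.sum() > 0:
            wb = self.formulation.weibull
            f = weibull_release_fraction(t_since_dose, wb, self.fed)
            if t_since_dose > wb.T_h and f < wb.Max_pct / 100.0:
                b = wb.shape(self.fed)
                dt = t_since_dose - wb.T_h
                fprime = (wb.Max_pct / 100.0 - f) * b * dt ** (b - 1.0) / wb.A_hb
                hazard = min(fprime / max(1.0 - f, 1.0e-12), _RELEASE_HAZARD_CAP)
                rel = hazard * np.maximum(unrel, 0.0)
                d_unrel -= rel
                d_diss += rel
                led[0] += rel.sum()
                led[1] += rel.sum()

        # particle dissolution / precipitation
        solid = np.maximum(y[self.i_solid].reshape(self.N_SEG, self.n_bins), 0.0)
        nref = np.maximum(y[self.i_nref].reshape(self.N_SEG, self.n_bins), 1.0e-12)
        d_solid = np.zeros_like(solid)
        d_nref = np.zeros_like(solid)
        frac = np.clip(solid / nref, 0.0, None)
        radius = np.maximum(self.bin_r0_cm[None, :] * np.cbrt(frac), _R_FLOOR_CM)
        h_eff = np.minimum(radius, H_EFF_CAP_CM)
        k = np.minimum(
            3.0 * self.diffusion_cm2_h / (self.density * radius * h_eff),
            _K_DISS_CAP)
        driving = np.maximum(self.solubility - conc, 0.0)
        rate = k * solid * driving[:, None]  # mg/h
        d_solid -= rate
        d_diss += rate.sum(axis=1)
        led[1] += rate.sum()
        # supersaturation relaxes into the smallest bin
        excess = np.maximum(conc - self.solubility, 0.0) * self.fluid_ml
        precip = PRECIPITATION_RATE_1_H * excess
        d_diss -= precip
        d_solid[:, 0] += precip
        d_nref[:, 0] += precip
        led[1] -= precip.sum()

        # absorption into enterocytes (no stomach absorption)
        j_abs = self.k_abs * np.maximum(diss, 0.0)
        d_diss -= j_abs
        d_ent += j_abs[1:]
        led[2] += j_abs.sum()

        # transit along the tube; colon outflow goes to feces
        for arr, darr in ((unrel, d_unrel), (diss, d_diss)):
            flow = self.k_transit * np.maximum(arr, 0.0)
            darr -= flow
            darr[1:] += flow[:-1]
            led[5] += flow[-1]
        for arr, darr in ((solid, d_solid), (nref, d_nref)):
            flow = self.k_transit[:, None] * arr
            darr -= flow
            darr[1:] += flow[:-1]
            if arr is solid:
                led[5] += flow[-1].sum()

        # enterocyte metabolism and basolateral transfer
        ent_conc = np.maximum(ent, 0.0) / self.ent_volume_L  # mg/L total
        gut_formed: dict[str, np.ndarray] = {}
        for pw, vmax_organ, km_mg_L in self.gut_pathways:
            fold = gut_cyp3a4_fold if pw.enzyme == "CYP3A4" else 1.0
            rate = (fold * vmax_organ * self.ent_dist
                    * ent_conc / (km_mg_L + ent_conc))  # mg/h per segment
            d_ent -= rate
            led[3] += rate.sum()
            if pw.product:
                gut_formed[pw.product] = gut_formed.get(pw.product, 0.0) + rate

        basolateral = self.villous_flow * ent_conc * self.compound.Rbp / self.kp_gut
        d_ent -= basolateral
        led[4] += basolateral.sum()

        dy[self.i_unrel] += d_unrel
        dy[self.i_diss] += d_diss
        if self.n_bins:
            dy[self.i_solid] += d_solid.ravel()
            dy[self.i_nref] += d_nref.ravel()
        dy[self.i_ent] += d_ent
        # ledger order: released, dissolved, absorbed, gut-metabolized, portal, fecal
        dy[self.i_ledger.start + 0] += led[0]
        dy[self.i_ledger.start + 1] += led[1]
        dy[self.i_ledger.start + 2] += led[2]
        dy[self.i_ledger.start + 3] += led[4]  # portal
        dy[self.i_ledger.start + 4] += led[3]  # gut metabolized
        dy[self.i_ledger.start + 5] += led[5]
        return basolateral, gut_formed, ent_conc

    # -- bookkeeping -------------------------------------------------------
    def ledger(self, y: np.ndarray, dose_mg: float) -> GutLedger:
        lumen = float(y[self.i_unrel].sum() + y[self.i_diss].sum())
        if self.n_bins:
            lumen += float(y[self.i_solid].sum())
        led = y[self.i_ledger]
        return GutLedger(
            dose_mg=dose_mg,
            released_mg=float(led[0]),
            dissolved_mg=float(led[1]),
            absorbed_mg=float(led[2]),
            portal_mg=float(led[3]),
            gut_metabolized_mg=float(led[4]),
            fecal_mg=float(led[5]),
            residual_lumen_mg=lumen,
            residual_enterocyte_mg=float(y[self.i_ent].sum()),
        )


@dataclass
class GutResult:
    """Output of a standalone gut simulation."""

    times_h: np.ndarray
    ledger: GutLedger
    dissolved_lumen_mg: np.ndarray
    enterocyte_mg: np.ndarray
    segments: tuple = field(default=GUT_SEGMENTS)

    @property
    def dis_pct(self) -> float:
        return self.ledger.dis_pct

    @property
    def fa_pct(self) -> float:
        return self.ledger.fa_pct

    @property
    def fdp_pct(self) -> float:
        return self.ledger.fdp_pct


def simulate_gut(formulation: Formulation, dose_mg: float,
                 compound: CompoundParameters, physiology: Physiology,
                 *, fed: bool = False, kp_gut: float = 1.0,
                 horizon_h: float = 96.0, gut_cyp3a4_fold: float = 1.0,
                 rtol: float = 1.0e-7, atol: float = 1.0e-9) -> GutResult:
    """Integrate the gut submodel alone, with the portal vein as a sink.

    Valid for absorption bookkeeping because luminal uptake is driven by the
    luminal concentration only; systemic drug does not re-enter the lumen.
    """
    from scipy.integrate import solve_ivp

    if dose_mg < 0:
        raise InvalidParameterError("dose must be non-negative")
    model = GutModel(compound, physiology, formulation, fed=fed, kp_gut=kp_gut)
    y0 = model.initial_state()
    model.apply_dose(y0, dose_mg)

    def rhs(t, y):
        dy = np.zeros_like(y)
        model.rhs(t, y, dy, gut_cyp3a4_fold)
        return dy

    # probe at a time safely past any release lag so the Weibull couplings
    # appear in the sparsity pattern
    from .disposition import probe_jacobian_sparsity
    sparsity = probe_jacobian_sparsity(lambda yy: rhs(2.5, yy), model.n_states)
    t_eval = np.arange(0.0, horizon_h + 1.0e-9, 0.1)
    sol = solve_ivp(rhs, (0.0, horizon_h), y0, method="BDF",
                    t_eval=t_eval, rtol=rtol, atol=atol, jac_sparsity=sparsity)
    if not sol.success:
        raise RuntimeError(f"gut solver failed: {sol.message}")
    y_end = sol.y[:, -1]
    return GutResult(
        times_h=sol.t,
        ledger=model.ledger(y_end, dose_mg),
        dissolved_lumen_mg=sol.y[model.i_diss, :],
        enterocyte_mg=sol.y[model.i_ent, :],
    )
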