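"""Whole-body perfusion-limited parent-metabolite PBPK model.

Twelve perfusion-limited tissues plus venous and arterial blood per compound,
fed by the compartmental gut model for oral doses.  Hepatic elimination runs
through Michaelis-Menten enzyme pathways (driven by the unbound liver
intracellular concentration) plus a linear unspecified intrinsic clearance;
renal filtration acts on the unbound plasma concentration.  Saturable pathway
capacities are whole-organ Vmax values obtained by scaling the per-unit-enzyme
rates of the compound file with the physiology's enzyme abundances.  Parent
metabolic flux with an epoxide product is routed into the metabolite's liver
(hepatic formation) or enterocyte pool (gut formation).

Enzyme amounts are dynamic states when induction is enabled: each inducible
enzyme follows a turnover equation whose production term is scaled by the
Emax model evaluated at the local inducer concentration (unbound liver
intracellular for hepatic enzymes, unbound enterocyte for gut CYP3A4).

Units: amounts mg, volumes L, flows L/h, time h, concentrations mg/L
(numerically equal to ug/mL).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .absorption import GutModel
from .clearance import InvalidParameterError, intrinsic_from_hepatic
from .parameters import (
    ABSORBING_SEGMENTS,
    CompoundParameters,
    EnzymePathway,
    Physiology,
    Regimen,
    Route,
    TISSUES,
)
from .partition import compute_kp_set, KpSet
from .induction import INDUCIBLE_ENZYMES, induction_fold

_TINY = 1.0e-12


class SolverError(RuntimeError):
    """Stiff-solver failure, carrying the integrator diagnostics."""


@dataclass(frozen=True)
class SimulationOptions:
    induction: bool = True
    rtol: float = 1.0e-7
    atol: float = 1.0e-9
    output_dt_h: float = 0.1
    track_metabolite: bool = True
    solver: str = "BDF"


def probe_jacobian_sparsity(fun, n_states: int, rng_seed: int = 0,
                            n_samples: int = 4):
    """Structural Jacobian sparsity of an ODE right-hand side, by probing.

    Evaluates the RHS at a few strictly positive random states and flags which
    outputs respond to each state perturbation; the union over samples (plus
    the diagonal) is returned as a sparse boolean matrix for the implicit
    solver's grouped finite-difference Jacobian.
    """
    from scipy import sparse

    rng = np.random.default_rng(rng_seed)
    pattern = np.zeros((n_states, n_states), dtype=bool)
    for k in range(n_samples):
        y0 = rng.lognormal(mean=0.0, sigma=1.5, size=n_states) * (10.0 ** (k - 1))
        f0 = fun(y0)
        for j in range(n_states):
            step = max(abs(y0[j]) * 1.0e-6, 1.0e-9)
            yp = y0.copy()
            yp[j] += step
            pattern[:, j] |= np.abs(fun(yp) - f0) > 0.0
    np.fill_diagonal(pattern, True)
    return sparse.csr_matrix(pattern)


@dataclass(frozen=True)
class LiverPathway:
    pathway: EnzymePathway
    vmax_organ_mg_h: float

    @property
    def label(self) -> str:
        product = self.pathway.product or "sink"
        return f"{self.pathway.enzyme}->{product}"


def liver_pathway_table(compound: CompoundParameters,
                        physiology: Physiology) -> list[LiverPathway]:
    """Whole-liver Vmax (mg substrate/h) for every hepatic pathway."""
    rows = []
    for pw in compound.pathways:
        if "liver" not in pw.sites:
            continue
        pool = physiology.enzyme_pool("liver", pw.enzyme)
        vmax = pw.Vmax * pool.amount(pw.vmax_unit) * 60.0 * compound.MW_g_mol * 1.0e-9
        rows.append(LiverPathway(pathway=pw, vmax_organ_mg_h=vmax))
    return rows


def effective_cl_int_liver(compound: CompoundParameters,
                           physiology: Physiology) -> float:
    """Linear unbound hepatic intrinsic clearance (L/h) for the compound.

    Uses the declared intrinsic value when present; otherwise inverts the
    well-stirred model on a declared organ clearance (the epoxide case).
    """
    if compound.CL_int_liver_unbound_L_h > 0:
        return compound.CL_int_liver_unbound_L_h
    if compound.CL_hepatic_L_h is not None:
        return intrinsic_from_hepatic(
            compound.CL_hepatic_L_h, compound.fu_p, compound.Rbp,
            physiology.hepatic_blood_flow_L_h)
    return 0.0


def michaelis_menten_rate(cu_uM: float, km_uM: float, vmax_organ_mg_h: float,
                          enzyme_fold: float = 1.0) -> float:
    """Saturable metabolic rate (mg/h) at unbound concentration ``cu_uM``."""
    if km_uM <= 0:
        raise InvalidParameterError("Km must be positive")
    if cu_uM < 0:
        cu_uM = 0.0
    return enzyme_fold * vmax_organ_mg_h * cu_uM / (km_uM + cu_uM)


def hepatic_elimination_rates(cu_uM: float, MW_g_mol: float,
                              liver_pathways: list[LiverPathway],
                              enzyme_folds: Mapping[str, float],
                              cl_int_liver_unbound_L_h: float) -> dict[str, float]:
    """Itemized hepatic elimination rates (mg/h) at a liver unbound conc.

    Returns one entry per saturable pathway (``"CYP3A4->CBZ-E"`` style keys)
    plus ``"CL_int"`` for the linear unspecified clearance.
    """
    rates: dict[str, float] = {}
    for lp in liver_pathways:
        fold = enzyme_folds.get(lp.pathway.enzyme, 1.0)
        rates[lp.label] = michaelis_menten_rate(
            cu_uM, lp.pathway.Km_uM, lp.vmax_organ_mg_h, fold)
    cu_mg_L = cu_uM * MW_g_mol / 1000.0
    rates["CL_int"] = cl_int_liver_unbound_L_h * max(cu_mg_L, 0.0)
    return rates


# ---------------------------------------------------------------------------
# state layout helpers

_IT = {name: i for i, name in enumerate(TISSUES)}
_N_TIS = len(TISSUES)


@dataclass
class _CompoundBlock:
    """Index bookkeeping for one compound's systemic states."""

    compound: CompoundParameters
    kps: KpSet
    cl_int: float
    liver_pathways: list[LiverPathway]
    off_tissues: int          # 12 tissues
    off_venous: int
    off_arterial: int
    off_renal: int
    off_hepmet: int           # len(liver_pathways) + 1 (linear last)
    off_ent: Optional[int] = None   # metabolite-only enterocyte pool (8)
    off_sysentry: Optional[int] = None
    off_formed: Optional[int] = None  # metabolite: [from liver, from gut]

    kp_arr: np.ndarray = field(default=None)  # type: ignore[assignment]

    def finalize(self) -> None:
        self.kp_arr = np.array([self.kps[t] for t in TISSUES])


class PBPKModel:
    """Assembled ODE system for one regimen."""

    def __init__(self, parent: CompoundParameters, physiology: Physiology,
                 regimen: Regimen, metabolite: Optional[CompoundParameters] = None,
                 options: SimulationOptions = SimulationOptions()) -> None:
        self.parent = parent
        self.metabolite = metabolite if options.track_metabolite else None
        self.phys = physiology
        self.regimen = regimen
        self.options = options

        self.qh = physiology.hepatic_blood_flow_L_h
        self.co = physiology.cardiac_output_L_h()
        self.v_ven = physiology.blood["volume_venous_L"]
        self.v_art = physiology.blood["volume_arterial_L"]
        self.q_t = np.array([physiology.tissues[t].flow_L_h for t in TISSUES])
        self.v_t = np.array([physiology.tissues[t].volume_L for t in TISSUES])

        offset = 0
        if regimen.route == Route.oral:
            kp_gut_parent = compute_kp_set(parent, physiology)["gut"]
            self.gut = GutModel(parent, physiology,
                                parent.formulation(regimen.formulation),
                                fed=regimen.fed, kp_gut=kp_gut_parent)
            self.off_gut = 0
            offset = self.gut.n_states
        else:
            self.gut = None
            self.off_gut = None

        self.blocks: list[_CompoundBlock] = []
        offset = self._add_block(parent, offset, is_metabolite=False)
        if self.metabolite is not None:
            offset = self._add_block(self.metabolite, offset, is_metabolite=True)

        # inducible enzyme states: (site, enzyme, kdeg, Emax, EC50)
        self.enzymes: list[tuple[str, str, float, float, float]] = []
        for enz in INDUCIBLE_ENZYMES:
            if enz not in parent.induction:
                continue
            ip = parent.induction[enz]
            emax = ip.Emax if options.induction else 0.0
            if enz in physiology.enzymes.get("liver", {}):
                kdeg = physiology.enzyme_pool("liver", enz).kdeg_1_h
                self.enzymes.append(("liver", enz, kdeg, emax, ip.EC50_uM))
            if enz in physiology.enzymes.get("gut", {}):
                kdeg = physiology.enzyme_pool("gut", enz).kdeg_1_h
                self.enzymes.append(("gut", enz, kdeg, emax, ip.EC50_uM))
        self.off_enz = offset
        offset += len(self.enzymes)
        self.n_states = offset

        self._liver_fold_idx = {
            enz: i for i, (site, enz, *_rest) in enumerate(self.enzymes)
            if site == "liver"}
        self._gut_3a4_idx = next(
            (i for i, (site, enz, *_r) in enumerate(self.enzymes)
             if site == "gut" and enz == "CYP3A4"), None)

        pb = self.blocks[0]
        self._p_mm_vmax = np.array([lp.vmax_organ_mg_h for lp in pb.liver_pathways])
        self._p_mm_km = np.array([lp.pathway.Km_uM for lp in pb.liver_pathways])
        self._p_mm_fold_idx = np.array(
            [self._liver_fold_idx.get(lp.pathway.enzyme, -1)
             for lp in pb.liver_pathways], dtype=int)
        self._p_mm_to_met = np.array(
            [1.0 if (self.metabolite is not None
                     and lp.pathway.product == "CBZ-E") else 0.0
             for lp in pb.liver_pathways])

        if self.gut is not None:
            self._ent_vol_L = self.gut.ent_volume_L
            self._villous = self.gut.villous_flow

    def _add_block(self, compound: CompoundParameters, offset: int,
                   is_metabolite: bool) -> int:
        kps = compute_kp_set(compound, self.phys)
        block = _CompoundBlock(
            compound=compound,
            kps=kps,
            cl_int=effective_cl_int_liver(compound, self.phys),
            liver_pathways=liver_pathway_table(compound, self.phys),
            off_tissues=offset,
            off_venous=offset + _N_TIS,
            off_arterial=offset + _N_TIS + 1,
            off_renal=offset + _N_TIS + 2,
            off_hepmet=offset + _N_TIS + 3,
        )
        offset = block.off_hepmet + len(block.liver_pathways) + 1
        if is_metabolite:
            block.off_ent = offset
            offset += len(ABSORBING_SEGMENTS)
            block.off_formed = offset
            offset += 2
        else:
            block.off_sysentry = offset
            offset += 1
        block.finalize()
        self.blocks.append(block)
        return offset

    # ------------------------------------------------------------------
    def initial_state(self) -> np.ndarray:
        y = np.zeros(self.n_states)
        y[self.off_enz:self.off_enz + len(self.enzymes)] = 1.0
        return y

    def _block_rhs(self, y: np.ndarray, dy: np.ndarray, block: _CompoundBlock,
                   folds: Mapping[str, float], portal_flux_mg_h: float,
                   liver_formation_mg_h: float, iv_rate_mg_h: float):
        """Circulatory + hepatic dynamics for one compound.

        Returns (cu_liver_uM, hepatic_elim_total, liver_inflow_conc).
        """
        cp = block.compound
        a_t = y[block.off_tissues:block.off_tissues + _N_TIS]
        c_ven = y[block.off_venous] / self.v_ven
        c_art = y[block.off_arterial] / self.v_art

        cv_t = (a_t / self.v_t) * (cp.Rbp / block.kp_arr)  # venous blood conc

        d_t = self.q_t * (c_art - cv_t)
        il, ilu, isp, igu = _IT["lung"], _IT["liver"], _IT["spleen"], _IT["gut"]
        # lung sits in series between venous and arterial blood
        d_t[il] = self.co * (c_ven - cv_t[il])

        # liver: hepatic artery + portal inflow (gut & spleen venous outflow
        # plus absorbed drug), minus hepatic venous outflow and elimination
        q_ha = self.q_t[ilu]
        liver_in = (q_ha * c_art + self.q_t[igu] * cv_t[igu]
                    + self.q_t[isp] * cv_t[isp] + portal_flux_mg_h)

        cu_mg_L = max((a_t[ilu] / self.v_t[ilu]) * cp.fu_p / block.kp_arr[ilu], 0.0)
        cu_uM = cu_mg_L * 1000.0 / cp.MW_g_mol

        if block.liver_pathways:
            if block is self.blocks[0]:
                vmax, km, fidx = self._p_mm_vmax, self._p_mm_km, self._p_mm_fold_idx
                fold_arr = np.array(
                    [folds.get(self.enzymes[i][1], 1.0) if i >= 0 else 1.0
                     for i in fidx]) if folds else np.ones(len(vmax))
            else:  # pragma: no cover - metabolite has no saturable pathways here
                vmax = np.array([lp.vmax_organ_mg_h for lp in block.liver_pathways])
                km = np.array([lp.pathway.Km_uM for lp in block.liver_pathways])
                fold_arr = np.ones(len(vmax))
            mm_rates = fold_arr * vmax * cu_uM / (km + cu_uM)
        else:
            mm_rates = np.zeros(0)
        linear_rate = block.cl_int * cu_mg_L
        elim_total = float(mm_rates.sum()) + linear_rate

        d_t[ilu] = liver_in + liver_formation_mg_h - self.qh * cv_t[ilu] - elim_total

        # venous pool collects everything except lung/liver/gut/spleen
        mask_sum = 0.0
        for i in range(_N_TIS):
            if i in (il, ilu, isp, igu):
                continue
            mask_sum += self.q_t[i] * cv_t[i]
        d_ven = mask_sum + self.qh * cv_t[ilu] - self.co * c_ven + iv_rate_mg_h
        d_art = self.co * (cv_t[il] - c_art)

        # renal filtration of unbound (arterial) plasma drug
        renal = cp.CL_renal_filt_L_h * cp.fu_p * max(c_art, 0.0) / cp.Rbp
        d_art -= renal

        dy[block.off_tissues:block.off_tissues + _N_TIS] += d_t
        dy[block.off_venous] += d_ven
        dy[block.off_arterial] += d_art
        dy[block.off_renal] += renal
        n_mm = len(block.liver_pathways)
        if n_mm:
            dy[block.off_hepmet:block.off_hepmet + n_mm] += mm_rates
        dy[block.off_hepmet + n_mm] += linear_rate

        liver_in_conc = liver_in / self.qh
        return cu_uM, elim_total, liver_in_conc, mm_rates

    def rhs(self, t: float, y: np.ndarray, gut_age_h: float,
            iv_rate_mg_h: float) -> np.ndarray:
        dy = np.zeros_like(y)
        liver_folds = {enz: max(y[self.off_enz + i], _TINY)
                       for i, (site, enz, *_r) in enumerate(self.enzymes)
                       if site == "liver"}

        # --- gut submodel (parent only)
        portal_parent = 0.0
        met_ent_formation = None
        ent_conc = None
        if self.gut is not None:
            fold_gut = 1.0
            if self._gut_3a4_idx is not None:
                fold_gut = max(y[self.off_enz + self._gut_3a4_idx], _TINY)
            y_gut = y[self.off_gut:self.off_gut + self.gut.n_states]
            dy_gut = dy[self.off_gut:self.off_gut + self.gut.n_states]
            basolateral, gut_formed, ent_conc = self.gut.rhs(
                gut_age_h, y_gut, dy_gut, fold_gut)
            portal_parent = float(basolateral.sum())
            met_ent_formation = gut_formed.get("CBZ-E")

        # --- parent systemic block
        pb = self.blocks[0]
        cu_parent_uM, elim_parent, liver_in_conc, mm_rates = self._block_rhs(
            y, dy, pb, liver_folds, portal_parent, 0.0, iv_rate_mg_h)

        # cumulative systemic entry: portal flux that escapes hepatic
        # extraction at the instantaneous extraction ratio (plus iv input)
        er = elim_parent / (self.qh * liver_in_conc + _TINY) if liver_in_conc > 0 else 0.0
        er = min(max(er, 0.0), 1.0)
        dy[pb.off_sysentry] += portal_parent * (1.0 - er) + iv_rate_mg_h

        # --- metabolite block
        if self.metabolite is not None:
            mb = self.blocks[1]
            mw_ratio = mb.compound.MW_g_mol / pb.compound.MW_g_mol
            hep_formation = float((mm_rates * self._p_mm_to_met).sum()) * mw_ratio
            dy[mb.off_formed] += hep_formation

            portal_met = 0.0
            if mb.off_ent is not None:
                a_ent = y[mb.off_ent:mb.off_ent + len(ABSORBING_SEGMENTS)]
                d_ent = dy[mb.off_ent:mb.off_ent + len(ABSORBING_SEGMENTS)]
                if self.gut is not None:
                    c_ent = np.maximum(a_ent, 0.0) / self._ent_vol_L
                    kp_gut_m = mb.kp_arr[_IT["gut"]]
                    outflow = self._villous * c_ent * mb.compound.Rbp / kp_gut_m
                    d_ent -= outflow
                    portal_met = float(outflow.sum())
                    if met_ent_formation is not None:
                        d_ent += met_ent_formation * mw_ratio
                        dy[mb.off_formed + 1] += float(met_ent_formation.sum()) * mw_ratio
            self._block_rhs(y, dy, mb, {}, portal_met, hep_formation, 0.0)

        # --- enzyme turnover
        if self.enzymes:
            gut_drive_uM = 0.0
            if ent_conc is not None and self.gut is not None:
                mean_conc = float((self.gut.ent_dist * ent_conc).sum())
                gut_drive_uM = (mean_conc * self.parent.fu_p
                                * 1000.0 / self.parent.MW_g_mol)
            for i, (site, _enz, kdeg, emax, ec50) in enumerate(self.enzymes):
                drive = cu_parent_uM if site == "liver" else gut_drive_uM
                e_star = y[self.off_enz + i]
                dy[self.off_enz + i] = kdeg * (
                    induction_fold(max(drive, 0.0), emax, ec50) - e_star)
        return dy


# ---------------------------------------------------------------------------
# simulation driver


@dataclass
class SimulationResult:
    """Concentration-time profiles plus the cumulative mass ledger."""

    times_h: np.ndarray
    profiles: dict[str, np.ndarray]
    enzyme_folds: dict[str, np.ndarray]
    ledger: dict[str, float]
    percentages: dict[str, float]
    regimen: Regimen
    options: SimulationOptions
    parent_name: str
    metabolite_name: Optional[str] = None

    def profile(self, key: str = "parent_plasma") -> np.ndarray:
        return self.profiles[key]

    @property
    def total_dose_mg(self) -> float:
        return self.regimen.dose_mg * self.regimen.n_doses

    def mass_balance_error(self) -> float:
        """Relative error of the parent dose accounting at end of run."""
        dose = self.total_dose_mg
        if dose == 0:
            return 0.0
        led = self.ledger
        accounted = (led["parent_body_residual_mg"] + led["parent_hepatic_metabolized_mg"]
                     + led["parent_renal_excreted_mg"])
        if self.regimen.route == Route.oral:
            accounted += (led["gut_residual_lumen_mg"] + led["gut_residual_enterocyte_mg"]
                          + led["gut_metabolized_mg"] + led["fecal_mg"])
        return abs(accounted - dose) / dose

    def metabolite_balance_error(self) -> float:
        formed = self.ledger.get("metabolite_formed_mg", 0.0)
        if formed <= 0:
            return 0.0
        accounted = (self.ledger["metabolite_body_residual_mg"]
                     + self.ledger["metabolite_eliminated_mg"])
        return abs(accounted - formed) / formed

    def to_frame(self):
        """Long-format profile table (time_h, site, concentration ug/mL)."""
        import pandas as pd

        rows = []
        for key, series in self.profiles.items():
            rows.append(pd.DataFrame({
                "time_h": self.times_h, "site": key, "concentration": series}))
        return pd.concat(rows, ignore_index=True)


def _segment_boundaries(regimen: Regimen) -> list[float]:
    bounds = {0.0, regimen.horizon_h}
    for td in regimen.dose_times():
        bounds.add(td)
        if regimen.route == Route.iv_infusion:
            bounds.add(min(td + regimen.infusion_duration_h, regimen.horizon_h))
    return sorted(b for b in bounds if b <= regimen.horizon_h)


def simulate_pbpk(regimen: Regimen, parent: CompoundParameters,
                  metabolite: Optional[CompoundParameters] = None,
                  physiology: Optional[Physiology] = None,
                  options: SimulationOptions = SimulationOptions()) -> SimulationResult:
    """Run the coupled gut + whole-body parent-metabolite simulation."""
    from .parameters import load_physiology

    if physiology is None:
        physiology = load_physiology()
    model = PBPKModel(parent, physiology, regimen, metabolite, options)
    y = model.initial_state()

    dose_times = regimen.dose_times()
    bounds = _segment_boundaries(regimen)
    infusion_rate = (regimen.dose_mg / regimen.infusion_duration_h
                     if regimen.route == Route.iv_infusion else 0.0)

    sparsity = None
    if options.solver == "BDF":
        # gut age past any release lag so Weibull couplings are captured
        sparsity = probe_jacobian_sparsity(
            lambda yy: model.rhs(2.5, yy, 2.5, 1.0), model.n_states)

    dt = options.output_dt_h
    all_t: list[np.ndarray] = []
    all_y: list[np.ndarray] = []
    last_dose = 0.0
    for a, b in zip(bounds[:-1], bounds[1:]):
        if any(abs(a - td) < 1.0e-9 for td in dose_times):
            last_dose = a
            if regimen.route == Route.oral:
                model.gut.apply_dose(y, regimen.dose_mg)
        iv_on = (regimen.route == Route.iv_infusion
                 and any(td - 1.0e-9 <= a < td + regimen.infusion_duration_h - 1.0e-9
                         for td in dose_times))
        rate = infusion_rate if iv_on else 0.0
        t0 = last_dose

        def rhs(t, yy):
            return model.rhs(t, yy, t - t0, rate)

        n_pts = max(int(round((b - a) / dt)), 1)
        t_eval = np.linspace(a, b, n_pts + 1)
        sol = solve_ivp(rhs, (a, b), y, method=options.solver,
                        t_eval=t_eval, rtol=options.rtol, atol=options.atol,
                        jac_sparsity=sparsity)
        if not sol.success:
            raise SolverError(
                f"integration failed on [{a}, {b}] h: {sol.message}; "
                f"|y|max={np.abs(y).max():.3g}")
        y = sol.y[:, -1].copy()
        if all_t:
            all_t.append(sol.t[1:])
            all_y.append(sol.y[:, 1:])
        else:
            all_t.append(sol.t)
            all_y.append(sol.y)

    times = np.concatenate(all_t)
    ys = np.concatenate(all_y, axis=1)
    return _assemble_result(model, regimen, options, times, ys, y)


def _assemble_result(model: PBPKModel, regimen: Regimen,
                     options: SimulationOptions, times: np.ndarray,
                     ys: np.ndarray, y_end: np.ndarray) -> SimulationResult:
    pb = model.blocks[0]
    profiles: dict[str, np.ndarray] = {}
    ilu = _IT["liver"]

    def block_profiles(block: _CompoundBlock, tag: str) -> None:
        cp = block.compound
        profiles[f"{tag}_plasma"] = ys[block.off_venous] / model.v_ven / cp.Rbp
        liver = ys[block.off_tissues + ilu] / model.v_t[ilu]
        profiles[f"{tag}_liver_total"] = liver
        profiles[f"{tag}_liver_unbound_uM"] = (
            liver * cp.fu_p / block.kp_arr[ilu] * 1000.0 / cp.MW_g_mol)

    block_profiles(pb, "parent")
    if model.metabolite is not None:
        block_profiles(model.blocks[1], "metabolite")

    if model.gut is not None:
        ent = ys[model.off_gut + model.gut.i_ent.start:
                 model.off_gut + model.gut.i_ent.stop]
        for i, seg in enumerate(ABSORBING_SEGMENTS):
            profiles[f"parent_enterocyte_{seg}"] = ent[i] / model.gut.ent_volume_L[i]

    enzyme_folds = {
        f"{site}:{enz}": ys[model.off_enz + i]
        for i, (site, enz, *_r) in enumerate(model.enzymes)}

    ledger: dict[str, float] = {}
    percentages: dict[str, float] = {}
    total_dose = regimen.dose_mg * regimen.n_doses

    body = float(y_end[pb.off_tissues:pb.off_tissues + _N_TIS].sum()
                 + y_end[pb.off_venous] + y_end[pb.off_arterial])
    n_mm = len(pb.liver_pathways)
    hepmet = y_end[pb.off_hepmet:pb.off_hepmet + n_mm + 1]
    ledger["parent_body_residual_mg"] = body
    ledger["parent_hepatic_metabolized_mg"] = float(hepmet.sum())
    for lp, amt in zip(pb.liver_pathways, hepmet[:n_mm]):
        ledger[f"parent_hepatic_{lp.label}_mg"] = float(amt)
    ledger["parent_hepatic_CL_int_mg"] = float(hepmet[n_mm])
    ledger["parent_renal_excreted_mg"] = float(y_end[pb.off_renal])
    ledger["parent_systemic_entry_mg"] = float(y_end[pb.off_sysentry])

    if model.gut is not None:
        gl = model.gut.ledger(y_end[model.off_gut:model.off_gut + model.gut.n_states],
                              total_dose)
        ledger["gut_residual_lumen_mg"] = gl.residual_lumen_mg
        ledger["gut_residual_enterocyte_mg"] = gl.residual_enterocyte_mg
        ledger["gut_metabolized_mg"] = gl.gut_metabolized_mg
        ledger["fecal_mg"] = gl.fecal_mg
        ledger["dissolved_cum_mg"] = gl.dissolved_mg
        ledger["absorbed_cum_mg"] = gl.absorbed_mg
        ledger["portal_cum_mg"] = gl.portal_mg
        percentages["Dis_pct"] = gl.dis_pct
        percentages["Fa_pct"] = gl.fa_pct
        percentages["FDp_pct"] = gl.fdp_pct
    if total_dose > 0:
        percentages["F_pct"] = 100.0 * float(y_end[pb.off_sysentry]) / total_dose

    if model.metabolite is not None:
        mb = model.blocks[1]
        m_body = float(y_end[mb.off_tissues:mb.off_tissues + _N_TIS].sum()
                       + y_end[mb.off_venous] + y_end[mb.off_arterial])
        if mb.off_ent is not None:
            m_body += float(y_end[mb.off_ent:mb.off_ent + len(ABSORBING_SEGMENTS)].sum())
        m_elim = float(y_end[mb.off_hepmet:mb.off_hepmet + len(mb.liver_pathways) + 1].sum()
                       + y_end[mb.off_renal])
        formed = float(y_end[mb.off_formed] + y_end[mb.off_formed + 1])
        ledger["metabolite_formed_mg"] = formed
        ledger["metabolite_formed_hepatic_mg"] = float(y_end[mb.off_formed])
        ledger["metabolite_formed_gut_mg"] = float(y_end[mb.off_formed + 1])
        ledger["metabolite_body_residual_mg"] = m_body
        ledger["metabolite_eliminated_mg"] = m_elim

    return SimulationResult(
        times_h=times, profiles=profiles, enzyme_folds=enzyme_folds,
        ledger=ledger, percentages=percentages, regimen=regimen,
        options=options, parent_name=model.parent.name,
        metabolite_name=model.metabolite.name if model.metabolite else None)


def superposition_check(regimen_multi: Regimen, regimen_single: Regimen,
                        parent: CompoundParameters,
                        metabolite: Optional[CompoundParameters] = None,
                        physiology: Optional[Physiology] = None,
                        options: SimulationOptions = SimulationOptions(induction=False),
                        ) -> float:
    """Max relative deviation of a multi-dose profile from dose superposition.

    The single-dose plasma profile is time-shifted to every dose time of the
    multiple-dose regimen and summed; the deviation is normalized by the peak
    of the superposed profile.  Near zero for a linear (induction-off,
    sub-saturating) system; autoinduction breaks it.
    """
    multi = simulate_pbpk(regimen_multi, parent, metabolite, physiology, options)
    single = simulate_pbpk(regimen_single, parent, metabolite, physiology, options)
    dt = options.output_dt_h
    n = len(multi.times_h)
    superposed = np.zeros(n)
    sp = single.profile("parent_plasma")
    for td in regimen_multi.dose_times():
        shift = int(round(td / dt))
        m = min(n - shift, len(sp))
        if m > 0:
            superposed[shift:shift + m] += sp[:m]
    peak = superposed.max()
    if peak <= 0:
        return 0.0
    return float(np.max(np.abs(multi.profile("parent_plasma") - superposed)) / peak)
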