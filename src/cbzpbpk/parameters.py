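"""Compound, physiology, formulation and regimen parameter sets.

All parameter files are plain YAML with units declared in the field names
(``_L_h``, ``_uM``, ``_cm_s`` ...).  Two compound files and one physiology file
ship with the package: carbamazepine (CBZ), its active epoxide metabolite
(CBZ-E), and a reference 30-year-old 75-kg male.  Everything is
schema-validated through pydantic before a simulation is assembled, so a bad
configuration fails before any ODE work starts.
"""

from __future__ import annotations

import math
from enum import Enum
from importlib import resources
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

GUT_ENZYMES = ("CYP3A4", "UGT2B7")  # only these are expressed at relevant gut levels


class ConfigurationError(ValueError):
    """Raised when a parameter set violates a model invariant."""


class EnzymePathway(BaseModel):
    """One saturable metabolic pathway (enzyme -> product)."""

    model_config = ConfigDict(frozen=True)

    enzyme: str
    product: Optional[str] = None
    Km_uM: float = Field(gt=0)
    Vmax: float = Field(ge=0)
    vmax_unit: str = "pmol/min/pmol"  # or "pmol/min/mg" for UGTs
    sites: tuple[str, ...] = ("liver",)

    @model_validator(mode="after")
    def _check_sites(self) -> "EnzymePathway":
        for site in self.sites:
            if site not in ("liver", "gut"):
                raise ConfigurationError(f"unknown pathway site {site!r}")
        if "gut" in self.sites and self.enzyme not in GUT_ENZYMES:
            raise ConfigurationError(
                f"{self.enzyme} cannot be placed in the gut; only "
                f"{GUT_ENZYMES} have relevant intestinal expression"
            )
        return self


class SolubilityPoint(BaseModel):
    model_config = ConfigDict(frozen=True)

    medium: str
    pH: float
    bile_salt_mM: float = Field(ge=0)
    solubility_mg_ml: float = Field(gt=0)


class InductionParams(BaseModel):
    """Emax induction parameters for one enzyme (in-vitro total-medium EC50)."""

    model_config = ConfigDict(frozen=True)

    Emax: float = Field(ge=0)
    EC50_uM: float = Field(gt=0)


class WeibullParams(BaseModel):
    """Weibull in-vivo release profile for controlled-release/enteric forms."""

    model_config = ConfigDict(frozen=True)

    T_h: float = Field(ge=0)
    Max_pct: float = Field(gt=0, le=100)
    A_hb: float = Field(gt=0)
    b: float = Field(gt=0)
    b_fed: Optional[float] = None

    def shape(self, fed: bool) -> float:
        if fed and self.b_fed is not None:
            return self.b_fed
        return self.b


class FormKind(str, Enum):
    solution = "solution"
    suspension = "suspension"
    IR_tablet = "IR_tablet"
    CR_tablet = "CR_tablet"
    CR_capsule = "CR_capsule"
    enteric_tablet = "enteric_tablet"


_PARTICLE_FORMS = {FormKind.suspension, FormKind.IR_tablet}
_WEIBULL_FORMS = {FormKind.CR_tablet, FormKind.CR_capsule, FormKind.enteric_tablet}


class Formulation(BaseModel):
    model_config = ConfigDict(frozen=True)

    form: FormKind
    particle_density_g_ml: Optional[float] = Field(default=None, gt=0)
    mean_particle_radius_um: Optional[float] = Field(default=None, gt=0)
    radius_sd_um: Optional[float] = Field(default=None, ge=0)
    n_bins: int = Field(default=1, ge=1)
    weibull: Optional[WeibullParams] = None

    @model_validator(mode="after")
    def _check_required(self) -> "Formulation":
        if self.form in _PARTICLE_FORMS:
            if self.particle_density_g_ml is None or self.mean_particle_radius_um is None:
                raise ConfigurationError(f"{self.form.value} requires particle fields")
        if self.form in _WEIBULL_FORMS and self.weibull is None:
            raise ConfigurationError(f"{self.form.value} requires Weibull parameters")
        return self

    def particle_bins(self) -> tuple[list[float], list[float]]:
        """Initial bin radii (um) and dose-mass fractions.

        Bins span mean +/- 2 SD of a normal radius distribution with the bin
        mass fraction proportional to the normal density at the bin centre.
        """
        if self.form not in _PARTICLE_FORMS:
            raise ConfigurationError(f"{self.form.value} has no particle bins")
        r0, sd, n = self.mean_particle_radius_um, self.radius_sd_um or 0.0, self.n_bins
        if n == 1 or sd == 0.0:
            return [r0], [1.0]
        radii = [r0 + sd * (-2.0 + 4.0 * i / (n - 1)) for i in range(n)]
        radii = [max(r, 0.05 * r0) for r in radii]
        weights = [math.exp(-0.5 * ((r - r0) / sd) ** 2) for r in radii]
        total = sum(weights)
        return radii, [w / total for w in weights]


class CompoundParameters(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    MW_g_mol: float = Field(gt=0)
    logP: float
    pKa: float
    ionization: str = "neutral"
    fu_p: float = Field(gt=0, le=1)
    Rbp: float = Field(gt=0)
    Peff_cm_s: float = Field(gt=0)
    diffusion_coeff_cm2_s: float = Field(gt=0)
    solubility_points: tuple[SolubilityPoint, ...]
    CL_int_liver_unbound_L_h: float = Field(default=0.0, ge=0)
    CL_hepatic_L_h: Optional[float] = Field(default=None, gt=0)
    CL_renal_filt_L_h: float = Field(default=0.0, ge=0)
    pathways: tuple[EnzymePathway, ...] = ()
    induction: dict[str, InductionParams] = {}
    formulations: dict[str, Formulation] = {}

    @model_validator(mode="after")
    def _check(self) -> "CompoundParameters":
        if not self.solubility_points:
            raise ConfigurationError("at least one solubility point is required")
        return self

    def formulation(self, form: FormKind | str) -> Formulation:
        key = form.value if isinstance(form, FormKind) else form
        if key not in self.formulations:
            raise ConfigurationError(f"{self.name} has no {key!r} formulation block")
        return self.formulations[key]

    def with_updates(self, **updates) -> "CompoundParameters":
        """Return a copy with top-level fields replaced (used by fitting)."""
        return self.model_copy(update=updates)


class TissueData(BaseModel):
    model_config = ConfigDict(frozen=True)

    volume_L: float = Field(gt=0)
    flow_L_h: float = Field(gt=0)
    f_ew: float = Field(ge=0, le=1)
    f_iw: float = Field(ge=0, le=1)
    f_nl: float = Field(ge=0, le=1)
    f_np: float = Field(ge=0, le=1)
    pr_ratio: float = Field(ge=0)


class EnzymePool(BaseModel):
    model_config = ConfigDict(frozen=True)

    amount_pmol: Optional[float] = Field(default=None, gt=0)
    amount_mg_protein: Optional[float] = Field(default=None, gt=0)
    kdeg_1_h: float = Field(gt=0)

    def amount(self, unit_basis: str) -> float:
        if unit_basis.endswith("/pmol"):
            if self.amount_pmol is None:
                raise ConfigurationError("pathway needs a pmol enzyme amount")
            return self.amount_pmol
        if unit_basis.endswith("/mg"):
            if self.amount_mg_protein is None:
                raise ConfigurationError("pathway needs a mg-protein amount")
            return self.amount_mg_protein
        raise ConfigurationError(f"unknown Vmax unit basis {unit_basis!r}")


class GutCompartment(BaseModel):
    model_config = ConfigDict(frozen=True)

    length_cm: float = Field(gt=0)
    radius_cm: float = Field(gt=0)
    fluid_volume_ml: float = Field(gt=0)
    pH: float
    bile_salt_fasted_mM: float = Field(ge=0)
    bile_salt_fed_mM: float = Field(ge=0)
    asf: float = Field(ge=0)
    transit_time_h: Optional[float] = Field(default=None, gt=0)
    enterocyte_volume_ml: Optional[float] = Field(default=None, gt=0)
    villous_flow_L_h: Optional[float] = Field(default=None, gt=0)

    def bile_salt_mM(self, fed: bool) -> float:
        return self.bile_salt_fed_mM if fed else self.bile_salt_fasted_mM


GUT_SEGMENTS = (
    "stomach", "duodenum", "jejunum1", "jejunum2",
    "ileum1", "ileum2", "ileum3", "caecum", "colon",
)
SMALL_INTESTINE = GUT_SEGMENTS[1:7]
ABSORBING_SEGMENTS = GUT_SEGMENTS[1:]  # no stomach absorption

TISSUES = (
    "lung", "adipose", "muscle", "liver", "kidney", "heart",
    "brain", "skin", "spleen", "gut", "bone", "rest",
)


class Physiology(BaseModel):
    model_config = ConfigDict(frozen=True)

    body_weight_kg: float = Field(gt=0)
    hematocrit: float = Field(gt=0, lt=1)
    GFR_L_h: float = Field(gt=0)
    hepatic_blood_flow_L_h: float = Field(gt=0)
    blood: dict[str, float]
    tissues: dict[str, TissueData]
    plasma_composition: dict[str, float]
    enzymes: dict[str, dict[str, EnzymePool]]
    gut_enzyme_distribution: dict[str, float]
    acat: dict

    @model_validator(mode="after")
    def _check(self) -> "Physiology":
        missing = [t for t in TISSUES if t not in self.tissues]
        if missing:
            raise ConfigurationError(f"physiology missing tissues: {missing}")
        qh = self.tissues["liver"].flow_L_h + self.tissues["gut"].flow_L_h \
            + self.tissues["spleen"].flow_L_h
        if abs(qh - self.hepatic_blood_flow_L_h) > 1e-6 * qh:
            raise ConfigurationError(
                "hepatic blood flow must equal hepatic artery + portal "
                f"(gut+spleen) flow; got {self.hepatic_blood_flow_L_h} vs {qh}"
            )
        si_total = sum(self.gut(seg).transit_time_h for seg in SMALL_INTESTINE)
        if abs(si_total - 3.3) > 0.05:
            raise ConfigurationError(
                f"small-intestinal transit must total ~3.3 h, got {si_total:.3f}"
            )
        return self

    def gut(self, segment: str) -> GutCompartment:
        return GutCompartment.model_validate(self.acat[segment])

    def gastric_half_time_h(self, fed: bool) -> float:
        key = "gastric_half_time_fed_h" if fed else "gastric_half_time_fasted_h"
        return float(self.acat[key])

    def enzyme_pool(self, site: str, enzyme: str) -> EnzymePool:
        try:
            return self.enzymes[site][enzyme]
        except KeyError as exc:
            raise ConfigurationError(f"no {enzyme} abundance for site {site!r}") from exc

    def cardiac_output_L_h(self) -> float:
        return self.tissues["lung"].flow_L_h


class Route(str, Enum):
    oral = "oral"
    iv_infusion = "iv_infusion"


class Regimen(BaseModel):
    """Dosing protocol: route, formulation, dose events and horizon."""

    model_config = ConfigDict(frozen=True)

    route: Route
    dose_mg: float = Field(ge=0)
    formulation: Optional[FormKind] = None
    n_doses: int = Field(default=1, ge=1)
    interval_h: float = Field(default=24.0, gt=0)
    infusion_duration_h: float = Field(default=0.25, gt=0)
    fed: bool = False
    simulation_horizon_h: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "Regimen":
        if self.route == Route.oral and self.formulation is None:
            raise ConfigurationError("oral regimens need a formulation")
        return self

    @property
    def horizon_h(self) -> float:
        if self.simulation_horizon_h is not None:
            return self.simulation_horizon_h
        if self.n_doses == 1:
            return 96.0
        return (self.n_doses - 1) * self.interval_h + 96.0

    def dose_times(self) -> list[float]:
        return [i * self.interval_h for i in range(self.n_doses)]


def _load_packaged_yaml(filename: str) -> dict:
    text = resources.files("cbzpbpk").joinpath("data", filename).read_text()
    return yaml.safe_load(text)


def load_compound(source: str) -> CompoundParameters:
    """Load a compound parameter file.

    ``source`` is either a shipped compound name (``"carbamazepine"``,
    ``"carbamazepine_epoxide"``) or a path to a YAML file.
    """
    if source in ("carbamazepine", "cbz"):
        raw = _load_packaged_yaml("carbamazepine.yaml")
    elif source in ("carbamazepine_epoxide", "cbz-e", "cbze"):
        raw = _load_packaged_yaml("carbamazepine_epoxide.yaml")
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    forms = {
        key: Formulation.model_validate({"form": key, **(block or {})})
        for key, block in (raw.pop("formulations", {}) or {}).items()
    }
    return CompoundParameters.model_validate({**raw, "formulations": forms})


def load_physiology(source: str = "adult_male") -> Physiology:
    if source == "adult_male":
        raw = _load_packaged_yaml("physiology_adult_male.yaml")
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    return Physiology.model_validate(raw)
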