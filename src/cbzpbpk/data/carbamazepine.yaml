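# Carbamazepine (CBZ) drug-dependent model inputs.
# Units are declared in the field names; concentrations derived from Km are in uM.
name: carbamazepine
MW_g_mol: 236.27
logP: 2.0
pKa: 10.86
ionization: neutral        # amide, pKa 10.86 -> effectively un-ionized at physiologic pH
fu_p: 0.225                # fraction unbound in plasma
Rbp: 0.9                   # blood:plasma concentration ratio
Peff_cm_s: 4.3e-4
diffusion_coeff_cm2_s: 0.86e-5
solubility_points:
  - {medium: SGF,     pH: 1.2, bile_salt_mM: 0.0,  solubility_mg_ml: 0.236}
  - {medium: aqueous, pH: 6.5, bile_salt_mM: 0.0,  solubility_mg_ml: 0.127}
  - {medium: FaSSIF,  pH: 6.8, bile_salt_mM: 3.0,  solubility_mg_ml: 0.283}
  - {medium: FeSSIF,  pH: 6.8, bile_salt_mM: 15.0, solubility_mg_ml: 0.52}
CL_int_liver_unbound_L_h: 3.316   # linear unspecified hepatic intrinsic clearance (unbound)
CL_renal_filt_L_h: 0.0084         # applied to unbound plasma concentration
pathways:
  - {enzyme: CYP2C8,  product: CBZ-E,   Km_uM: 757,  Vmax: 0.669, vmax_unit: pmol/min/pmol, sites: [liver]}
  - {enzyme: CYP3A4,  product: CBZ-E,   Km_uM: 248,  Vmax: 0.75,  vmax_unit: pmol/min/pmol, sites: [liver, gut]}
  - {enzyme: CYP3A5,  product: CBZ-E,   Km_uM: 2300, Vmax: 10.0,  vmax_unit: pmol/min/pmol, sites: [liver]}
  - {enzyme: CYP2B6,  product: OH-CBZ,  Km_uM: 420,  Vmax: 0.429, vmax_unit: pmol/min/pmol, sites: [liver]}
  - {enzyme: CYP3A4,  product: OH-CBZ,  Km_uM: 282,  Vmax: 0.164, vmax_unit: pmol/min/pmol, sites: [liver, gut]}
  - {enzyme: UGT2B7,  product: CBZ-glu, Km_uM: 214,  Vmax: 0.79,  vmax_unit: pmol/min/mg,   sites: [liver, gut]}
# Emax induction parameters (in-vitro total-medium EC50, used directly)
induction:
  CYP3A4: {Emax: 10.0,  EC50_uM: 22.0}
  CYP3A5: {Emax: 2.95,  EC50_uM: 142.0}
  CYP2C8: {Emax: 3.49,  EC50_uM: 22.0}
  CYP2B6: {Emax: 10.14, EC50_uM: 26.0}
  CYP2C9: {Emax: 1.83,  EC50_uM: 22.0}
formulations:
  solution: {}
  suspension:
    particle_density_g_ml: 1.2
    mean_particle_radius_um: 25.0
    radius_sd_um: 0.0
    n_bins: 1
  IR_tablet:
    particle_density_g_ml: 1.5
    mean_particle_radius_um: 60.0
    radius_sd_um: 20.0
    n_bins: 5
  CR_tablet:
    particle_density_g_ml: 1.5
    weibull: {T_h: 0.5, Max_pct: 95.0, A_hb: 3.0, b: 0.45, b_fed: 1.0}
  CR_capsule:
    particle_density_g_ml: 1.5
    weibull: {T_h: 0.7, Max_pct: 100.0, A_hb: 4.7, b: 0.8, b_fed: 1.4}
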