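# Carbamazepine-10,11-epoxide (CBZ-E) drug-dependent model inputs.
name: carbamazepine-10,11-epoxide
MW_g_mol: 252.27
logP: 1.4
pKa: 11.03
ionization: neutral
fu_p: 0.518
Rbp: 1.53
Peff_cm_s: 50.0e-4
diffusion_coeff_cm2_s: 0.87e-5
solubility_points:
  - {medium: water, pH: 7.0, bile_salt_mM: 0.0, solubility_mg_ml: 1.34}
# EPHX1 elimination lumped into a linear hepatic organ clearance (back-calculated);
# converted to unbound intrinsic clearance against the physiology's hepatic blood flow.
CL_hepatic_L_h: 4.86
CL_renal_filt_L_h: 0.14
pathways: []
induction: {}
formulations:
  solution: {}
  suspension:
    particle_density_g_ml: 1.2
    mean_particle_radius_um: 25.0
    radius_sd_um: 0.0
    n_bins: 1
  enteric_tablet:
    particle_density_g_ml: 1.2
    weibull: {T_h: 2.0, Max_pct: 84.0, A_hb: 1.0, b: 0.75, b_fed: 0.75}
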