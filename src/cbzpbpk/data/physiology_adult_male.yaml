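# Reference physiology: healthy 30-year-old, 75 kg European male.
# Tissue volumes and blood flows follow ICRP-89 style adult-male reference values;
# composition fractions (extracellular/intracellular water, neutral lipid, neutral
# phospholipid, tissue:plasma albumin ratio) follow the published Rodgers-Rowland
# tables used for composition-based partitioning.
body_weight_kg: 75.0
hematocrit: 0.45
GFR_L_h: 7.2
hepatic_blood_flow_L_h: 90.0     # pinned: hepatic artery + portal vein, whole blood

blood:
  volume_total_L: 5.6
  volume_venous_L: 3.73          # includes venous return pool
  volume_arterial_L: 1.87

# flow_L_h is whole-blood flow; liver flow is the arterial (hepatic artery) share only,
# portal inflow arrives via gut and spleen venous outflow plus absorbed drug.
tissues:
  lung:    {volume_L: 0.53,  flow_L_h: 340.0, f_ew: 0.336, f_iw: 0.446, f_nl: 0.0219, f_np: 0.0128, pr_ratio: 0.212}
  adipose: {volume_L: 14.5,  flow_L_h: 15.6,  f_ew: 0.135, f_iw: 0.017, f_nl: 0.853,  f_np: 0.0016, pr_ratio: 0.037}
  muscle:  {volume_L: 29.0,  flow_L_h: 45.0,  f_ew: 0.118, f_iw: 0.630, f_nl: 0.0100, f_np: 0.0072, pr_ratio: 0.064}
  liver:   {volume_L: 1.80,  flow_L_h: 27.0,  f_ew: 0.161, f_iw: 0.573, f_nl: 0.0135, f_np: 0.0238, pr_ratio: 0.086}
  kidney:  {volume_L: 0.31,  flow_L_h: 74.0,  f_ew: 0.273, f_iw: 0.483, f_nl: 0.0121, f_np: 0.0240, pr_ratio: 0.130}
  heart:   {volume_L: 0.33,  flow_L_h: 16.0,  f_ew: 0.320, f_iw: 0.456, f_nl: 0.0115, f_np: 0.0166, pr_ratio: 0.157}
  brain:   {volume_L: 1.45,  flow_L_h: 42.0,  f_ew: 0.162, f_iw: 0.620, f_nl: 0.0392, f_np: 0.0015, pr_ratio: 0.048}
  skin:    {volume_L: 3.30,  flow_L_h: 18.0,  f_ew: 0.382, f_iw: 0.291, f_nl: 0.0284, f_np: 0.0111, pr_ratio: 0.277}
  spleen:  {volume_L: 0.15,  flow_L_h: 10.5,  f_ew: 0.207, f_iw: 0.579, f_nl: 0.0077, f_np: 0.0113, pr_ratio: 0.097}
  gut:     {volume_L: 1.65,  flow_L_h: 52.5,  f_ew: 0.282, f_iw: 0.475, f_nl: 0.0487, f_np: 0.0163, pr_ratio: 0.158}
  bone:    {volume_L: 10.5,  flow_L_h: 15.0,  f_ew: 0.100, f_iw: 0.346, f_nl: 0.0174, f_np: 0.0016, pr_ratio: 0.100}
  rest:    {volume_L: 3.00,  flow_L_h: 24.4,  f_ew: 0.200, f_iw: 0.550, f_nl: 0.0400, f_np: 0.0100, pr_ratio: 0.100}

plasma_composition: {f_water: 0.945, f_nl: 0.0023, f_np: 0.0013}

# Whole-organ enzyme amounts. CYP amounts in pmol (specific content x 40 mg microsomal
# protein per g liver x 1800 g liver); UGT2B7 capacity is carried as mg microsomal
# protein because its Vmax basis is per mg protein.
enzymes:
  liver:
    CYP3A4: {amount_pmol: 9.864e6, kdeg_1_h: 0.0193}   # 137 pmol/mg
    CYP3A5: {amount_pmol: 1.728e6, kdeg_1_h: 0.0193}   # 24 pmol/mg
    CYP2C8: {amount_pmol: 1.728e6, kdeg_1_h: 0.0193}   # 24 pmol/mg
    CYP2B6: {amount_pmol: 1.224e6, kdeg_1_h: 0.0193}   # 17 pmol/mg
    CYP2C9: {amount_pmol: 5.256e6, kdeg_1_h: 0.0193}   # 73 pmol/mg
    UGT2B7: {amount_mg_protein: 7.2e4, kdeg_1_h: 0.0193}
  gut:
    CYP3A4: {amount_pmol: 7.05e4, kdeg_1_h: 0.0301}    # ~70 nmol whole small intestine
    UGT2B7: {amount_mg_protein: 3.0e3, kdeg_1_h: 0.0301}

# Small-intestinal axial distribution of gut enzymes (fraction per segment).
gut_enzyme_distribution:
  duodenum: 0.11
  jejunum1: 0.32
  jejunum2: 0.28
  ileum1:   0.15
  ileum2:   0.09
  ileum3:   0.05
  caecum:   0.0
  colon:    0.0

# Compartmental absorption-transit geometry (fasted defaults).
# transit_time_h: mean residence time (first-order); small-intestine times sum to 3.3 h.
# fluid_volume_ml: resident luminal fluid available for dissolution.
# asf: regional absorption scale factor multiplying 2*Peff/R.
acat:
  gastric_half_time_fasted_h: 0.25
  gastric_half_time_fed_h: 1.0
  stomach:  {length_cm: 28.0, radius_cm: 4.80, fluid_volume_ml: 250.0, pH: 1.3, bile_salt_fasted_mM: 0.0, bile_salt_fed_mM: 0.0,  asf: 0.0}
  duodenum: {length_cm: 14.1, radius_cm: 1.53, fluid_volume_ml: 53.0,  pH: 6.0, bile_salt_fasted_mM: 2.8, bile_salt_fed_mM: 15.0, asf: 3.2,  transit_time_h: 0.26, enterocyte_volume_ml: 24.0, villous_flow_L_h: 4.1}
  jejunum1: {length_cm: 51.4, radius_cm: 1.45, fluid_volume_ml: 177.0, pH: 6.2, bile_salt_fasted_mM: 2.8, bile_salt_fed_mM: 15.0, asf: 2.6,  transit_time_h: 0.93, enterocyte_volume_ml: 85.0, villous_flow_L_h: 9.4}
  jejunum2: {length_cm: 51.4, radius_cm: 1.29, fluid_volume_ml: 139.0, pH: 6.4, bile_salt_fasted_mM: 2.6, bile_salt_fed_mM: 12.0, asf: 2.0,  transit_time_h: 0.74, enterocyte_volume_ml: 85.0, villous_flow_L_h: 7.3}
  ileum1:   {length_cm: 41.1, radius_cm: 1.13, fluid_volume_ml: 86.0,  pH: 6.6, bile_salt_fasted_mM: 2.4, bile_salt_fed_mM: 10.0, asf: 1.2,  transit_time_h: 0.58, enterocyte_volume_ml: 68.0, villous_flow_L_h: 5.2}
  ileum2:   {length_cm: 41.1, radius_cm: 0.98, fluid_volume_ml: 64.0,  pH: 6.9, bile_salt_fasted_mM: 2.2, bile_salt_fed_mM: 8.0,  asf: 0.7,  transit_time_h: 0.42, enterocyte_volume_ml: 68.0, villous_flow_L_h: 3.7}
  ileum3:   {length_cm: 41.1, radius_cm: 0.82, fluid_volume_ml: 46.0,  pH: 7.4, bile_salt_fasted_mM: 2.0, bile_salt_fed_mM: 6.0,  asf: 0.4,  transit_time_h: 0.37, enterocyte_volume_ml: 68.0, villous_flow_L_h: 2.6}
  caecum:   {length_cm: 13.8, radius_cm: 3.39, fluid_volume_ml: 3.0,   pH: 6.4, bile_salt_fasted_mM: 0.0, bile_salt_fed_mM: 0.0,  asf: 0.18, transit_time_h: 4.5, enterocyte_volume_ml: 30.0, villous_flow_L_h: 2.1}
  colon:    {length_cm: 28.4, radius_cm: 2.41, fluid_volume_ml: 3.0,   pH: 6.8, bile_salt_fasted_mM: 0.0, bile_salt_fed_mM: 0.0,  asf: 0.18, transit_time_h: 13.5, enterocyte_volume_ml: 60.0, villous_flow_L_h: 2.1}
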