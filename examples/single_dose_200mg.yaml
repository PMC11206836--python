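# 200 mg carbamazepine immediate-release tablet, fasted single dose.
compound: carbamazepine
metabolite: carbamazepine_epoxide
physiology: adult_male
induction: false
regimen:
  route: oral
  dose_mg: 200
  formulation: IR_tablet
  n_doses: 1
  simulation_horizon_h: 96
scan:
  doses: [50, 100, 200, 400, 600, 800]
  route: oral
  regimen_type: single
  formulation: IR_tablet
synth:
  noise_cv: 0.2
  lloq: 0.01
sensitivity:
  parameter: fu_p
ddi:
  victim: quinidine
  victim_dose_mg: 200
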