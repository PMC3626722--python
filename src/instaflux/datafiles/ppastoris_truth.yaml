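# Synthetic reference flux distribution (mmol/gCDW/h) used as the default
# ground truth for simulated datasets and worked examples.  It satisfies
# S.v = 0 and the shipped constraint set exactly and mirrors the headline
# physiology of glucose-methanol co-assimilation: ~55% of the Glc6P supply
# enters the oxidative PPP, ~54% of methanol is dissimilated to CO2,
# trehalose recycling ~1.5% of glucose uptake, 1.2 mmol/gCDW/h unlabelled
# pyruvate exchange.  This is a demo setting, not a fitted result.
net:
  upt_glc: 0.71
  hxk: 0.732
  upt_metoh: 0.94
  pgi: 0.2189
  pmi: 0.035
  pfk: 0.2040333333
  fbpase: 0.05
  fba: 0.1540333333
  tpi: 0.5864333333
  gapdh: 1.1549333333
  pgm: 1.1099333333
  eno: 1.1099333333
  pyk: 1.1099333333
  pyrt: 0.4699333333
  pdh: 0.4699333333
  pdc: 0.20
  acs: 0.20
  emp11C: 1.2
  emp11D: 1.2
  cs: 0.4899333333
  acn: 0.4899333333
  idh: 0.4899333333
  akgdh: 0.2899333333
  tca4a: 0.1449666667
  tca4b: 0.1449666667
  tca5fa: 0.2799666667
  tca5fb: 0.2799666667
  tca5ba: 0.125
  tca5bb: 0.125
  mdh: 0.3099333333
  pyc: 0.33
  aa_glu: 0.200
  aa_asp: 0.150
  aa_ala: 0.0
  tca8: 0.02
  zwf: 0.4026
  gnd: 0.4026
  rpi: 0.0000666667
  rpe: 0.4025333333
  tkt1: -0.0119333333
  tal: -0.0119333333
  tkt2: -0.0179333333
  met1: 0.94
  met2a: 0.2162
  met2b: 0.2162
  met3: 0.4324
  met4: 0.5076
  met5: 0.5076
  tre1: 0.01525
  tre2: 0.01525
  tre3: 0.01525
  tre4: 0.011
  sec_treh: 0.00425
  bm_glc6p: 0.080
  bm_man6p: 0.035
  bm_rib5p: 0.012
  bm_e4p: 0.006
  bm_pg3: 0.045
  bm_pyr: 0.110
  bm_accoa: 0.180
  bm_glu: 0.200
  bm_asp: 0.130
  co2_out: 2.03
exchange:
  pgi: 2.0
  pmi: 0.08
  fba: 0.6
  tpi: 1.5
  gapdh: 0.8
  pgm: 1.2
  eno: 1.5
  mdh: 1.0
  aa_glu: 0.5
  aa_asp: 0.8
  aa_ala: 0.3
  rpi: 0.3
  rpe: 0.3
  tkt1: 0.15
  tal: 0.12
  tkt2: 0.15
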