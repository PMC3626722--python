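# Synthetic stand-in thermodynamic inputs for the NET analysis of the
# glucose-methanol network (the study's Gibbs-energy database is not
# redistributable).  Transformed standard reaction Gibbs energies in
# kJ/mol at ionic strength 0.15 M and three intracellular pH scenarios;
# cofactor-dependent dehydrogenases release one proton, so their dgr0
# falls by ~5.7 kJ/mol per pH unit.  ATP/ADP and water are folded into
# the transformed dgr0; protons and water are excluded from stoichiometry.
# Directions are the net flux signs of the reference flux distribution.
temperature: 298.15
ionic_strength: 0.15
cell_volume: 1.7
reactions:
  pgi:    {stoich: {Glc6P: -1, Fru6P: 1}, dgr0: {'7.0': 2.5, '7.2': 2.5, '7.5': 2.5}}
  pmi:    {stoich: {Fru6P: -1, Man6P: 1}, dgr0: {'7.0': -1.0, '7.2': -1.0, '7.5': -1.0}}
  pfk:    {stoich: {Fru6P: -1, FBP: 1}, dgr0: {'7.0': -16.0, '7.2': -16.0, '7.5': -16.0}}
  fbpase: {stoich: {FBP: -1, Fru6P: 1}, dgr0: {'7.0': -11.0, '7.2': -11.0, '7.5': -11.0}}
  fba:    {stoich: {FBP: -1, DHAP: 1, GA3P: 1}, dgr0: {'7.0': 20.5, '7.2': 20.5, '7.5': 20.5}}
  tpi:    {stoich: {DHAP: -1, GA3P: 1}, dgr0: {'7.0': 5.5, '7.2': 5.5, '7.5': 5.5}}
  eno:    {stoich: {PG2: -1, PEP: 1}, dgr0: {'7.0': -4.0, '7.2': -4.0, '7.5': -4.0}}
  fmh:    {stoich: {FUM: -1, MAL: 1}, dgr0: {'7.0': -3.6, '7.2': -3.6, '7.5': -3.6}}
  rpi:    {stoich: {Rul5P: -1, Rib5P: 1}, dgr0: {'7.0': -2.0, '7.2': -2.0, '7.5': -2.0}}
  rpe:    {stoich: {Rul5P: -1, Xul5P: 1}, dgr0: {'7.0': -3.4, '7.2': -3.4, '7.5': -3.4}}
  tkt1:   {stoich: {Xul5P: -1, Rib5P: -1, Sed7P: 1, GA3P: 1}, dgr0: {'7.0': 4.7, '7.2': 4.7, '7.5': 4.7}}
  tal:    {stoich: {Sed7P: -1, GA3P: -1, E4P: 1, Fru6P: 1}, dgr0: {'7.0': -2.5, '7.2': -2.5, '7.5': -2.5}}
  tkt2:   {stoich: {Xul5P: -1, E4P: -1, Fru6P: 1, GA3P: 1}, dgr0: {'7.0': -1.5, '7.2': -1.5, '7.5': -1.5}}
  # channelled transketolase/transaldolase variant replacing tkt1 + tal
  tktal:  {stoich: {Xul5P: -1, Rib5P: -1, Fru6P: 1, E4P: 1}, dgr0: {'7.0': 2.2, '7.2': 2.2, '7.5': 2.2}}
  # NAD-coupled dehydrogenases (one proton released)
  mdh_nad: {stoich: {MAL: -1, NAD: -1, OAA: 1, NADH: 1}, dgr0: {'7.0': 29.14, '7.2': 28.0, '7.5': 26.29}}
  fld_nad: {stoich: {Form: -1, NAD: -1, FOR: 1, NADH: 1}, dgr0: {'7.0': -38.9, '7.2': -40.0, '7.5': -41.7}}
directions:
  pgi: 1
  pmi: 1
  pfk: 1
  fbpase: 1
  fba: 1
  tpi: 1
  eno: 1
  fmh: 1
  rpi: 1
  rpe: 1
  tkt1: -1
  tal: -1
  tkt2: -1
  mdh_nad: 1
  fld_nad: 1
directions_channelled:
  pgi: 1
  pmi: 1
  pfk: 1
  fbpase: 1
  fba: 1
  tpi: 1
  eno: 1
  fmh: 1
  rpi: 1
  rpe: 1
  tktal: -1
  tkt2: -1
  mdh_nad: 1
  fld_nad: 1
default_ranges_mm: [0.001, 10.0]
cofactor_ranges_mm:
  NAD: [0.0001, 5.0]
  NADH: [0.0001, 5.0]
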