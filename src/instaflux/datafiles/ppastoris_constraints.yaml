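# Seventeen constrained fluxes (mmol/gCDW/h):
#  - three measured exchange rates (glucose uptake, methanol uptake, CER)
#  - nine biomass precursor drains from biomass composition x growth rate
#  - four 1:1 splits for fluxes with symmetric products (met2, tca4,
#    tca5 forward and backward)
#  - the unlabelled pyruvate source/sink tie emp11C == emp11D
upt_glc: 0.71
upt_metoh: 0.94
co2_out: 2.03
bm_glc6p: 0.080
bm_man6p: 0.035
bm_rib5p: 0.012
bm_e4p: 0.006
bm_pg3: 0.045
bm_pyr: 0.110
bm_accoa: 0.180
bm_glu: 0.200
bm_asp: 0.130
met2a: == met2b
tca4a: == tca4b
tca5fa: == tca5fb
tca5ba: == tca5bb
emp11C: == emp11D
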