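rate,value,sd
q_glucose,-0.71,0.01
q_methanol,-0.94,0.02
q_o2,-2.57,0.03
q_co2,2.03,0.03
q_biomass,3.14,0.04
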