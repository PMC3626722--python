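# Measured MS fragments (synthetic stand-in for the study's LC/GC-MS list):
# 15 fragments, 80 mass-isotopomer fractions per time point.  Carbon
# positions are 1-based biochemical numbering; Glc6P is observed through
# its C3-C6 fragment.  Ion formulas are used only for natural-abundance
# correction of raw data and describe the carbon backbone here because the
# simulated data are already abundance-corrected.
glc6p_c3c6: {metabolite: Glc6P, positions: [3, 4, 5, 6], formula: C4H9O7P}
fru6p:      {metabolite: Fru6P, positions: [1, 2, 3, 4, 5, 6], formula: C6H13O9P}
fbp:        {metabolite: FBP, positions: [1, 2, 3, 4, 5, 6], formula: C6H14O12P2}
dhap:       {metabolite: DHAP, positions: [1, 2, 3], formula: C3H7O6P}
ga3p:       {metabolite: GA3P, positions: [1, 2, 3], formula: C3H7O6P}
pep:        {metabolite: PEP, positions: [1, 2, 3], formula: C3H5O6P}
pyr:        {metabolite: Pyr_c, positions: [1, 2, 3], formula: C3H4O3}
ala:        {metabolite: Ala, positions: [1, 2, 3], formula: C3H7NO2}
glu:        {metabolite: Glu, positions: [1, 2, 3, 4, 5], formula: C5H9NO4}
asp:        {metabolite: Asp, positions: [1, 2, 3, 4], formula: C4H7NO4}
mal:        {metabolite: MAL, positions: [1, 2, 3, 4], formula: C4H6O5}
succ:       {metabolite: SUCC, positions: [1, 2, 3, 4], formula: C4H6O4}
xul5p:      {metabolite: Xul5P, positions: [1, 2, 3, 4, 5], formula: C5H11O8P}
rib5p:      {metabolite: Rib5P, positions: [1, 2, 3, 4, 5], formula: C5H11O8P}
sed7p:      {metabolite: Sed7P, positions: [1, 2, 3, 4, 5, 6, 7], formula: C7H15O10P}
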