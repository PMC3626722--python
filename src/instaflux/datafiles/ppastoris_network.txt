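# Reduced central-carbon network of P. pastoris co-assimilating glucose and
# methanol, reconstructed from the published model description: glycolysis/
# gluconeogenesis with FBPase, oxidative + non-oxidative PPP, TCA cycle,
# methanol dissimilation (Metoh -> Form -> FOR -> CO2) and assimilation
# (DAS: Form + Xul5P -> DHA + GA3P), trehalose cycling, PDH bypass,
# aKG<->Glu and OAA<->Asp exchanges, Asp lyase, an unlabelled mitochondrial
# pyruvate source/sink (emp11C/emp11D) and biomass precursor drains.
#
# 37 carbon-pool metabolites; CO2 is balanced for stoichiometry only.
# 63 reaction entries, 16 reversible: 79 fluxes including bidirectional.
# Symmetric-product fluxes (met2, tca4, tca5 fwd/bwd) appear as explicit
# a/b atom-map variants tied 1:1 in the constraint file.

@external Glcx Metohx CO2x BIOx NPyrx Trehx
@balance_only CO2

# uptake
upt_glc:   Glcx(abcdef) -> Glc(abcdef)
hxk:       Glc(abcdef) -> Glc6P(abcdef)
upt_metoh: Metohx(a) -> Metoh(a)

# glycolysis / gluconeogenesis
pgi:    Glc6P(abcdef) <-> Fru6P(abcdef)
pmi:    Fru6P(abcdef) <-> Man6P(abcdef)
pfk:    Fru6P(abcdef) -> FBP(abcdef)
fbpase: FBP(abcdef) -> Fru6P(abcdef)
fba:    FBP(abcdef) <-> DHAP(cba) + GA3P(def)
tpi:    DHAP(abc) <-> GA3P(abc)
gapdh:  GA3P(abc) <-> PG3(abc)
pgm:    PG3(abc) <-> PG2(abc)
eno:    PG2(abc) <-> PEP(abc)
pyk:    PEP(abc) -> Pyr_c(abc)
pyrt:   Pyr_c(abc) -> Pyr_m(abc)
pdh:    Pyr_m(abc) -> ACCoA_m(bc) + CO2(a)

# PDH bypass and the unlabelled pyruvate source/sink
pdc:    Pyr_c(abc) -> ACALD(bc) + CO2(a)
acs:    ACALD(ab) -> ACCoA_m(ab)
emp11C: NPyrx(abc) -> Pyr_m(abc)
emp11D: Pyr_m(abc) -> NPyrx(abc)

# TCA cycle (CIT carbons 1-4 from OAA, 5-6 from acetyl)
cs:     OAA(abcd) + ACCoA_m(ef) -> CIT(abcdef)
acn:    CIT(abcdef) -> ICIT(abcdef)
idh:    ICIT(abcdef) -> AKG(bcdef) + CO2(a)
akgdh:  AKG(abcde) -> SUCC(bcde) + CO2(a)
tca4a:  SUCC(abcd) -> FUM(abcd)
tca4b:  SUCC(abcd) -> FUM(dcba)
tca5fa: FUM(abcd) -> MAL(abcd)
tca5fb: FUM(abcd) -> MAL(dcba)
tca5ba: MAL(abcd) -> FUM(abcd)
tca5bb: MAL(abcd) -> FUM(dcba)
mdh:    MAL(abcd) <-> OAA(abcd)
pyc:    Pyr_c(abc) + CO2(d) -> OAA(abcd)

# amino-acid exchange pools and Asp lyase
aa_glu: AKG(abcde) <-> Glu(abcde)
aa_asp: OAA(abcd) <-> Asp(abcd)
aa_ala: Pyr_c(abc) <-> Ala(abc)
tca8:   Asp(abcd) -> FUM(abcd)

# pentose phosphate pathway
zwf:  Glc6P(abcdef) -> P6G(abcdef)
gnd:  P6G(abcdef) -> CO2(a) + Rul5P(bcdef)
rpi:  Rul5P(abcde) <-> Rib5P(abcde)
rpe:  Rul5P(abcde) <-> Xul5P(abcde)
tkt1: Xul5P(abcde) + Rib5P(fghij) <-> Sed7P(abfghij) + GA3P(cde)
tal:  Sed7P(abcdefg) + GA3P(hij) <-> E4P(defg) + Fru6P(abchij)
tkt2: Xul5P(abcde) + E4P(fghi) <-> Fru6P(abfghi) + GA3P(cde)

# methanol utilisation
met1:  Metoh(a) -> Form(a)
met2a: Form(a) + Xul5P(bcdef) -> DHA(abc) + GA3P(def)
met2b: Form(a) + Xul5P(bcdef) -> DHA(cba) + GA3P(def)
met3:  DHA(abc) -> DHAP(abc)
met4:  Form(a) -> FOR(a)
met5:  FOR(a) -> CO2(a)

# trehalose cycling and secretion
tre1:     Glc6P(abcdef) -> G1P(abcdef)
tre2:     G1P(abcdef) + Glc6P(ghijkl) -> T6P(abcdefghijkl)
tre3:     T6P(abcdefghijkl) -> Treh(abcdefghijkl)
tre4:     Treh(abcdefghijkl) -> Glc(abcdef) + Glc(ghijkl)
sec_treh: Treh(abcdefghijkl) -> Trehx(abcdefghijkl)

# biomass precursor drains (growth-rate-fixed)
bm_glc6p: Glc6P(abcdef) -> BIOx(abcdef)
bm_man6p: Man6P(abcdef) -> BIOx(abcdef)
bm_rib5p: Rib5P(abcde) -> BIOx(abcde)
bm_e4p:   E4P(abcd) -> BIOx(abcd)
bm_pg3:   PG3(abc) -> BIOx(abc)
bm_pyr:   Pyr_c(abc) -> BIOx(abc)
bm_accoa: ACCoA_m(ab) -> BIOx(ab)
bm_glu:   Glu(abcde) -> BIOx(abcde)
bm_asp:   Asp(abcd) -> BIOx(abcd)

# CO2 evolution
co2_out: CO2(a) -> CO2x(a)
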