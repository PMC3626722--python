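metabolite,pool_umol_gcdw,measured
Glc6P,2.5,1
Fru6P,0.55,1
FBP,1.2,1
DHAP,0.8,1
GA3P,0.05,1
PG3,0.9,1
PG2,0.12,1
PEP,0.4,1
Pyr_c,0.5,1
Pyr_m,0.3,1
ACCoA_m,0.10,1
CIT,3.5,1
AKG,0.9,1
SUCC,0.8,1
FUM,0.4,1
MAL,1.8,1
OAA,0.05,1
Glu,150,1
Asp,8,1
Ala,20,1
Treh,25,1
Rul5P,0.12,1
Xul5P,0.18,1
Rib5P,0.3,1
Sed7P,0.5,1
E4P,0.05,1
Man6P,0.4,1
Glc,0.5,0
ACALD,0.05,0
ICIT,0.2,0
G1P,0.15,0
T6P,0.08,0
P6G,0.1,0
DHA,0.3,0
Form,0.1,0
FOR,0.5,0
Metoh,0.8,0
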