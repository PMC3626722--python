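fragment_id,time_h,m0,m1,m2,sigma_rel
b12,0.001388888888888889,0.9813957780931143,0.010731157627223358,0.007873064279662507,0.02
b12,0.002525951474970711,0.9528917575300613,0.028590312163428153,0.018517930306510586,0.02
b12,0.004593910214812832,0.8901694137694484,0.07019736604928159,0.039633220181269885,0.02
b12,0.00835487588375243,0.7769428874054463,0.13870135784508175,0.08435575474947196,0.02
b12,0.015194887964468409,0.6359209147339467,0.22932376393874548,0.1347553213273079,0.02
b12,0.027634715759421842,0.5024281769095851,0.31044578194152855,0.1871260411488863,0.02
b12,0.050258844743693715,0.3667893487137859,0.39919108778899043,0.23401956349722372,0.02
b12,0.09140501016767315,0.2649316583215579,0.4558945154234688,0.27917382625497345,0.02
b12,0.16623692658197772,0.21239767674405896,0.49535711741354144,0.29224520584239966,0.02
b12,0.30233261512392806,0.19795305740871963,0.4987202149640909,0.30332672762718943,0.02
b12,0.5498478108749073,0.19736042138483828,0.5014610854260684,0.3011784931890933,0.02
b12,1.0,0.2008693399179057,0.4989323642415353,0.300198295840559,0.02
c12,0.001388888888888889,0.9784288267819167,0.012392265260663868,0.00917890795741945,0.02
c12,0.002525951474970711,0.9462448422021305,0.03083952389033008,0.022915633907539434,0.02
c12,0.004593910214812832,0.8684416669172691,0.08247303710314217,0.04908529597958865,0.02
c12,0.00835487588375243,0.7192233231564047,0.174845479206761,0.10593119763683448,0.02
c12,0.015194887964468409,0.5392280186189425,0.29001223793635245,0.17075974344470507,0.02
c12,0.027634715759421842,0.3396550958108524,0.4106796578273625,0.24966524636178525,0.02
c12,0.050258844743693715,0.2263159504194711,0.4834275556219678,0.2902564939585609,0.02
c12,0.09140501016767315,0.20758638768415819,0.49327890227720356,0.2991347100386383,0.02
c12,0.16623692658197772,0.1988664578705396,0.4897663607320339,0.3113671813974264,0.02
c12,0.30233261512392806,0.19806496027711037,0.5034132237567982,0.2985218159660915,0.02
c12,0.5498478108749073,0.20162836591045832,0.5014997995614052,0.29687183452813637,0.02
c12,1.0,0.19199071502418893,0.5026271179736986,0.30538216700211257,0.02
c1,0.001388888888888889,0.9938455148299887,0.006154485170011279,,0.02
c1,0.002525951474970711,0.9826672956007342,0.017332704399265878,,0.02
c1,0.004593910214812832,0.9477660954721319,0.052233904527868136,,0.02
c1,0.00835487588375243,0.8940414666980743,0.10595853330192585,,0.02
c1,0.015194887964468409,0.8280392507958106,0.17196074920418938,,0.02
c1,0.027634715759421842,0.7575186433974496,0.24248135660255044,,0.02
c1,0.050258844743693715,0.7041986870650726,0.29580131293492745,,0.02
c1,0.09140501016767315,0.6978363355426718,0.30216366445732823,,0.02
c1,0.16623692658197772,0.689737417764545,0.31026258223545505,,0.02
c1,0.30233261512392806,0.6922226343100597,0.30777736568994035,,0.02
c1,0.5498478108749073,0.7012847833949788,0.2987152166050212,,0.02
c1,1.0,0.6967484888106034,0.3032515111893966,,0.02
d1,0.001388888888888889,1.0,0.0,,0.02
d1,0.002525951474970711,1.0,0.0,,0.02
d1,0.004593910214812832,0.9935663889525124,0.006433611047487669,,0.02
d1,0.00835487588375243,0.9851290952552677,0.014870904744732218,,0.02
d1,0.015194887964468409,0.9532553681634555,0.04674463183654453,,0.02
d1,0.027634715759421842,0.8847722930191191,0.115227706980881,,0.02
d1,0.050258844743693715,0.7975248538129502,0.2024751461870497,,0.02
d1,0.09140501016767315,0.7344460527761414,0.2655539472238586,,0.02
d1,0.16623692658197772,0.7043509516889312,0.29564904831106875,,0.02
d1,0.30233261512392806,0.7062382482366544,0.2937617517633456,,0.02
d1,0.5498478108749073,0.7028497395705001,0.2971502604294999,,0.02
d1,1.0,0.6986761389646513,0.30132386103534875,,0.02
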