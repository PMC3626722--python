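# Cofactor production coefficients per unit net flux (mol/mol).
# Lumped steps carry the cofactors of their components: gapdh includes
# phosphoglycerate kinase (ATP), akgdh includes succinyl-CoA synthetase,
# acs includes the NADP-dependent acetaldehyde dehydrogenase and the
# two-ATP-equivalent acetyl-CoA synthetase.  P/O and growth-associated
# ATP demand are set where the accounting is run.
hxk:   {ATP: -1}
pfk:   {ATP: -1}
gapdh: {NADH: 1, ATP: 1}
pyk:   {ATP: 1}
pdh:   {NADH: 1}
acs:   {NADPH: 1, ATP: -2}
idh:   {NADH: 1}
akgdh: {NADH: 1, ATP: 1}
tca4a: {FADH2: 1}
tca4b: {FADH2: 1}
mdh:   {NADH: 1}
pyc:   {ATP: -1}
zwf:   {NADPH: 1}
gnd:   {NADPH: 1}
aa_glu: {NADPH: -1}
met3:  {ATP: -1}
met4:  {NADH: 1}
met5:  {NADH: 1}
tre2:  {ATP: -2}
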