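# Cofactor coefficients per unit reaction flux for the reference model.
# GAPD lumps GAPDH+PGK (1 ATP, 1 cytosolic NADH); GLUT lumps transport+HK;
# AKGDH lumps aKGDH+succinyl-CoA synthetase (GTP counted as ATP-equivalent).
# reaction	cofactor	coefficient
GLUT	atp	-1
PFKALD	atp	-1
GAPD	atp	1
GAPD	nadh_c	1
PK	atp	1
LDH	nadh_c	-1
G6PDH	nadph	2
PDH	nadh_m	1
IDH	nadh_m	1
AKGDH	nadh_m	1
AKGDH	gtp	1
SDH	fadh2	1
MDH	nadh_m	1
MDHC	nadh_c	-1
ME1	nadph	1
ME2	nadph	1
GDH	nadh_m	1
PC	atp	-1
ACL	atp	-1
PROS	nadph	-2
PROS	atp	-1
BIOMASS	atp	-1800
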