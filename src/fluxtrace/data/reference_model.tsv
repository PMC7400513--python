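# metabolites
glc_e	extracellular	6	0	0
lac_e	extracellular	3	0	0
pyr_e	extracellular	3	0	0
gln_e	extracellular	5	0	0
ala_e	extracellular	3	0	0
ser_e	extracellular	3	0	0
pro_e	extracellular	5	0	0
co2_e	extracellular	1	0	0
hexp	cytosol	6	0	1
p5p	cytosol	5	0	1
gap	cytosol	3	0	1
pg3	cytosol	3	0	1
pep	cytosol	3	0	1
pyr_c	cytosol	3	0	1
ser	cytosol	3	0	1
ala	cytosol	3	0	1
cit_c	cytosol	6	0	1
oaa_c	cytosol	4	0	1
accoa_c	cytosol	2	0	1
mal_c	cytosol	4	0	1
pyr_m1	mitochondria	3	0	1
pyr_m2	mitochondria	3	0	1
accoa_m	mitochondria	2	0	1
oaa_m	mitochondria	4	0	1
cit_m	mitochondria	6	0	1
akg	mitochondria	5	0	1
suc	mitochondria	4	1	1
fum	mitochondria	4	1	1
mal_m	mitochondria	4	0	1
glu	mitochondria	5	0	1
gln	mitochondria	5	0	1
pro	mitochondria	5	0	1
pyr_mix	mixing	3	0	0
mal_mix	mixing	4	0	0

# reactions
GLUT	glc_e (ABCDEF) --> hexp (ABCDEF)	0	0	3000
PFKALD	hexp (ABCDEF) --> gap (CBA) + gap (DEF)	0	0	3000
GAPD	gap (ABC) --> pg3 (ABC)	0	0	3000
ENO	pg3 (ABC) --> pep (ABC)	0	0	3000
PK	pep (ABC) --> pyr_c (ABC)	0	0	3000
LDH	pyr_c (ABC) --> lac_e (ABC)	0	0	3000
PYRX	pyr_c (ABC) --> pyr_e (ABC)	0	0	3000
G6PDH	hexp (ABCDEF) --> co2_e (A) + p5p (BCDEF)	0	0	3000
TKTA	p5p (ABCDE) + p5p (FGHIJ) + p5p (KLMNO) --> hexp (ABKCDE) + hexp (FGLMNO) + gap (HIJ)	0	0	3000
MPC1	pyr_c (ABC) --> pyr_m1 (ABC)	0	0	3000
MPC2	pyr_c (ABC) --> pyr_m2 (ABC)	0	0	3000
PDH	pyr_m1 (ABC) --> co2_e (A) + accoa_m (BC)	0	0	3000
CS	oaa_m (ABCD) + accoa_m (ab) --> cit_m (ABCDab)	0	0	3000
IDH	cit_m (ABCDEF) --> co2_e (A) + akg (BCDEF)	0	0	3000
AKGDH	akg (ABCDE) --> co2_e (A) + suc (BCDE)	0	0	3000
SDH	suc (ABCD) --> fum (ABCD)	1	-3000	3000
FH	fum (ABCD) --> mal_m (ABCD)	1	-3000	3000
MDH	mal_m (ABCD) --> oaa_m (ABCD)	1	-3000	3000
PC	pyr_m2 (ABC) + co2_e (a) --> oaa_m (ABCa)	0	0	3000
ME2	mal_m (ABCD) --> pyr_m2 (ABC) + co2_e (D)	0	0	3000
GLNUP	gln_e (ABCDE) --> gln (ABCDE)	0	0	3000
GLS	gln (ABCDE) --> glu (ABCDE)	0	0	3000
GDH	glu (ABCDE) --> akg (ABCDE)	1	-3000	3000
PROS	glu (ABCDE) --> pro (ABCDE)	0	0	3000
PROX	pro (ABCDE) --> pro_e (ABCDE)	0	0	3000
ALT	pyr_m2 (ABC) --> ala (ABC)	0	0	3000
ALAX	ala (ABC) --> ala_e (ABC)	0	0	3000
SERUP	ser_e (ABC) --> ser (ABC)	0	0	3000
SDS	ser (ABC) --> pyr_c (ABC)	0	0	3000
CITX	cit_m (ABCDEF) --> cit_c (ABCDEF)	0	0	3000
ACL	cit_c (ABCDEF) --> oaa_c (ABCD) + accoa_c (EF)	0	0	3000
MDHC	oaa_c (ABCD) --> mal_c (ABCD)	0	0	3000
MALT	mal_m (ABCD) --> mal_c (ABCD)	0	0	3000
ME1	mal_c (ABCD) --> pyr_c (ABC) + co2_e (D)	0	0	3000

# biomass
dry_cell_weight_pg	514
hexp	55
p5p	105
pg3	130
pyr_c	100
accoa_c	600
oaa_c	330
glu	300
gln	150
ala	60
ser	200
pro	120

# mixing
pyr_mix	pyr_c,pyr_m2
mal_mix	mal_m,mal_c
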