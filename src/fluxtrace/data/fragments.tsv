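# Curated GC-MS fragment list for the reference model (TBDMS/methoxime
# derivatized ions, [M-57]-style). id	metabolite	carbons	formula
pyr_frag	pyr_mix	1-3	C6H12NO3Si
pg3_frag	pg3	1-3	C17H38O7PSi3
pep_frag	pep	1-3	C11H24O6PSi2
fum_frag	fum	1-4	C12H21O4Si2
akg_frag	akg	1-5	C14H28NO5Si2
mal_frag	mal_mix	1-4	C18H39O5Si3
pro_frag	pro	1-5	C13H28NO2Si2
glu_frag	glu	1-5	C19H40NO4Si3
gln_frag	gln	1-5	C19H41N2O3Si3
cit_frag	cit_m	1-6	C26H55O7Si4
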