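# Reported extracellular fluxes (nmol/10^6 cells/h) with 95% CIs for
# parental HEK293 cells and the FH-attenuated line; inputs for the
# comparative reporting arithmetic.
# metabolite	direction	parental	parental_lb	parental_ub	fhdim	fhdim_lb	fhdim_ub
glucose	uptake	578.8	541.5	616.1	533.5	499.3	567.8
glutamine	uptake	82.7	77.3	88.1	52.7	49.3	56.1
cysteine	uptake	4.1	3.8	4.5	3.3	3.1	3.6
serine	uptake	22.0	20	24.1	16.2	15.2	17.3
arginine	uptake	8.7	8.1	9.3	9.6	8.9	10.4
lactate	secretion	1087.7	1036.9	1138.5	1009.8	975.1	1044.6
pyruvate	secretion	61.7	55.5	67.8	57.8	52	63.6
alanine	secretion	17.1	16.2	18.1	19.4	18.4	20.3
proline	secretion	13.9	13.4	14.3	1.5	1.4	1.5
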