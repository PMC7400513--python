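# Reported ATP production fluxes (nmol/10^6 cells/h) for parental HEK293
# cells and the FH-attenuated line; inputs for the ledger reporting
# arithmetic.
# pathway	parental	fhdim
glycolysis	1161.3	1074.6
tca_cycle	1070.9	826.8
total_net	2215.3	1885.1
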