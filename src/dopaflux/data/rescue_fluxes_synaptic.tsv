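reaction_id	role	control_flux	pd_flux	rescued_flux	printed_improvement
ATPS4mi	energy	8.9379	8.5965	9.4468	Yes
EX_dopa[e]	exchange	1.0826	0.3840	0.3118	No
EX_met_L[e]	exchange	-1.8909	-1.2779	-1.2324	No
EX_gln_L[e]	exchange	-16.6588	-16.6238	-17.5047	Yes
EX_lys_L[e]	exchange	-15.0386	-14.9391	-15.1006	Yes
EX_his_L[e]	exchange	-6.3213	-7.2753	-6.9867	Yes
EX_4mop[e]	exchange	-0.1546	-0.1951	-0.1687	Yes
EX_urea[e]	exchange	0.2291	0.1597	0.3223	Yes
EX_lac_L[e]	exchange	-0.3649	-0.2427	-0.3285	Yes
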