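reaction_id	role	control_flux	pd_flux	rescued_flux	printed_improvement
ATPS4mi	energy	8.5862	9.48623	9.5930	Yes
EX_gln_L[e]	exchange	-17.0832	-16.8687	-17.4678	Yes
EX_lys_L[e]	exchange	-19.2610	-18.9466	-19.7937	Yes
EX_his_L[e]	exchange	-6.9666	-5.9576	-6.1757	Yes
EX_glyc_R[e]	exchange	0.3131	0.2876	0.2876	No
EX_lac_L[e]	exchange	-1.1569	-0.6983	-0.7279	Yes
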