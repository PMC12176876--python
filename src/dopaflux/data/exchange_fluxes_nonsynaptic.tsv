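reaction_id	metabolite	control_flux	pd_flux	printed_change	printed_consistency
EX_dopa[e]	Dopamine	0	0	No excrete	-
EX_glc_D[e]	D-Glucose	-0.4825	-0.2792	Lower uptake	Yes
EX_trp_L[e]	L-Tryptophan	-0.8357	-0.8357	Same	-
EX_met_L[e]	L-Methionine	-1.1715	-1.2528	Higher uptake	No
EX_asn_L[e]	L-Asparagine	0.4867	0.4867	Same	-
EX_orn[e]	Ornithine	25.3657	25.3657	Same	-
EX_gln_L[e]	L-Glutamine	-17.0832	-16.8687	Lower uptake	Yes
EX_lys_L[e]	L-Lysine	-19.2610	-18.9466	Lower uptake	Yes
EX_his_L[e]	L-Histidine	-6.9666	-5.9576	Lower uptake	Yes
EX_ile_L[e]	L-Isoleucine	-8.4975	-8.4975	Same	-
EX_Lpipecol[e]	L-Pipecolic acid	0.8811	1.0950	Higher excrete	No
EX_cit[e]	Citric acid	0.2540	0.2540	Same	-
EX_4mop[e]	Ketoleucine	-0.5428	-0.5550	Higher uptake	No
EX_ptrc[e]	Putrescine	-0.1268	-0.1268	Same	-
EX_glyc_R[e]	Glyceric acid	0.3131	0.2876	Lower excrete	Yes
EX_urea[e]	Urea	0.0624	0.0882	Higher excrete	No
EX_lac_L[e]	L-Lactic acid	-1.1569	-0.6983	Lower uptake	Yes
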