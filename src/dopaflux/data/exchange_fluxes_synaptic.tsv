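reaction_id	metabolite	control_flux	pd_flux	printed_change	printed_consistency
EX_dopa[e]	Dopamine	1.0826	0.3840	Lower excrete	No
EX_glc_D[e]	D-Glucose	-0.7525	-0.3146	Lower uptake	Yes
EX_trp_L[e]	L-Tryptophan	-0.8357	-0.8357	Same	-
EX_met_L[e]	L-Methionine	-1.8909	-1.2779	Lower uptake	Yes
EX_asn_L[e]	L-Asparagine	0.4867	0.4867	Same	-
EX_orn[e]	Ornithine	25.3657	25.3657	Same	-
EX_gln_L[e]	L-Glutamine	-16.6588	-16.6238	Lower uptake	Yes
EX_lys_L[e]	L-Lysine	-15.0386	-14.9391	Lower uptake	Yes
EX_his_L[e]	L-Histidine	-6.3213	-7.2753	Higher uptake	No
EX_ile_L[e]	L-Isoleucine	-8.4975	-8.4975	Same	-
EX_Lpipecol[e]	L-Pipecolic acid	0	0	Same	-
EX_cit[e]	Citric acid	0.2540	0.2540	Same	-
EX_4mop[e]	Ketoleucine	-0.1546	-0.1951	Higher uptake	No
EX_ptrc[e]	Putrescine	-0.1268	-0.1268	Same	-
EX_glyc_R[e]	Glyceric acid	0.2876	0.2876	Same	-
EX_urea[e]	Urea	0.2291	0.1597	Lower excrete	Yes
EX_lac_L[e]	L-Lactic acid	-0.3649	-0.2427	Lower uptake	Yes
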