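metabolite	reaction_id	directions	citations
Dopamine	EX_dopa[e]	increased	B114
D-Glucose	EX_glc_D[e]	increased;decreased	B99;B56
L-Tryptophan	EX_trp_L[e]	decreased	B100
L-Methionine	EX_met_L[e]	increased	B114
L-Asparagine	EX_asn_L[e]	increased	B114
Ornithine	EX_orn[e]	increased	B112
L-Glutamine	EX_gln_L[e]	increased;decreased	B110;B114;B100
L-Lysine	EX_lys_L[e]	increased	B112
L-Histidine	EX_his_L[e]	increased	B112;B114
L-Isoleucine	EX_ile_L[e]	increased	B112
L-Pipecolic acid	EX_Lpipecol[e]	decreased	B56
Citric acid	EX_cit[e]	increased	B114
Ketoleucine	EX_4mop[e]	increased	B112
Putrescine	EX_ptrc[e]	increased	B114;B80
Glyceric acid	EX_glyc_R[e]	decreased	B99
Urea	EX_urea[e]	decreased	B99
L-Lactic acid	EX_lac_L[e]	increased	B114
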