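# Common currency metabolites (KEGG compound ids).
# High-degree co-factors whose simple-graph shortcuts are biochemically
# meaningless; used as the default removal list for linearization.
C00001	H2O
C00002	ATP
C00003	NAD+
C00004	NADH
C00005	NADPH
C00006	NADP+
C00007	O2
C00008	ADP
C00009	orthophosphate
C00010	CoA
C00011	CO2
C00013	diphosphate
C00014	NH3
C00015	UDP
C00020	AMP
C00080	H+
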