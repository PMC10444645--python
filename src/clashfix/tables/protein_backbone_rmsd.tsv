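# Published survey: backbone (N/CA/C) RMSD in Angstroms between optimized and
# X-ray geometries for 21 proteins, per semiempirical method, after optimal
# rigid superposition.  Column means are recomputed by survey_stats.
protein	PM6-ORG	PM6-D3H4	PM7
Crambin	0.797	0.537	0.526
Acyl-Coenzyme A	0.771	0.649	0.605
Zinc finger domain of KLF4	0.816	1.215	1.117
Barnase	0.857	0.669	0.740
Zinc endoprotease	0.990	0.742	0.741
Apoptosis inhibitor	1.033	1.080	1.409
Human hemoglobin, chain A	0.686	0.588	0.736
Flavodoxin	0.637	0.587	0.681
Rab6	0.863	0.788	0.802
Adenylyltransferase	1.106	0.918	1.075
Calcium binding domain	0.821	0.634	0.808
Magnesium loaded ALG-2	0.879	0.802	0.809
Peridinin-chlorophyll	0.825	0.736	0.959
Bacteriorhodopsin	0.934	0.958	1.045
Green Fluorescent Protein	0.962	0.642	0.801
Chymotrypsin	0.951	0.970	1.168
3CLpro	1.108	0.910	1.224
Potassium channel	1.765	1.036	1.146
P450	1.121	0.933	1.040
Sodium channel	1.220	0.997	1.736
Transcobalamin	1.094	1.029	1.113
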