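# Published survey: volumes (A^3) inside the solvent-accessible surface for 21
# proteins (experimental geometry and per-method optimized geometries) and the
# percent change of each optimized volume relative to the experimental one.
# Column means of the percent changes are recomputed by survey_stats.
protein	PDB	PM6-ORG	PM6-D3H4	PM7	PM6-ORG pct	PM6-D3H4 pct	PM7 pct
Crambin	6786	6315	6353	6308	-6.95	-6.38	-7.04
Acyl-Coenzyme A	15285	14218	14561	14360	-6.98	-4.74	-6.05
Zinc finger domain of KLF4	15048	14547	14575	14230	-3.33	-3.15	-5.44
Barnase	18241	16778	17323	16625	-8.02	-5.03	-8.86
Zinc endoprotease	20168	18400	18666	18231	-8.77	-7.45	-9.61
Apoptosis inhibitor	22983	21646	21360	20600	-5.82	-7.06	-10.37
Human hemoglobin, chain A	23364	22094	21164	21364	-5.44	-9.42	-8.56
Flavodoxin	24405	22733	22517	22133	-6.85	-7.74	-9.31
Rab6	24754	23104	23837	23221	-6.66	-3.70	-6.19
Adenylyltransferase	25493	25389	24945	24128	-0.41	-2.15	-5.35
Calcium binding domain	25911	24313	25168	24037	-6.17	-2.87	-7.23
Magnesium loaded ALG-2	26510	25240	25618	25173	-4.79	-3.36	-5.04
Peridinin-chlorophyll	29872	28131	28381	27120	-5.83	-4.99	-9.21
Bacteriorhodopsin	35478	32633	33304	32611	-8.02	-6.13	-8.08
Green Fluorescent Protein	33660	31558	32377	31489	-6.24	-3.81	-6.45
Chymotrypsin	40672	38941	39270	38236	-4.26	-3.45	-5.99
3CLpro	42947	39716	40856	39444	-7.52	-4.87	-8.16
Potassium channel	49257	46880	47054	45786	-4.83	-4.47	-7.05
P450	52059	48486	48745	47287	-6.86	-6.37	-9.17
Sodium channel	53356	53313	50913	49213	-0.08	-4.58	-7.76
Transcobalamin	62042	57107	58339	56699	-7.95	-5.97	-8.61
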