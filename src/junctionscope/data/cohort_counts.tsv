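class	n	decimals	note
KIAA1549::BRAF	143	2
BRAF_V600E	59	2
BRAF_fusion_noncanonical	14	2	partner list enumerates 13 names but BCAS1 appears twice (12 unique symbols)
BRAF_SNV_other	7	0
FGFR1::TACC1	9	2
KDD_FGFR1	17	2
FGFR1_SNV	13	2
FGFR2_fusion	12	2
FGFR3::TACC3	3	2
other_RTK_fusion	18	2
KRAS_SNV	4	2
PDGFRA_SNV	1	2
MYB	3	2
MYBL1	1	2
IDH1_SNV	11	1
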