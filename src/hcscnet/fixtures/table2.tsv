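# Published per-miRNA target summary for the 18 differentially expressed miRNAs
# of the hepatic cancer stem cell study (two stem/parental hepatoma cell-line
# pairs; seven-source consensus target prediction, >=2 sources).
# Columns: direction is the miRNA's regulation (stem vs parental cancer cells);
# total_predicted counts consensus-predicted target genes; de_targets counts
# differentially expressed targets (= up_targets + down_targets); candidates
# counts anti-correlated targets (down targets of an up miRNA, up targets of a
# down miRNA).  Row invariants: de_targets = up_targets + down_targets;
# column sums 1460 (de_targets), 651 (up-miRNA candidates), 103 (down-miRNA
# candidates).
mirna	direction	total_predicted	de_targets	up_targets	down_targets	candidates
hsa-miR-100	down	574	22	4	18	4
hsa-miR-210	down	1180	33	5	28	5
hsa-miR-29c	down	3533	99	26	73	26
hsa-miR-181c	down	5492	141	15	126	15
hsa-miR-22*	down	2343	55	4	51	4
hsa-miR-15b*	down	1641	45	4	41	4
hsa-miR-199a-3p	down	3707	99	11	88	11
hsa-miR-199b-3p	down	3456	96	10	86	10
hsa-miR-149	down	5100	116	24	92	24
hsa-miR-378d	up	7	0	0	0	0
hsa-miR-450b-5p	up	5865	146	8	138	138
hsa-miR-338-5p	up	5240	156	15	141	141
hsa-miR-760	up	4249	113	32	81	81
hsa-miR-378	up	3486	92	20	72	72
hsa-miR-215	up	2878	81	11	70	70
hsa-miR-375	up	3312	95	10	85	85
hsa-miR-1269b	up	12	0	0	0	0
hsa-miR-1269	up	2877	71	7	64	64
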