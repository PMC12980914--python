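# Published allele depths and genotype calls for the CRFK and PG-4 cell-line genomes, one row per panel locus per sample.
# ref_depth/alt_depth "." = locus assayed by structural-variant evidence (depth track, junction reads or long reads), not a pileup.
# note "compound_het": printed depth pair reflects whole-read wild-type matching; the het genotype comes from read-backed phasing
# of the two adjacent variants (7 deletion-only + 13 substitution-only reads, 0 carrying both).
#locus_id	sample	ref_depth	alt_depth	genotype	note
TYR_cb	CRFK	18	0	+/+
TYR_cs	CRFK	25	0	+/+
TYR_ca	CRFK	25	0	+/+
TYR_cm	CRFK	40	0	+/+
TYRP1_b	CRFK	22	0	+/+
TYRP1_bl	CRFK	20	0	+/+
MC1R_e	CRFK	35	0	+/+
KIT_wg	CRFK	27	0	+/+
MLPH_d	CRFK	15	4	+/d
ASIP_a	CRFK	0	48	a/a
LVRN_tb_176	CRFK	16	0	+/+
LVRN_tb_416	CRFK	34	0	+/+
LVRN_tb_682	CRFK	33	0	+/+
LVRN_tb_2522	CRFK	0	10	t^b/t^b
DKK4_ti_188	CRFK	36	0	+/+
DKK4_ti_53	CRFK	33	0	+/+
FGF5_l_356ins	CRFK	24	0	+/+
FGF5_l_406	CRFK	24	0	+/+
FGF5_l_474del	CRFK	26	0	+/+
FGF5_l_475	CRFK	0	26	l/l
FGF5_l_577	CRFK	37	0	+/+
KRT71_hr	CRFK	40	0	+/+
KRT71_re_complex	CRFK	51	0	+/+
KRT71_re_445	CRFK	37	0	+/+
LPAR6_re	CRFK	16	0	+/+
KIT_wW	CRFK	.	.	+/+	longread
KIT_wS	CRFK	.	.	+/+	longread
KIT_wSal	CRFK	.	.	+/+	depth_track
ARHGAP36_o	CRFK	.	.	+/+	depth_track
PAX3_DBE_Cel	CRFK	.	0	+/+	junction_reads
PAX3_DBE_ALT	CRFK	.	0	+/+	junction_reads
TYR_cb	PG-4	16	0	+/+
TYR_cs	PG-4	17	20	+/c^s
TYR_ca	PG-4	34	0	+/+
TYR_cm	PG-4	54	0	+/+
TYRP1_b	PG-4	26	0	+/+
TYRP1_bl	PG-4	19	0	+/+
MC1R_e	PG-4	34	0	+/+
KIT_wg	PG-4	28	0	+/+
MLPH_d	PG-4	38	0	+/+
ASIP_a	PG-4	0	25	a/a
LVRN_tb_176	PG-4	17	0	+/+
LVRN_tb_416	PG-4	10	12	+/t^b
LVRN_tb_682	PG-4	22	0	+/+
LVRN_tb_2522	PG-4	5	3	+/t^b
DKK4_ti_188	PG-4	20	0	+/+
DKK4_ti_53	PG-4	30	0	+/+
FGF5_l_356ins	PG-4	22	0	+/+
FGF5_l_406	PG-4	25	0	+/+
FGF5_l_474del	PG-4	0	7	+/l	compound_het
FGF5_l_475	PG-4	0	13	l/+	compound_het
FGF5_l_577	PG-4	27	0	+/+
KRT71_hr	PG-4	25	0	+/+
KRT71_re_complex	PG-4	32	0	+/+
KRT71_re_445	PG-4	29	0	+/+
LPAR6_re	PG-4	19	0	+/+
KIT_wW	PG-4	.	.	+/+	longread
KIT_wS	PG-4	.	.	+/w^s	longread
KIT_wSal	PG-4	.	.	+/+	depth_track
ARHGAP36_o	PG-4	.	.	+/+	depth_track
PAX3_DBE_Cel	PG-4	.	0	+/+	junction_reads
PAX3_DBE_ALT	PG-4	.	0	+/+	junction_reads
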