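# coatcall variant panel v1 — 13 coat/iris genes of the domestic cat
# coordinates are 1-based inclusive; INS/SV_INS rows give the two bases flanking the insertion point
# ref/alt are genomic-strand strings; "." = span taken from coordinates; "" (empty) = deleted/none
# chrom "absent" = locus has no coordinates in that assembly
#locus_id	gene	trait	allele_name	variant_class	cds_notation	chrom_fca126	start_fca126	end_fca126	ref_fca126	alt_fca126	chrom_anams	start_anams	end_anams	ref_anams	alt_anams	inheritance	inheritance_source	epistasis_tags
TYR_cb	TYR	Color	c^b	SNV	c0.679G>T	D1	44022819	44022819	C	A	D1	46081417	46081417	C	A	recessive	study	base_color
TYR_cs	TYR	Color	c^s	SNV	c0.904G>A	D1	44013031	44013031	C	T	D1	46071661	46071661	C	T	recessive	study	base_color
TYR_ca	TYR	Color	c^a	DEL	c0.939del	D1	44012996	44012996	.		D1	46071626	46071626	.		recessive	study	base_color
TYR_cm	TYR	Color	c^m	DELINS	c0.820_936delinsAATCTC	D1	44012836	44012998	.	GAGATT	D1	46071466	46071628	.	GAGATT	recessive	study	base_color
TYRP1_b	TYRP1	Brown	b	SNV	c0.1261+5G>A	D4	38142265	38142265	G	A	D4	39391308	39391308	G	A	recessive	external	base_color
TYRP1_bl	TYRP1	Brown	b^l	SNV	c0.298C>T	D4	38130163	38130163	C	T	D4	39379209	39379209	C	T	recessive	external	base_color
MC1R_e	MC1R	Amber	e	SNV	c0.250G>A	E2	61570294	61570294	G	A	E2	62623146	62623146	G	A	recessive	external	base_color
KIT_wW	KIT	White	w^w	SV_INS	intron1:FERV1-LTR_insertion	B1	161388687	161388688	.	FERV1-LTR	B1	163130991	163130992	.	FERV1-LTR	dominant	study	full_white
KIT_wS	KIT	White	w^s	SV_INS	intron1:FERV1_insertion	B1	161388687	161388688	.	FERV1	B1	163130991	163130992	.	FERV1	dominant_spotting	study	spotting
KIT_wg	KIT	White	w^g	DELINS	c0.1035_1036delinsCA	B1	161337385	161337386	.	TG	B1	163079561	163079562	.	TG	recessive	external	gloves
KIT_wSal	KIT	White	w^Sal	SV_DEL	KIT-KDR_intergenic:95kb_deletion	B1	161142880	161237957	.		B1	162885414	162980052	.		recessive	external	salmiak
ARHGAP36_o	ARHGAP36	Orange	o	SV_DEL	intron1:5kb_deletion	absent	0	0			X	109186183	109191258	.		x_linked	external	orange
MLPH_d	MLPH	Dilution	d	DEL	c0.83del	C1	218197448	218197448	.		C1	219535339	219535339	.		recessive	study	dilution
ASIP_a	ASIP	Agouti	a	DEL	c0.123_124del	A3	24831083	24831084	.		A3	25283750	25283751	.		recessive	external	nonagouti
LVRN_tb_176	LVRN	Tabby	t^b	SNV	c0.176C>A	A1	94477275	94477275	C	A	A1	97133509	97133509	C	A	recessive	external	tabby_blotched
LVRN_tb_416	LVRN	Tabby	t^b	SNV	c0.416C>A	A1	94477515	94477515	C	A	A1	97133749	97133749	C	A	recessive	external	tabby_blotched
LVRN_tb_682	LVRN	Tabby	t^b	SNV	c0.682G>A	A1	94477781	94477781	G	A	A1	97134015	97134015	G	A	recessive	external	tabby_blotched
LVRN_tb_2522	LVRN	Tabby	t^b	SNV	c0.2522G>A	A1	94536796	94536796	G	A	A1	97192983	97192983	G	A	recessive	external	tabby_blotched
DKK4_ti_188	DKK4	Ticked	ti	SNV	c0.188G>A	B1	40429492	40429492	G	A	B1	41805975	41805975	G	A	dominant	external	tabby_ticked
DKK4_ti_53	DKK4	Ticked	ti	SNV	c0.53C>T	B1	40428846	40428846	C	T	B1	41805329	41805329	C	T	dominant	external	tabby_ticked
FGF5_l_356ins	FGF5	Longhair	l	INS	c0.356_357insT	B1	139634675	139634676		A	B1	141368532	141368533		A	recessive	study	longhair
FGF5_l_406	FGF5	Longhair	l	SNV	c0.406C>T	B1	139645946	139645946	G	A	B1	141379803	141379803	G	A	recessive	study	longhair
FGF5_l_474del	FGF5	Longhair	l	DEL	c0.474del	B1	139634261	139634261	.		B1	141368118	141368118	.		recessive	study	longhair
FGF5_l_475	FGF5	Longhair	l	SNV	c0.475A>C	B1	139634260	139634260	T	G	B1	141368117	141368117	T	G	recessive	study	longhair
FGF5_l_577	FGF5	Longhair	l	SNV	c0.577G>A	B1	139634158	139634158	C	T	B1	141368015	141368015	C	T	recessive	study	longhair
KRT71_hr	KRT71	Hairless	hr	SNV	c0.816+1G>A	B4	78941699	78941699	C	T	B4	80471148	80471148	C	T	recessive	external	texture_hairless
KRT71_re_complex	KRT71	Rexing	re	DELINS	c0.1108-4_1184del;c0.1184_1185insAGTTGGAG;c0.1196_1197insT	B4	78939390	78939470	.	CTCCAACT	B4	80468919	80468999	.	CTCCAACT	recessive	external	texture_rex
KRT71_re_445	KRT71	Rexing	re	SNV	c0.445-1G>C	B4	78943283	78943283	C	G	B4	80472733	80472733	C	G	recessive	external	texture_rex
LPAR6_re	LPAR6	Rexing	re	DEL	c0.250_253del	A1	22865220	22865223	.		A1	23372953	23372956	.		recessive	external	texture_rex
PAX3_DBE_Cel	PAX3	Blue iris	DBE^Cel	SV_INS	intron4:FERV1-LTR_homolog_insertion	C1	205833101	205833102	.	N[395]	C1	207180017	207180018	.	N[395]	dominant	external	blue_iris
PAX3_DBE_ALT	PAX3	Blue iris	DBE^ALT	SV_INS	intron4:RD114-LTR_homolog_insertion	C1	205834854	205834855	.	N[433]	C1	207181773	207181774	.	N[433]	dominant	external	blue_iris
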