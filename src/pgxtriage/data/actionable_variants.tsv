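# Actionable-variant fixture: 24 PharmGKB level-1A/1B variants of a national
# exome cohort (N=1904) with their published het/hom carrier counts, gnomAD and
# cohort allele frequencies. Coordinates are SYNTHETIC placeholders (true
# chromosome per gene, dummy positions; keying downstream is by rsid).
# maf_cohort_printed is the published 3-significant-figure cohort MAF.
contig	position	ref	alt	gene	star_allele	function_class	effect	impact	hgvs_c	hgvs_p	rsid	gnomad_af	het_count	hom_count	maf_cohort_printed
chr10	1000001	A	C	CYP2C9	*3	.	missense	MODERATE	c.1075A>C	Ile359Leu	rs1057910	0.0636	247	8	0.0691
chr10	1000002	C	T	CYP2C9	*2	.	missense	MODERATE	c.430C>T	Arg144Cys	rs1799853	0.0926	390	35	0.121
chr22	1000003	G	A	CYP2D6	*4	.	splice_acceptor	HIGH	c.506-1G>A	.	rs3892097	0.138	487	74	0.167
chr22	1000004	AT	A	CYP2D6	*6	none	frameshift	HIGH	c.454delT	Trp152fs	rs5030655	0.00791	42	0	0.0110
chr22	1000005	C	T	CYP2D6	.	decreased	missense	MODERATE	c.100C>T	Pro34Ser	rs1065852	0.207	511	115	0.195
chr12	1000006	T	C	SLCO1B1	*5	decreased	missense	MODERATE	c.521T>C	Val174Ala	rs4149056	0.133	585	73	0.192
chr22	1000007	CA	C	CYP2D6	*3	.	frameshift	HIGH	c.775delA	Arg259fs	rs35742686	0.0124	67	2	0.0186
chr16	1000008	G	A	VKORC1	.	.	utr3	MODIFIER	c.*134G>A	.	rs7294	.	64	20	0.0273
chr19	1000009	G	A	CYP4F2	.	.	missense	MODERATE	c.1297G>A	Val433Met	rs2108622	0.274	759	142	0.274
chr19	1000010	G	T	CYP2B6	.	.	missense	MODERATE	c.516G>T	Gln172His	rs3745274	0.272	651	101	0.224
chr10	1000011	G	A	CYP2C19	*2	none	synonymous	LOW	c.681G>A	Pro227Pro	rs4244285	0.176	411	35	0.126
chr10	1000012	A	G	CYP2C19	*4	.	start_lost	HIGH	c.1A>G	Met1?	rs28399504	0.00231	11	0	0.00289
chr10	1000013	T	C	CYP2C19	*8	none	missense	MODERATE	c.358T>C	Trp120Arg	rs41291556	0.00152	11	0	0.00289
chr7	1000014	ACTT	A	CFTR	.	.	inframe_deletion	MODERATE	c.1521_1523delCTT	Phe508del	rs113993960	0.00696	39	0	0.0102
chr7	1000015	C	T	CFTR	.	.	missense	MODERATE	c.220C>T	Arg74Trp	rs115545701	0.00142	1	0	0.000263
chr7	1000016	G	C	CFTR	.	.	missense	MODERATE	c.328G>C	Asp110His	rs113993958	0.0000203	1	0	0.000263
chr7	1000017	T	G	CFTR	.	.	missense	MODERATE	c.3154T>G	Phe1052Val	rs150212784	0.000632	4	0	0.00105
chr7	1000018	G	A	CFTR	.	.	missense	MODERATE	c.3209G>A	Arg1070Gln	rs78769542	0.000623	1	0	0.000263
chr7	1000019	G	C	CFTR	.	.	missense	MODERATE	c.3454G>C	Asp1152His	rs75541969	0.000407	2	0	0.000526
chr1	1000020	A	T	DPYD	.	.	missense	MODERATE	c.2846A>T	Asp949Val	rs67376798	0.00284	9	0	0.00236
chr1	1000021	G	A	DPYD	*2A	.	splice_donor	HIGH	c.1905+1G>A	.	rs3918290	0.00574	10	0	0.00263
chr6	1000022	G	C	TPMT	*2	none	missense	MODERATE	c.238G>C	Ala80Pro	rs1800462	0.00172	6	0	0.00158
chr6	1000023	G	A	TPMT	*3B	decreased	missense	MODERATE	c.460G>A	Ala154Thr	rs1800460	0.0280	93	1	0.0249
chr6	1000024	A	G	TPMT	*3C	decreased	missense	MODERATE	c.719A>G	Tyr240Cys	rs1142345	0.0366	98	2	0.0268
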