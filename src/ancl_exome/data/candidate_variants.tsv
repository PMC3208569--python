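# Transcription of the published validated-candidate table (exome survivors
# after the filtering cascade): 19 single-nucleotide substitutions + 3 indels.
# Positions per human genome build 37 (hg19/GRCh37), 1-based.
# segregates = published extended co-segregation call within the family.
# gerp printed only for the DNAJC5 variant region.
chrom	pos	ref	alt	gene	aa_subst	var_class	prediction	segregates	gerp
1	16915434	T	C	NBPF1	K135E	missense	benign	no	.
2	130899804	T	C	CCDC74B	H149R	missense	benign	no	.
3	64072900	*	-AA	LOC100287879	.	frameshift	.	no	.
3	33883492	G	A	PDCD6IP	G429S	missense	probably_damaging	yes	.
3	75788010	A	C	ZNF717	V255G	missense	benign	no	.
4	155191162	G	A	DCHS2	T1701I	missense	possibly_damaging	no	.
4	164247234	C	G	NPY1R	G158A	missense	possibly_damaging	no	.
4	148653570	A	G	ARHGAP10	I40V	missense	benign	no	.
4	162421268	A	G	FSTL5	M452T	missense	benign	no	.
5	180376974	T	G	BTNL8	H311Q	missense	probably_damaging	no	.
6	132030966	G	C	ENPP3	L398V	missense	unknown	no	.
7	100550039	*	+CTC	MUC3A	.	coding-indel	.	no	.
10	90356030	*	-TTTTA	LIPJ	.	splice	.	yes	.
13	19042781	T	C	LOC729501	T434C	missense	unknown	no	.
13	115012439	A	G	CDC16	M311V	missense	benign	no	.
13	29287552	C	T	SLC46A3	V109I	missense	benign	no	.
15	43038399	C	T	TTBK2	R1110H	missense	possibly_damaging	no	.
16	16218686	G	A	ABCC1	V1211I	missense	possibly_damaging	no	.
16	25123254	C	G	LCMT1	S17T	missense	probably_damaging	no	.
16	24804954	A	T	TNRC6A	Q1112H	missense	probably_damaging	no	.
20	62562226	T	G	DNAJC5	L115R	missense	possibly_damaging	yes	5.34
X	3747372	C	T	LOC389906	W263*	nonsense	unknown	no	.
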