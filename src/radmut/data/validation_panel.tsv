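name	line_id	chrom	pos	ref	alt	called_genotype	depth	alt_depth	status	sanger_confirmed
149_IND1	M149	1	23789397	GAT	G	hom_alt	31	31	unique	Y
153_IND4	M153	4	15522985	C	CTCAGCCG	hom_alt	28	28	unique	Y
166_IND1	M166	1	18131046	AGCGCATGTGCCATG	A	hom_alt	27	27	unique	Y
166_IND3	M166	6	5694121	CA	C	hom_alt	33	33	unique	Y
193_SNP1	M193	2	32736082	A	ACCAACG	hom_alt	30	30	unique	Y
193_SNP4	M193	6	28952090	A	G	het	31	16	unique	Y
193_SNP5	M193	7	10033642	T	C	hom_alt	29	29	unique	Y
193_SNP6	M193	12	24819926	C	A	het	29	3	filtered_allele_ratio	N
193_IND6	M193	12	1851681	AC	A	hom_alt	32	32	unique	Y
225_SNP2	M225	3	30121299	T	G	hom_alt	26	26	unique	Y
225_SNP3	M225	5	18773517	G	A	hom_alt	34	34	not_unique	Y
232_IND1	M232	1	38864179	AGG	A	hom_alt	30	30	unique	Y
238_SNP4	M238	8	24636417	G	A	hom_alt	28	28	unique	Y
238_SNP5	M238	9	19013812	G	C	het	30	14	unique	Y
238_IND1	M238	1	2382470	CG	C	hom_alt	25	25	unique	Y
238_IND2	M238	1	3324566	GGTGGT	G	hom_alt	29	29	unique	Y
238_IND4	M238	6	12475810	C	CAAGT	hom_alt	31	31	unique	Y
238_IND5	M238	6	16993055	TA	A	hom_alt	27	27	unique	Y
238_IND6	M238	6	17139752	A	AGATGCTCTAGGACAGTTTGTTGG	hom_alt	24	24	not_unique	Y
242_SNP1	M242	1	14877967	G	T	hom_alt	35	35	not_unique	Y
242_SNP3	M242	3	8704769	G	A	het	30	15	not_unique	Y
242_SNP5	M242	8	8951950	G	T	hom_alt	32	32	unique	Y
242_IND1	M242	1	13935043	A	AT	het	12	5	low_coverage	N
242_IND4	M242	7	29013042	CAAGG	C	hom_alt	30	30	unique	Y
242_IND4_2	M242	7	29013050	G	GC	hom_alt	30	30	unique	Y
244_SNP3	M244	7	11432559	C	T	het	21	2	filtered_allele_ratio	N
244_SNP4	M244	11	22433103	C	T	het	25	2	filtered_allele_ratio	N
244_IND1	M244	8	24737886	A	ACCAACG	hom_alt	26	26	not_unique	Y
314_SNP2	M314	4	28342904	G	T	hom_alt	29	29	unique	Y
314_IND1	M314	4	3682688	G	GAT	hom_alt	30	30	unique	Y
314_IND1_2	M314	4	3682689	G	GA	hom_alt	30	30	not_unique	Y
314_IND1_3	M314	4	3682697	GGT	G	hom_alt	28	28	unique	Y
314_IND1_4	M314	4	3682701	CAG	C	hom_alt	28	28	unique	Y
314_IND2	M314	7	15991122	AC	A	hom_alt	30	30	unique	Y
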