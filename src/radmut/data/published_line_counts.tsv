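line_id	treatment	dose_gy	total	snv	indel	small	freq_small	freq_all	sv	del	dup	inv	ins	itx	ctx	freq_sv
M149	gamma	150	7016	5205	1432	6637	64788.31	61288.48	379	339	16	7	17	2	5	1134564.64
M153	gamma	150	7294	5054	1919	6973	61666.43	58952.56	321	273	18	10	20	0	0	1339563.86
M166	gamma	300	7147	3924	2884	6808	63160.99	60165.10	339	306	11	7	15	3	2	1268436.58
M193	gamma	450	8816	6328	1861	8189	52509.46	48774.95	627	558	38	13	18	9	30	685805.42
M225	xray	75	6158	4389	1248	5637	76281.71	69827.87	521	460	26	16	19	10	42	825335.89
M232	xray	75	9546	6859	2188	9047	47529.57	45045.05	499	445	30	14	10	10	45	861723.45
M238	xray	75	8128	4378	3303	7681	55982.29	52903.54	447	406	14	13	14	4	51	961968.68
M242	xray	75	18612	10619	7652	18271	23534.56	23103.37	341	285	18	15	23	7	21	1260997.07
M244	xray	75	9392	7172	1984	9156	46963.74	45783.65	236	188	18	12	18	3	34	1822033.90
M314	xray	150	6271	4425	1357	5782	74368.73	68569.61	489	425	24	22	18	7	28	879345.60
M317	xray	150	6069	4216	1372	5588	76950.61	70851.87	481	421	24	16	20	8	33	893970.89
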