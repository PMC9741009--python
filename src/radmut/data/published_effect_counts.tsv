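line_id	missense	missense_pct	nonsense	nonsense_pct	silent	silent_pct	high	high_pct	low	low_pct	moderate	moderate_pct	modifier	modifier_pct
M149	131	60.93	1	0.465	83	38.605	42	0.261	91	0.565	147	0.913	15823	98.261
M153	204	55.135	3	0.811	163	44.054	54	0.286	209	1.108	223	1.183	18371	97.423
M166	422	57.415	4	0.544	309	42.041	48	0.129	374	1.006	468	1.259	36281	97.606
M193	148	56.705	1	0.383	112	42.912	52	0.253	141	0.685	162	0.787	20238	98.276
M225	87	55.769	0	0.00	69	44.231	28	0.221	82	0.646	95	0.749	12481	98.384
M232	204	58.621	4	1.149	140	40.23	64	0.273	164	0.7	231	0.986	22966	98.041
M238	419	60.201	4	0.575	273	39.224	74	0.173	353	0.827	458	1.073	41798	97.927
M242	1363	58.198	26	1.11	953	40.692	264	0.245	1294	1.203	1479	1.375	104546	97.177
M244	158	55.052	5	1.742	124	43.206	58	0.287	159	0.787	167	0.826	19829	98.1
M314	107	52.709	2	0.985	94	46.305	46	0.363	107	0.845	118	0.931	12398	97.861
M317	100	49.751	4	1.99	97	48.259	35	0.292	111	0.925	108	0.9	11751	97.884
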