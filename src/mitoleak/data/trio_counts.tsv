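trio	role	individual	motif	permutation	count	aligned_reads
Trio1	mother	S1	A	T-A	252906	8478213
Trio1	mother	S1	A	C-G	11	8478213
Trio1	mother	S1	B	A-C-G	411706	8478213
Trio1	mother	S1	B	G-T-A	1	8478213
Trio1	mother	S1	C	G-T-G	0	5397958
Trio1	mother	S1	C	A-C-A	80	5397958
Trio1	mother	S1	D	T-C-A	53821	5397958
Trio1	mother	S1	D	C-T-G	0	5397958
Trio1	father	S2	A	T-A	27	10785620
Trio1	father	S2	A	C-G	323903	10785620
Trio1	father	S2	B	A-C-G	45	10785620
Trio1	father	S2	B	G-T-A	318	10785620
Trio1	father	S2	C	G-T-G	0	3516279
Trio1	father	S2	C	A-C-A	67	3516279
Trio1	father	S2	D	T-C-A	2	3516279
Trio1	father	S2	D	C-T-G	0	3516279
Trio1	child	S3	A	T-A	322675	10872601
Trio1	child	S3	A	C-G	6	10872601
Trio1	child	S3	B	A-C-G	520938	10872601
Trio1	child	S3	B	G-T-A	1	10872601
Trio1	child	S3	C	G-T-G	0	5990929
Trio1	child	S3	C	A-C-A	85	5990929
Trio1	child	S3	D	T-C-A	60397	5990929
Trio1	child	S3	D	C-T-G	0	5990929
Trio2	mother	S4	A	T-A	237212	8459438
Trio2	mother	S4	A	C-G	1	8459438
Trio2	mother	S4	B	A-C-G	412320	8459438
Trio2	mother	S4	B	G-T-A	25	8459438
Trio2	mother	S4	C	G-T-G	0	14010367
Trio2	mother	S4	C	A-C-A	153	14010367
Trio2	mother	S4	D	T-C-A	12	14010367
Trio2	mother	S4	D	C-T-G	162	14010367
Trio2	father	S5	A	T-A	102	7981400
Trio2	father	S5	A	C-G	2088	7981400
Trio2	father	S5	B	A-C-G	19	7981400
Trio2	father	S5	B	G-T-A	326148	7981400
Trio2	father	S5	C	G-T-G	0	5930021
Trio2	father	S5	C	A-C-A	86	5930021
Trio2	father	S5	D	T-C-A	0	5930021
Trio2	father	S5	D	C-T-G	0	5930021
Trio2	child	S6	A	T-A	234586	8184182
Trio2	child	S6	A	C-G	2	8184182
Trio2	child	S6	B	A-C-G	343282	8184182
Trio2	child	S6	B	G-T-A	16	8184182
Trio2	child	S6	C	G-T-G	0	4096769
Trio2	child	S6	C	A-C-A	77	4096769
Trio2	child	S6	D	T-C-A	0	4096769
Trio2	child	S6	D	C-T-G	52	4096769
Trio3	mother	S7	A	T-A	237181	9500936
Trio3	mother	S7	A	C-G	1	9500936
Trio3	mother	S7	B	A-C-G	414430	9500936
Trio3	mother	S7	B	G-T-A	0	9500936
Trio3	mother	S7	C	G-T-G	86457	5571846
Trio3	mother	S7	C	A-C-A	5	5571846
Trio3	mother	S7	D	T-C-A	0	5571846
Trio3	mother	S7	D	C-T-G	1	5571846
Trio3	father	S8	A	T-A	183	8124010
Trio3	father	S8	A	C-G	5986	8124010
Trio3	father	S8	B	A-C-G	118	8124010
Trio3	father	S8	B	G-T-A	115	8124010
Trio3	father	S8	C	G-T-G	0	6293236
Trio3	father	S8	C	A-C-A	162098	6293236
Trio3	father	S8	D	T-C-A	0	6293236
Trio3	father	S8	D	C-T-G	0	6293236
Trio3	child	S9	A	T-A	212099	7307511
Trio3	child	S9	A	C-G	2	7307511
Trio3	child	S9	B	A-C-G	385255	7307511
Trio3	child	S9	B	G-T-A	0	7307511
Trio3	child	S9	C	G-T-G	71994	9868902
Trio3	child	S9	C	A-C-A	4	9868902
Trio3	child	S9	D	T-C-A	0	9868902
Trio3	child	S9	D	C-T-G	0	9868902
Trio4	mother	S10	A	T-A	254517	10151535
Trio4	mother	S10	A	C-G	1	10151535
Trio4	mother	S10	B	A-C-G	468255	10151535
Trio4	mother	S10	B	G-T-A	0	10151535
Trio4	mother	S10	C	G-T-G	0	3158406
Trio4	mother	S10	C	A-C-A	38	3158406
Trio4	mother	S10	D	T-C-A	26346	3158406
Trio4	mother	S10	D	C-T-G	2	3158406
Trio4	father	S11	A	T-A	238561	8416736
Trio4	father	S11	A	C-G	2	8416736
Trio4	father	S11	B	A-C-G	402764	8416736
Trio4	father	S11	B	G-T-A	0	8416736
Trio4	father	S11	C	G-T-G	0	7067065
Trio4	father	S11	C	A-C-A	94	7067065
Trio4	father	S11	D	T-C-A	23	7067065
Trio4	father	S11	D	C-T-G	76244	7067065
Trio4	child	S12	A	T-A	235512	8141655
Trio4	child	S12	A	C-G	3	8141655
Trio4	child	S12	B	A-C-G	469861	8141655
Trio4	child	S12	B	G-T-A	0	8141655
Trio4	child	S12	C	G-T-G	1	8799863
Trio4	child	S12	C	A-C-A	145	8799863
Trio4	child	S12	D	T-C-A	78760	8799863
Trio4	child	S12	D	C-T-G	4	8799863
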