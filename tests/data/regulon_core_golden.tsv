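tu_id	lead_gene	replicon	peak_center	support	distance_to_tss	shared_peak	site_seq	site_score	role	mechanism	mixed_direction	enrich_D56A	enrich_D56E	enrich_WT	enrich_dcenK
TU0000	TU0000g0	chr1	1755	16	-26	False	TGACTCCGGATTCAG	15.9769	-	repression_consistent	False	1.494	4.305	3.426	1.442
TU0003	TU0003g0	chr1	6308	16	-49	False	TGACCTGCACCTCAC	12.7165	+	activation_consistent	False	1.729	3.492	2.652	1.493
TU0004	TU0004g0	chr1	7260	16	-11	False	AGGAACGGCATTCAG	12.3188	-	repression_consistent	False	1.344	4.498	2.794	1.402
TU0005	TU0005g0	chr1	8255	16	-16	False	GGAGACGGGACTCAA	13.6788	-	unclassified	False	1.521	5.654	2.737	1.474
TU0006	TU0006g0	chr1	9293	16	-64	False	AGAGCCTCGCCTCAT	13.3083	+	activation_consistent	False	1.565	4.635	4.282	1.627
TU0008	TU0008g0	chr1	12295	16	-46	False	TCAGCCGGAAATGAC	12.442	+	activation_consistent	False	1.182	4.169	3.267	1.39
TU0009	TU0009g0	chr1	13306	16	-67	False	TGAAGCCCAATTCAT	17.6158	+	activation_consistent	False	1.709	5.19	3.102	1.687
TU0010	TU0010g0	chr1	13920	16	-70	False	TGGCTGCGCATGCAT	10.3089	+	activation_consistent	False	1.911	4.447	2.877	1.682
TU0015	TU0015g0	chr1	21490	16	-50	False	TCAGCGTCCATTCAA	16.7268	+	activation_consistent	False	1.735	4.78	3.214	1.627
TU0016	TU0016g0	chr1	23521	16	-49	False	TGAGAGTCCACTGAC	15.6367	+	activation_consistent	False	1.852	4.581	3.47	1.794
TU0017	TU0017g0	chr1	26927	16	-48	False	TGAGGCCCCCCTCAA	13.5438	+	activation_consistent	False	1.819	4.318	3.321	1.524
TU0018	TU0018g0	chr1	28450	16	-61	False	TGACCGGGCATTGAT	17.3719	+	activation_consistent	False	1.531	4.694	3.235	1.727
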