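locus_id	gene_name	annotation	replicon	peak_center	shared_peak	enrich_D56E	enrich_WT	enrich_dcenK	enrich_D56A	motif_seq	lfc_D56E	fdr_D56E	lfc_dcenK	fdr_dcenK	lfc_D56A	fdr_D56A	role	category	tm_domain	signal_peptide	essential
RSP_0847	RSP_0847	two component transcriptional regulator winged helix family	chr1	2597500	N	1.4	--	--	--	ACACGAGCGCGTGAG	0.49	9.1E-07	-5.16	5.9E-07	-4.34	1.1E-06	+	envelope_extracytoplasmic	N	N	Y
RSP_0672	tolQ	Cell division and transport-associated protein TolQ	chr1	2413901	N	4.5	3.2	1.6	1.6	TGACGCAGATGTGTT	2.51	2.3E-03	-0.58	6.7E-03	n.s.	n.s.	+	envelope_extracytoplasmic	Y	N	Y
RSP_1807	RSP_1807	putative secreted protein	chr1	392575	N	3.8	1.7	--	--	TCGCAAAACCTTGAT	2.72	4.1E-06	-2.04	1.4E-04	-1.97	8.0E-05	+	envelope_extracytoplasmic	N	Y	N
RSP_1834	RSP_1834	Beta-lactamase superfamily	chr1	426084	N	2.8	2.3	--	--	TGACGCAGCTGTGAA	2.47	4.4E-06	-5.56	1.7E-05	-5.43	2.8E-07	+	envelope_extracytoplasmic	N	Y	N
RSP_1199	RSP_1199	L,D-transpeptidases/carboxypeptidases	chr1	2970115	N	2.9	2.2	--	--	TGACGCGGGCGTGAA	2.47	4.4E-05	-1.98	9.9E-05	-1.39	5.1E-04	+	envelope_extracytoplasmic	N	Y	N
RSP_1200	RSP_1200	uncharacterized protein with SCP/PR1 domains	chr1	2970115	Y	2.9	2.2	--	--	TGAGTTGCATTTGAA	0.52	1.6E-05	-0.52	3.7E-03	n.s.	n.s.	+	envelope_extracytoplasmic	Y	Y	N
RSP_1880	RSP_1880	peptidoglycan-binding domain-containing protein	chr1	478200	N	2.0	1.6	--	--	TCACATGGCCGTGTT	-1.80	4.6E-06	1.24	5.3E-03	n.s.	n.s.	-	envelope_extracytoplasmic	N	Y	N
RSP_1168	surA	PpiC-type peptidyl-prolyl cis-trans isomerase	chr1	2933000	N	1.8	1.4	--	--	TGACATGATCGTGTG	3.40	2.8E-06	-1.48	9.1E-04	-0.74	1.1E-02	+	envelope_extracytoplasmic	N	Y	N
RSP_1169	secA	protein translocase subunit secA	chr1	2933000	Y	1.8	1.4	--	--	TCGCGCGACGTTGAC	1.80	3.0E-06	-0.94	1.7E-03	n.s.	n.s.	+	envelope_extracytoplasmic	N	N	Y
RSP_1844	RSP_1844	putative periplasmic protein	chr1	435330	N	2.0	--	--	--	TGGCGCAGGCGTGAC	1.25	2.2E-05	n.s.	n.s.	n.s.	n.s.	+	envelope_extracytoplasmic	N	Y	N
RSP_2718	RSP_2718	putative outer membrane protein	chr1	1368770	N	2.0	--	--	--	TCACCTCCTCGTGAG	3.09	8.2E-04	-4.76	5.9E-07	-6.49	2.9E-07	+	envelope_extracytoplasmic	Y	Y	N
RSP_0890	mlaC	Intermembrane phospholipid transport system binding protein	chr1	2641460	N	1.8	--	--	--	TCAATACTTGGTGAT	2.47	1.7E-03	-0.74	2.2E-03	-1.14	6.9E-04	+	envelope_extracytoplasmic	N	Y	N
RSP_0730	RSP_0730	TIGR02302 family protein	chr1	2473818	N	3.2	1.9	--	--	TCACTTCGCCGTCAT	2.23	2.0E-04	-1.63	3.7E-04	-0.63	1.5E-02	+	envelope_extracytoplasmic	Y	N	N
RSP_0704	RSP_0704	ABC peptide transporter substrate binding protein	chr1	2450500	N	2.0	1.4	--	--	TCACGCAATCGCAAC	1.77	2.1E-05	-0.62	4.0E-03	n.s.	n.s.	+	envelope_extracytoplasmic	Y	Y	N
RSP_1860	RSP_1860	cell wall hydrolase involved in spore germination	chr1	458700	N	1.6	1.7	--	--	TGGCAAAAATGTCAC	1.42	2.1E-03	-0.61	1.1E-02	-1.25	6.6E-04	+	envelope_extracytoplasmic	N	Y	N
RSP_2847	RSP_2847	putative lipoprotein (predicted lipid binding domain)	chr1	1458970	N	1.6	1.6	--	1.6	TCTTCGTCCCCTGAC	-1.20	1.1E-03	0.97	2.7E-02	n.s.	n.s.	-	envelope_extracytoplasmic	Y	Y	N
RSP_0915	RSP_0915	putative periplasmic protein	chr1	2665900	N	1.5	--	--	--	TGACAAACGTGTTAG	1.43	5.7E-04	n.s.	n.s.	n.s.	n.s.	+	envelope_extracytoplasmic	N	Y	N
RSP_2006	RSP_2006	uncharacterized protein involved in outer membrane biogenesis	chr1	606400	N	1.6	--	--	--	TCACGCAATCCTGAC	0.67	7.9E-04	n.s.	n.s.	n.s.	n.s.	+	envelope_extracytoplasmic	Y	N	N
RSP_1413	RSP_1413	TRAP-T family transporter periplasmic binding component	chr2	930800	N	1.7	1.6	--	--	TCACAAATGCATTAC	-1.34	1.2E-02	0.89	5.8E-02	n.s.	n.s.	-	envelope_extracytoplasmic	Y	Y	N
RSP_2561	exoP	putative succinoglycan biosynthesis transport protein ExoP	chr1	1207306	N	2.7	1.8	--	1.5	TCACGATCCTCTCAG	n.s.	n.s.	n.s.	n.s.	-0.60	4.2E-02	+	envelope_extracytoplasmic	Y	N	N
RSP_1024	RSP_1024	Putative MoxR family protein	chr1	278100	N	1.7	--	--	--	TCACGATCATTTGTG	0.85	9.1E-05	-0.56	6.1E-03	-0.84	3.8E-03	+	envelope_extracytoplasmic	Y	N	N
RSP_1000	dsbC	Disulphide bond corrector protein DsbC	chr1	2758300	N	2.8	1.5	--	--	TGGCGCAGTTGTGAC	2.48	5.9E-06	-1.64	1.9E-03	-2.07	8.8E-05	+	envelope_extracytoplasmic	N	Y	N
RSP_0999	RSP_0999	putative transcriptional regulator	chr1	2758300	Y	2.8	1.5	--	--	TCGCGCGACTGTGGC	1.37	4.5E-05	n.s.	n.s.	n.s.	n.s.	+	envelope_extracytoplasmic	N	N	N
RSP_2633	ccmF	Cytochrome c maturation protein CcmF	chr1	1273100	N	1.6	--	--	--	TGACGGGAAGGCGAC	1.06	3.2E-02	-0.21	3.0E-02	n.s.	n.s.	+	envelope_extracytoplasmic	Y	N	Y
RSP_2685	cycH	Putative cytochrome c-type biogenesis protein cycH	chr1	1330900	N	2.2	--	--	--	TGACGGGATATTGAC	0.79	1.1E-04	n.s.	n.s.	-0.89	1.6E-02	+	envelope_extracytoplasmic	Y	N	Y
RSP_2686	soxB	putative sarcosine oxidase beta subunit	chr1	1330900	Y	2.2	--	--	--	TCGCAACTCGGTGAT	3.76	6.0E-05	-1.21	5.5E-04	n.s.	n.s.	+	envelope_extracytoplasmic	N	N	N
RSP_1465	RSP_1465	putative aminoglycoside phosphotransferase	chr1	51549	N	1.9	1.5	--	--	TCACGCAATCTTTAT	0.78	4.5E-05	-1.14	1.2E-03	-1.42	1.6E-03	+	envelope_extracytoplasmic	N	N	N
RSP_3067	RSP_3067	hypothetical protein	chr2	106900	N	1.6	--	--	--	TCGCAGGATCTTGAT	4.51	1.9E-06	n.s.	n.s.	-1.27	8.0E-03	+	envelope_extracytoplasmic	Y	N	N
RSP_1496	RSP_1496	Lysozome-like putative lipoprotein	chr1	84880	N	2.5	1.6	--	--	TCGCGTTTTTCTGAA	1.37	1.3E-03	n.s.	n.s.	n.s.	n.s.	+	envelope_extracytoplasmic	N	Y	N
RSP_2410	rpoH1	RNA polymerase sigma 32 subunit RpoH	chr1	1039245	N	4.1	2.5	--	--	TTACATTCGCGTGAT	3.20	3.2E-04	-3.38	1.4E-06	-2.30	4.6E-06	+	cytoplasmic	N	N	N
RSP_0559	msrA	Peptide methionine sulfoxide reductase	chr1	2296600	N	1.6	--	--	--	TGGCGCGAGCGTGAT	3.11	8.9E-06	-1.78	1.6E-04	-1.41	4.1E-04	+	cytoplasmic	N	N	N
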