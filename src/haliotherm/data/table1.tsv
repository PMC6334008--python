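gene_name	membership	readcount_heat_RL	readcount_control_RL	log2fc_RL	readcount_heat_YL	readcount_control_YL	log2fc_YL
60 kDa heat shock protein	both	22940.4	1697.5	3.8	20808.9	1119.9	4.2
Activator of 90 kDa heat shock protein ATPase homolog 1	both	5238.0	55.9	6.6	3873.5	50.9	6.2
DnaJ homolog subfamily A member 1	both	14258.0	185.5	6.3	11714.6	111.0	6.7
DnaJ homolog subfamily B member 4	both	71733.8	474.1	7.2	76468.9	365.2	7.7
DnaJ homolog subfamily B member 9	both	442.4	19.8	4.5	318.0	16.1	4.3
DnaJ homolog subfamily C member 3	both	1816.7	101.8	4.2	1586.5	83.3	4.3
Haliotis discus hannai heat shock protein 90 mRNA	both	18359.5	290.8	6.0	29654.7	230.6	7.0
Heat shock 70 kDa protein	both	517199.6	157.6	11.7	512778.1	193.8	11.4
Heat shock 70 kDa protein C	both	40.2	3.1	3.7	91.9	2.7	5.1
Heat shock 70 kDa protein cognate 4	both	200721.2	6687.8	4.9	224124.7	4084.2	5.8
Heat shock 70 kDa protein 5-1	both	89771.3	3321.8	4.8	135757.5	2553.6	5.7
Heat shock 70 kDa protein 5-2	both	124.3	11.6	3.4	257.6	13.5	4.3
Heat shock protein 70 B2-1	both	1026410.4	601.0	10.7	953619.4	531.1	10.8
Heat shock protein 70 B2-2	both	103617.9	120.2	9.8	98169.6	108.6	9.8
Heat shock protein 83	both	351431.0	6616.4	5.7	389863.4	4789.3	6.3
Heat shock protein beta-2	both	266.7	4.7	5.8	137.1	2.5	5.8
Small heat shock protein 26-1	both	104467.4	28.1	11.9	109373.2	42.0	11.3
Small heat shock protein 26-2	both	81010.9	25.4	11.6	118746.7	46.2	11.3
Small heat shock protein 26-3	both	754714.9	417.6	10.8	795488.0	395.2	11.0
Stress-70 protein, mitochondrial	both	4156.8	1003.4	2.1	6168.8	854.8	2.9
DnaJ homolog subfamily A member 2	RL_only	5218.5	1508.9	1.8
DnaJ homolog subfamily B member 2	RL_only	308.6	95.0	1.7
DnaJ homolog subfamily C member 10	RL_only	23.3	2.8	3.0
DnaJ homolog subfamily C member 24	RL_only	25.0	120.8	-2.3
DnaJ homolog subfamily C member 27	RL_only	42.0	7.7	2.4
DnaJ homolog subfamily C member 7	RL_only	3339.3	1067.1	1.6
Heat shock 70 kDa protein 13	RL_only	32.4	5.6	2.5
Heat shock 70 kDa protein 4	RL_only	133179.5	549.7	7.9
Heat shock 70 kDa protein cognate 4 (RL)	RL_only	80171.5	1847.4	5.4
Heat shock factor protein 1	RL_only	235.3	44.7	2.4
Small heat shock protein	RL_only	112213.5	112.6	10.0
Heat shock 70 kDa protein 4 (YL)	YL_only				152438.4	406.7	8.6
Heat shock 70 kDa protein cognate 4 (YL)	YL_only				75878.2	1199.4	6.0
Heat shock 70 kDa protein 5	YL_only				28.2	0.9	4.9
Small heat shock protein [Tegillarca granosa]	YL_only				131461.7	144.5	9.8
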