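subject	session	run	group	iso_pct	bsr_pct	heart_rate_bpm	etco2_mmhg	temperature_c
O	1	1	BS	1.2	10.9	141	28	36.6
O	1	2	BS	1.2	7.7	140	28	36.6
O	1	3	BS	1.2	12.8	136	29	36.8
O	1	4	BS	1.2	11.9	135	29	36.8
O	1	5	BS	1.2	2.6	135	29	36.9
O	1	6	BS	1.2	3.8	142	29	37
O	1	8	BS	1.2	1.2	135	28	37.1
O	1	9	BS	1.2	1.6	131	28	37.2
O	2	10	BS	1.3	38.9	131	26	37.1
O	2	11	BS	1.3	23.3	134	27	37
O	2	12	BS	1.3	32.1	136	27	37
O	2	13	BS	1.3	18	139	27	37
O	2	14	BS	1.3	27.9	140	27	37
O	2	15	BS	1.3	36.7	140	27	37
O	2	16	BS	1.3	26.3	142	28	37.1
O	2	17	BS	1.3	18.4	139	28	37
O	2	18	BS	1.1	14.1	140	28	37
O	2	19	BS	1.1	11.1	142	28	37
O	2	20	BS	1.1	16.5	140	28	37
O	3	27	BS	0.8	1.5	147	27	37.7
O	3	7	SW	1.2	0	157	29	37
O	3	21	SW	0.8	0	147	26	37.3
O	3	22	SW	0.8	0	148	27	37.4
O	3	23	SW	0.8	0	149	27	37.5
O	3	24	SW	0.8	0	148	27	37.5
O	3	25	SW	0.8	0	149	27	37.7
O	3	26	SW	0.8	0	146	27	37.7
O	3	28	SW	0.8	0	147	27	37.8
T	4	31	BS	1.2	1.72	148	27	37.0
T	4	32	BS	1.2	0.56	156	27	37.1
T	4	33	BS	1.2	2.92	157	27	37.0
T	4	34	BS	1.2	1.68	160	27	36.8
T	4	35	BS	1.2	3.10	160	27	36.4
T	4	36	BS	1.2	0.86	159	26	36.3
T	4	38	BS	1.2	1.90	159	27	36.6
T	4	29	SW	1.2	0	146	26	36.6
T	4	30	SW	1.2	0	148	26	36.8
T	4	37	SW	1.2	0	159	27	36.3
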