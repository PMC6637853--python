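sample_id	group	phenotype	gebv	mapped_reads
H-OA1	High	OA	2.11	970350
H-OA2	High	OA	1.54	745742
H-OA3	High	OA	3.20	1009408
H-OA4	High	OA	3.25	1051535
H-OA5	High	OA	2.16	1052657
H-OA6	High	OA	2.08	1289704
H-OA7	High	OA	1.58	610678
H-OA8	High	OA	1.92	564255
H-OA9	High	OA	4.14	555136
H-OA10	High	OA	2.61	607145
H-OA11	High	OA	3.89	1035882
H-OA12	High	OA	2.84	520790
H-OA13	High	OA	1.76	584448
L-OA1	Low	OA	-7.06	605324
L-OA2	Low	OA	-4.98	1308497
L-OA3	Low	OA	-5.51	703560
L-OA4	Low	OA	-2.41	525015
L-OA5	Low	OA	-1.54	594924
L-OA6	Low	OA	-2.95	563260
L-OA7	Low	OA	-2.43	349772
L-OA8	Low	OA	-7.03	557486
L-OA9	Low	OA	-3.48	656226
L-OA10	Low	OA	-2.67	685506
L-OA11	Low	OA	-1.63	690291
L-OA12	Low	OA	-8.07	748090
L-OA13	Low	OA	-4.14	689313
L-OA14	Low	OA	-7.36	602604
L-OA15	Low	OA	-2.91	732483
H-CLA1	High	CLA	0.008	439844
H-CLA2	High	CLA	0.012	1152736
H-CLA3	High	CLA	0.008	938908
H-CLA4	High	CLA	0.012	1308497
H-CLA5	High	CLA	0.011	235852
H-CLA6	High	CLA	0.016	874538
H-CLA7	High	CLA	0.022	976093
H-CLA8	High	CLA	0.025	1039805
H-CLA9	High	CLA	0.009	555136
H-CLA10	High	CLA	0.009	918555
H-CLA11	High	CLA	0.012	675360
H-CLA12	High	CLA	0.012	772395
H-CLA13	High	CLA	0.019	713501
H-CLA14	High	CLA	0.019	500697
H-CLA15	High	CLA	0.014	636795
L-CLA1	Low	CLA	-0.008	457706
L-CLA2	Low	CLA	-0.013	532780
L-CLA3	Low	CLA	-0.017	988632
L-CLA4	Low	CLA	-0.011	521652
L-CLA5	Low	CLA	-0.010	300196
L-CLA6	Low	CLA	-0.009	1264789
L-CLA7	Low	CLA	-0.016	685506
L-CLA8	Low	CLA	-0.013	702016
L-CLA9	Low	CLA	-0.015	605442
L-CLA10	Low	CLA	-0.013	677737
L-CLA11	Low	CLA	-0.009	522944
L-CLA12	Low	CLA	-0.010	658923
L-CLA13	Low	CLA	-0.010	752121
L-CLA14	Low	CLA	-0.018	1306312
L-CLA15	Low	CLA	-0.010	511704
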