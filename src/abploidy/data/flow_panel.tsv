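sample_id	predicted_ploidy	genome_size_pg	f_coefficient
A10	4	2.01	0.4626290
A2	4	1.98	0.4874794
A3	4	1.89	0.4989708
A5	8	3.95	0.7521384
A7	8	3.91	0.7375464
A8	6		0.6590505
A9	4		0.6591026
B2	6		0.6851450
C10	4	2.05	0.5537149
C11	4	2.07	0.6018592
C12	4	2.16	0.7253990
C13	4	2.10	0.5612218
C2	8	4.11	0.6370933
C3	8	3.91	0.6462146
C6	8	4.03	0.6586822
C7	8	4.02	0.6511071
C9	4	1.98	0.5090996
D11	4	2.03	0.5282259
D12	4	1.98	0.5797022
D13	4	2.00	0.5316529
D4	4	2.02	0.4880390
D5	4		0.5689966
D6	4		0.5329394
D7	4	1.98	0.5285508
D9	4		0.5883302
E12	4	2.25	0.9306997
E13	4	1.95	0.5329020
E3	4		0.5596739
E9	4	1.90	0.6129666
F13	4		0.5824805
F2	8	3.89	0.7088652
F9	4		0.5298573
H1	8	4.00	0.6649627
H2	6		0.6356703
H5	4	1.90	0.5980863
H6	4	2.09	0.5114880
I12	4	3.92	0.5655735
K12	4		0.8911014
K13	8	4.06	0.6993060
K2	6	2.97	0.6762899
Y1	8	4.04	0.6719352
Y10	4	1.94	0.5231192
Y11	4	1.94	0.5305513
Y12	6	3.09	0.4818650
Y13	4	1.96	0.5409885
Y14	4	2.00	0.6399941
Y15	4	1.99	0.5887442
Y16	4	2.04	0.5315376
Y17	4	2.03	0.9306310
Y18	4	1.92	0.5848370
Y19	4	1.96	0.7527237
Y20	4	1.96	0.4969260
Y21	4		0.7338246
Y22	4	1.97	0.5330414
Y23	4	1.92	0.5324003
Y24	4		0.5332007
Y25	8	4.00	0.6457727
Y26	4	2.07	0.6786632
Y27	4	2.25	0.9150782
Y28	4	1.97	0.5485428
Y3	8	3.95	0.7125974
Y30	6	3.12	0.5107852
Y31	4	1.92	0.6035490
Y32	4		0.5363337
Y33	6		0.5013505
Y34	4	2.02	0.6940500
Y35	6	3.09	0.4918896
Y36	8	3.93	0.7040981
Y37	6		0.5104751
Y38	4		0.5411762
Y39	8		0.7010347
Y4	4	2.02	0.5241846
Y40	4		0.5249877
Y41	4		0.5479036
Y43	8		0.7306636
Y44	6		0.6423147
Y45	4		0.5160759
Y46	4		0.5224431
Y47	4		0.5202388
Y48	8		0.6391666
Y49	8		0.7164914
Y51	8		0.7094003
Y53	8		0.7097670
Y55	4		0.6842193
Y56			0.8527072
Y57	4		0.5704187
Y6	8	4.05	0.6671984
Y7	6	3.17	0.5155284
Y9	8		0.6446644
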