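site_id	pH	humidity	TP	TOC	TN	Fe	Ca	K	CEC
BZ	74.3	3.91	13.01	4.44	0.45	20.86	4775.63	78.88	19.80
BA1	7.88	4.06	22.70	1.72	0.39	18.58	1080.46	86.19	8.80
BA2	6.85	0.08	5.14	0.26	0.70	17.85	1400.71	103.63	0.95
BA3	7.36	2.07	13.92	0.99	0.545	18.21	1240.58	94.91	4.87
KA1	6.68	4.31	1.30	0.52	0.46	11.58	2227.83	88.29	2.35
KA2	6.65	6.05	13.33	1.34	0.56	12.21	2293.08	98.48	7.70
KA3	6.61	2.56	3.48	0.47	0.52	11.58	2227.83	88.29	1.75
KS1	5.74	2.08	1.49	0.60	1.41	13.26	2599.17	91.52	5.10
KS2	7.82	6.52	1.14	1.69	1.56	12.93	3142.08	79.09	13.00
KS3	7.61	1.52	1.21	0.54	0.70	16.01	1298.42	50.75	4.30
KS4	6.42	1.81	1.00	0.74	0.88	13.95	1452.50	51.84	4.45
KS5	6.46	2.13	1.10	1.39	0.72	12.93	3142.08	79.09	5.90
KS6	6.74	1.47	0.72	0.59	0.40	16.01	1298.42	50.75	5.00
SB1	8.19	6.81	2.15	1.21	0.51	14.53	4812.92	170.45	6.75
SB2	7.99	3.82	1.88	0.95	0.65	14.34	6004.17	163.68	7.45
SB3	8.00	8.87	0.92	1.44	0.46	14.53	4812.92	170.45	20.55
GF1	8.22	4.24	3.16	2.24	0.61	17.36	4923.75	131.03	8.00
GF2	7.77	6.04	18.39	4.70	0.46	17.45	5740.42	274.63	11.50
GF3	8.34	3.63	6.64	1.96	0.57	17.36	4923.75	131.03	7.75
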