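gene	geo_mean	arith_mean	min_ct	max_ct	sd_mad	cv_percent	r	p_value
SsuACT	21.55	21.56	20.64	22.68	0.7	3.25	0.987	0.001
SsuUBCJ2	24.49	24.51	23.01	26.38	0.84	3.44	0.987	0.001
SsuCal7	20.59	20.61	19.51	21.7	0.73	3.53	0.977	0.001
SsuHis	22.05	22.07	20.62	23.43	0.8	3.63	0.93	0.007
SsuRIB	22.3	22.31	21.36	23.54	0.69	3.1	0.928	0.008
SsuUDP	24.83	24.88	23.24	27.97	1.35	5.42	0.926	0.008
SsuTUA1	23.86	23.88	22.85	25.47	0.85	3.58	0.92	0.009
SsuUBC17	21.6	21.64	20.03	24.14	1.17	5.38	0.919	0.01
SsuTUA2	21.98	21.98	21.21	22.92	0.48	2.18	0.905	0.013
SsuUBC2	21.5	21.56	19.61	24.28	1.31	6.07	0.887	0.018
SsuTUB	23.35	23.39	21.69	25.6	1.2	5.11	0.858	0.029
SsuCas	23.35	23.71	20.28	33.38	3.22	13.6	0.83	0.041
SsuMDH	25.54	25.56	24.46	26.86	0.82	3.2	0.824	0.044
SsueIF5	21.43	21.46	19.81	23.24	0.8	3.72	0.761	0.079
SsuGTP	22.86	22.87	21.98	24.3	0.52	2.28	0.742	0.092
SsuUBC1	25.31	25.32	24.18	26.41	0.68	2.68	0.741	0.092
SsuGAPDH	20.11	20.11	19.32	20.72	0.46	2.3	0.634	0.176
ColGAPDH	25.17	25.19	24.19	26.21	0.64	2.53	0.602	0.206
SsuMet2	18.01	18.03	16.75	19.27	0.78	4.35	0.513	0.296
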