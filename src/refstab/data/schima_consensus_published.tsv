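gene	genorm	normfinder	bestkeeper	geo_mean_rank	combined_rank
SsuACT	3	1	1	1.44	1
SsuRIB	1	2	5	2.15	2
SsuTUA1	1	4	6	2.88	3
SsuCal7	4	3	3	3.3	4
SsuMDH	2	5	8	4.31	5
SsuUBCJ2	8	6	2	4.58	6
SsuTUA2	5	7	7	6.26	7
SsuHis	7	9	4	6.32	8
SsuGTP	6	8	10	7.83	9
SsueIF5	9	10	9	9.32	10
SsuUBC1	10	12	11	10.97	11
SsuGAPDH	11	13	12	11.97	12
ColGAPDH	12	14	13	12.97	13
SsuTUB	14	11	16	13.51	14
SsuMet2	13	18	14	14.85	15
SsuUBC17	15	15	15	15	16
SsuUBC2	16	16	17	16.33	17
SsuUDP	17	17	18	17.33	18
SsuCas	18	19	19	18.66	19
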