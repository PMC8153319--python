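gene	average	min_ct	max_ct	range_ct
SsuACT	21.562	20.638	22.681	2.043
SsuTUA1	23.877	22.855	25.474	2.62
SsuTUA2	21.984	21.214	22.918	1.704
SsuTUB	23.388	21.687	25.599	3.911
ColGAPDH	25.185	24.188	26.214	2.026
SsuCal7	20.608	19.505	21.703	2.198
SsuCas	23.709	20.28	33.379	13.099
SsueIF5	21.455	19.81	23.243	3.433
SsuGAPDH	20.113	19.325	20.723	1.398
SsuGTP	22.875	21.975	24.304	2.328
SsuHis	22.073	20.623	23.434	2.811
SsuMDH	25.556	24.456	26.864	2.408
SsuMet2	18.032	16.752	19.275	2.523
SsuRIB	22.314	21.358	23.539	2.181
SsuUBC1	25.32	24.18	26.41	2.229
SsuUBC17	21.644	20.03	24.137	4.107
SsuUBC2	21.556	19.607	24.277	4.67
SsuUBCJ2	24.512	23.014	26.375	3.361
SsuUDP	24.877	23.242	27.973	4.73
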