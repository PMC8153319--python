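gene	tissue	mean_ct	sd_ct	n
SsuACT	leaf	21.125	2.752	3
SsuACT	bud	20.818	0.668	3
SsuACT	fruit	22.681	1.065	3
SsuACT	phloem	21.606	0.604	3
SsuACT	root	22.504	1.687	3
SsuACT	xylem	20.638	0.700	3
SsuTUA1	leaf	23.116	3.300	3
SsuTUA1	bud	22.855	1.102	3
SsuTUA1	fruit	24.844	1.528	3
SsuTUA1	phloem	23.801	0.875	3
SsuTUA1	root	25.474	0.979	3
SsuTUA1	xylem	23.173	0.766	3
SsuTUA2	leaf	21.717	1.408	3
SsuTUA2	bud	21.637	1.138	3
SsuTUA2	fruit	22.489	1.343	3
SsuTUA2	phloem	21.927	0.284	3
SsuTUA2	root	22.918	1.060	3
SsuTUA2	xylem	21.214	0.388	3
SsuTUB	leaf	23.802	2.168	3
SsuTUB	bud	22.222	0.634	3
SsuTUB	fruit	24.350	0.855	3
SsuTUB	phloem	22.667	0.281	3
SsuTUB	root	25.599	1.185	3
SsuTUB	xylem	21.687	0.812	3
ColGAPDH	leaf	24.569	1.992	3
ColGAPDH	bud	24.188	1.022	3
ColGAPDH	fruit	26.065	1.048	3
ColGAPDH	phloem	26.214	0.373	3
ColGAPDH	root	25.079	0.822	3
ColGAPDH	xylem	24.997	0.272	3
SsuCal7	leaf	20.469	2.372	3
SsuCal7	bud	19.505	0.960	3
SsuCal7	fruit	21.703	0.636	3
SsuCal7	phloem	20.858	0.228	3
SsuCal7	root	21.444	1.328	3
SsuCal7	xylem	19.672	1.033	3
SsuCas	leaf	22.702	3.140	3
SsuCas	bud	20.807	0.850	3
SsuCas	fruit	33.379	1.396	3
SsuCas	phloem	21.377	0.187	3
SsuCas	root	23.713	2.040	3
SsuCas	xylem	20.280	0.637	3
SsueIF5	leaf	21.820	2.500	3
SsueIF5	bud	19.810	1.122	3
SsueIF5	fruit	21.700	0.709	3
SsueIF5	phloem	21.423	0.266	3
SsueIF5	root	23.243	1.744	3
SsueIF5	xylem	20.736	0.619	3
SsuGAPDH	leaf	19.325	2.828	3
SsuGAPDH	bud	19.818	1.308	3
SsuGAPDH	fruit	20.596	0.941	3
SsuGAPDH	phloem	20.723	0.325	3
SsuGAPDH	root	20.409	0.326	3
SsuGAPDH	xylem	19.810	0.278	3
SsuGTP	leaf	22.843	2.547	3
SsuGTP	bud	21.975	1.044	3
SsuGTP	fruit	22.920	1.006	3
SsuGTP	phloem	22.966	0.437	3
SsuGTP	root	24.304	1.194	3
SsuGTP	xylem	22.239	0.692	3
SsuHis	leaf	21.538	2.536	3
SsuHis	bud	20.623	0.710	3
SsuHis	fruit	22.414	0.705	3
SsuHis	phloem	22.775	0.268	3
SsuHis	root	23.434	2.293	3
SsuHis	xylem	21.654	0.458	3
SsuMDH	leaf	24.656	3.161	3
SsuMDH	bud	24.456	0.432	3
SsuMDH	fruit	26.864	1.025	3
SsuMDH	phloem	25.655	0.211	3
SsuMDH	root	26.601	0.786	3
SsuMDH	xylem	25.104	0.760	3
SsuMet2	leaf	17.014	2.966	3
SsuMet2	bud	16.752	0.789	3
SsuMet2	fruit	17.975	1.264	3
SsuMet2	phloem	19.275	0.189	3
SsuMet2	root	18.652	1.393	3
SsuMet2	xylem	18.522	0.908	3
SsuRIB	leaf	21.848	2.851	3
SsuRIB	bud	21.358	0.871	3
SsuRIB	fruit	23.163	1.038	3
SsuRIB	phloem	22.122	0.454	3
SsuRIB	root	23.539	2.217	3
SsuRIB	xylem	21.856	0.544	3
SsuUBC1	leaf	24.886	3.431	3
SsuUBC1	bud	24.180	0.886	3
SsuUBC1	fruit	25.768	0.564	3
SsuUBC1	phloem	26.410	0.186	3
SsuUBC1	root	25.820	0.990	3
SsuUBC1	xylem	24.857	0.396	3
SsuUBC17	leaf	22.491	3.106	3
SsuUBC17	bud	20.030	1.158	3
SsuUBC17	fruit	21.798	1.360	3
SsuUBC17	phloem	21.316	0.288	3
SsuUBC17	root	24.137	2.867	3
SsuUBC17	xylem	20.090	0.560	3
SsuUBC2	leaf	22.343	2.593	3
SsuUBC2	bud	20.277	0.247	3
SsuUBC2	fruit	21.973	1.268	3
SsuUBC2	phloem	20.856	0.569	3
SsuUBC2	root	24.277	2.711	3
SsuUBC2	xylem	19.607	0.508	3
SsuUBCJ2	leaf	24.718	2.937	3
SsuUBCJ2	bud	23.014	0.667	3
SsuUBCJ2	fruit	24.883	0.758	3
SsuUBCJ2	phloem	24.601	0.248	3
SsuUBCJ2	root	26.375	2.294	3
SsuUBCJ2	xylem	23.482	0.350	3
SsuUDP	leaf	25.303	3.170	3
SsuUDP	bud	23.309	1.093	3
SsuUDP	fruit	25.399	0.965	3
SsuUDP	phloem	24.038	0.669	3
SsuUDP	root	27.973	2.695	3
SsuUDP	xylem	23.242	0.684	3
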