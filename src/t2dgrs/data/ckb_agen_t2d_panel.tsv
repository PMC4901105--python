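chrom	snp_id	gene	risk_allele	alt_allele	raf_ckb	raf_chbchs	raf_ceu	or_ckb	lo_ckb	hi_ckb	p_ckb	n_ckb	or_agen	lo_agen	hi_agen	p_agen	or_meta	lo_meta	hi_meta	p_meta	p_het	discovery_pop	in_grs	mechanism
1	rs10923931	NOTCH2	T	G	0.032	0.041	0.081	1.16	1.05	1.27	2.5e-3	93125	1.00	0.86	1.16	9.90e-1	1.11	1.02	1.20	1.07e-2	1.05e-1	EU	1	other
1	rs340874	PROX1	C	T	0.391	0.394	0.525	1.05	1.01	1.09	5.5e-3	93106	1.08	1.03	1.14	2.84e-3	1.06	1.03	1.09	5.06e-5	3.44e-1	EU	1	BC
2	rs780094	GCKR	C	T	0.488	0.459	0.591	1.08	1.04	1.12	1.3e-5	93120	1.06	1.01	1.11	2.10e-2	1.07	1.04	1.10	8.73e-7	4.96e-1	EU	1	IR
2	rs7578597	THADA	T	C	0.993	0.993	0.417	1.27	1.01	1.60	4.4e-2	93131	0.93	0.62	1.40	7.37e-1	1.18	0.96	1.44	1.12e-1	1.97e-1	EU	1	BC
2	rs243021	BCL11A	A	G	0.670	0.644	0.480	1.07	1.03	1.11	3.4e-4	93125	1.05	1.00	1.10	4.02e-2	1.06	1.03	1.09	5.56e-5	5.02e-1	EU	1	BC
2	rs7593730	RBMS1	C	T	0.836	0.808	0.818	0.98	0.93	1.02	3.4e-1	93129	1.00	0.94	1.07	9.20e-1	0.99	0.95	1.02	4.75e-1	5.33e-1	EU	0	other
2	rs3923113	GRB14	A	C	0.866	0.849	0.591	1.00	0.95	1.05	9.7e-1	93088	1.03	0.95	1.12	4.80e-1	1.01	0.97	1.05	6.73e-1	5.44e-1	SA	1	IR
2	rs2943641	IRS1	C	T	0.925	0.928	0.662	1.04	0.97	1.11	2.5e-1	93104	1.12	1.03	1.22	1.11e-2	1.07	1.02	1.13	1.07e-2	1.79e-1	EU	1	IR
3	rs1801282	PPARG	C	G	0.946	0.959	0.904	1.07	0.99	1.16	1.0e-1	93126	1.15	1.01	1.30	3.20e-2	1.09	1.02	1.16	1.22e-2	3.54e-1	EU	1	IR
3	rs6780569	UBE2E2	G	A	0.798	0.779	0.909	1.11	1.06	1.16	3.0e-6	93127	1.17	1.12	1.22	1.58e-11	1.14	1.10	1.18	8.32e-16	1.26e-1	EA	1	other
3	rs831571	PSMD6	C	T	0.634	0.589	0.763	1.06	1.02	1.10	1.5e-3	93094	1.09	1.05	1.13	1.36e-6	1.08	1.05	1.11	1.38e-8	2.42e-1	EA	1	other
3	rs4607103	ADAMTS9	C	T	0.638	0.608	0.783	1.00	0.97	1.04	8.6e-1	93114	0.99	0.95	1.04	6.74e-1	1.00	0.97	1.03	9.83e-1	7.51e-1	EU	1	IR
3	rs11708067	ADCY5	A	G	0.997	0.993	0.783	1.92	1.28	2.88	1.5e-3	93127	1.18	0.80	1.74	4.04e-1	1.49	1.13	1.97	5.19e-3	8.81e-2	EU	1	BC
3	rs1470579	IGF2BP2	C	A	0.257	0.250	0.308	1.11	1.07	1.16	1.1e-7	93108	1.15	1.11	1.19	2.90e-13	1.13	1.10	1.16	4.21e-19	2.17e-1	EU	1	BC
3	rs16861329	ST64GAL1	C	G	0.809	0.764	0.869	1.04	1.00	1.09	7.7e-2	93098	0.92	0.86	0.99	1.80e-2	1.01	0.97	1.04	7.69e-1	4.50e-3	SA	1	other
4	rs6815464	MAEA	C	G	0.578	0.555	0.985	1.08	1.04	1.12	3.4e-5	93082	1.13	1.10	1.16	1.57e-20	1.11	1.09	1.13	3.60e-22	3.64e-2	EA	1	other
4	rs10010131	WFS1	G	A	0.938	0.925	0.646	1.04	0.94	1.15	4.7e-1	45198	1.00	0.91	1.10	9.92e-1	1.02	0.95	1.09	6.18e-1	6.00e-1	EU	0	other
5	rs4457053	ZBED3	G	A	0.052	0.055	0.298	1.10	1.02	1.18	1.6e-2	93124	1.00	0.85	1.18	9.77e-1	1.08	1.01	1.16	2.90e-2	3.22e-1	EU	1	other
6	rs7754840	CDKAL1	C	G	0.409	0.394	0.318	1.21	1.17	1.26	3.6e-27	93130	1.18	1.14	1.22	2.94e-20	1.20	1.17	1.23	1.58e-45	2.65e-1	EU	1	BC
6	rs9470794	ZFAND3	C	T	0.316	0.339	0.116	1.02	0.98	1.05	4.1e-1	93111	1.12	1.08	1.16	2.06e-10	1.07	1.04	1.10	4.64e-7	2.39e-4	EA	1	other
7	rs2191349	DGKB	T	G	0.654	0.654	0.535	1.05	1.00	1.09	3.5e-2	74375	1.12	1.08	1.17	3.88e-9	1.09	1.06	1.12	8.69e-9	1.51e-2	EU	1	BC
7	rs864745	JAZF1	T	C	0.766	0.786	0.505	1.04	1.00	1.09	3.8e-2	93120	1.06	1.00	1.12	3.50e-2	1.05	1.01	1.09	4.65e-3	7.21e-1	EU	1	BC
7	rs4607517	GCK	A	G	0.211	0.195	0.207	1.01	0.97	1.06	5.5e-1	93113	1.03	0.97	1.09	3.97e-1	1.02	0.98	1.05	3.02e-1	6.84e-1	EU	1	BC
7	rs6467136	GCC1-PAX4	G	A	0.784	0.776	0.520	1.04	1.00	1.09	6.5e-2	93018	1.11	1.07	1.14	4.96e-11	1.08	1.05	1.11	1.58e-9	2.92e-2	EA	1	BC
7	rs972283	KLF14	G	A	0.710	0.697	0.540	1.04	1.00	1.08	4.2e-2	93126	0.99	0.93	1.06	8.52e-1	1.03	0.99	1.06	1.00e-1	2.22e-1	EU	1	IR
8	rs896854	TP53INP1	T	C	0.308	0.303	0.429	1.04	1.00	1.08	4.4e-2	93127	1.07	1.02	1.12	9.05e-3	1.05	1.02	1.08	9.15e-4	3.59e-1	EU	1	other
8	rs13266634	SLC30A8	C	T	0.538	0.529	0.758	1.10	1.06	1.13	3.4e-8	92535	1.10	1.07	1.14	4.04e-8	1.10	1.07	1.13	7.89e-15	7.78e-1	EU	1	BC
9	rs7041847	GLIS3	A	G	0.463	0.459	0.556	1.07	1.03	1.10	2.9e-4	92708	1.10	1.07	1.13	1.99e-14	1.09	1.06	1.11	2.86e-14	1.76e-1	EA	1	BC
9	rs17584499	PTPRD	T	C	0.101	0.091	0.202	1.00	0.95	1.06	9.3e-1	93019	1.09	1.00	1.19	4.00e-2	1.03	0.98	1.08	2.48e-1	1.13e-1	EA	1	other
9	rs10811661	CDKN2A/B	T	C	0.543	0.575	0.803	1.22	1.18	1.26	7.1e-28	93062	1.12	1.07	1.16	1.49e-7	1.17	1.14	1.21	1.23e-31	1.29e-3	EU	1	BC
9	rs13292136	TLE4/CHCHD9	C	T	0.909	0.923	0.934	1.08	1.01	1.14	2.2e-2	93118	0.99	0.92	1.07	8.84e-1	1.04	0.99	1.09	1.01e-1	1.06e-1	EU	1	other
10	rs10906115	CDC123	A	G	0.626	0.654	0.641	1.08	1.05	1.12	1.1e-5	93076	1.08	1.05	1.13	1.65e-5	1.08	1.06	1.11	7.11e-10	9.97e-1	EA	1	BC
10	rs1802295	VPS26A	T	C	0.109	0.096	0.338	1.03	0.97	1.08	3.8e-1	93048	1.01	0.94	1.09	8.00e-1	1.02	0.98	1.07	3.73e-1	7.89e-1	SA	1	other
10	rs1111875	HHEX/IDE	C	T	0.279	0.279	0.581	1.11	1.07	1.15	6.2e-8	93093	1.08	1.04	1.13	8.67e-5	1.10	1.07	1.13	3.47e-11	3.81e-1	EU	1	BC
10	rs7901695	TCF7L2	C	T	0.031	0.026	0.328	1.37	1.25	1.50	6.5e-12	92365	1.18	1.03	1.35	1.60e-2	1.31	1.21	1.41	1.91e-12	6.93e-2	EU	1	BC
10	rs10886471	GRK5	C	T	0.794	0.774	0.455	1.00	0.96	1.05	9.0e-1	84095	1.06	0.99	1.13	1.00e-1	1.02	0.98	1.06	2.97e-1	1.93e-1	EA	1	other
11	rs4752781	DUSP8/INS	T	A	0.833	0.813	0.465	0.99	0.95	1.04	7.3e-1	92932	1.04	0.98	1.10	1.70e-1	1.01	0.97	1.05	5.96e-1	2.27e-1	EU	0	other
11	rs2237892	KCNQ1	C	T	0.676	0.656	0.924	1.25	1.20	1.30	4.6e-30	92991	1.19	1.14	1.24	3.62e-18	1.22	1.19	1.26	8.65e-46	7.70e-2	EA	1	BC
11	rs5215	KCNJ11	C	T	0.386	0.387	0.384	1.07	1.04	1.11	7.8e-5	93120	1.10	1.06	1.14	2.28e-7	1.09	1.06	1.11	1.22e-10	3.69e-1	EU	1	BC
11	rs1552224	ARAP1	A	C	0.916	0.909	0.884	1.09	1.02	1.16	1.1e-2	93130	1.16	1.05	1.28	2.50e-3	1.11	1.05	1.17	1.85e-4	2.92e-1	EU	1	BC
11	rs10830963	MTNR1B	G	C	0.428	0.413	0.258	1.02	0.99	1.06	2.0e-1	93107	1.00	0.93	1.08	9.50e-1	1.02	0.99	1.05	2.40e-1	6.25e-1	EU	1	BC
12	rs1531343	HMGA2	C	G	0.098	0.118	0.106	1.05	0.99	1.11	9.9e-2	92189	1.06	0.99	1.14	1.05e-1	1.05	1.01	1.10	1.94e-2	7.83e-1	EU	1	IR
12	rs7961581	TSPAN8/LGR5	C	T	0.215	0.204	0.263	1.04	1.00	1.08	7.1e-2	93114	1.01	0.95	1.06	8.49e-1	1.03	0.99	1.06	1.31e-1	3.18e-1	EU	1	BC
13	rs1359790	SPRY2	G	A	0.716	0.685	0.732	1.06	1.02	1.10	2.5e-3	93096	1.05	1.01	1.10	1.02e-2	1.06	1.03	1.09	7.73e-5	7.66e-1	EA	1	BC
15	rs7403531	RASGRP1	T	C	0.350	0.315	0.278	1.03	0.99	1.07	9.3e-2	84075	1.08	1.02	1.13	3.80e-3	1.05	1.02	1.08	2.95e-3	2.40e-1	EA	1	other
15	rs7172432	VPS13C	A	G	0.618	0.627	0.591	1.07	1.03	1.11	4.3e-4	93095	1.11	1.07	1.15	2.86e-8	1.09	1.06	1.11	1.47e-10	1.62e-1	EA	1	BC
15	rs7178572	HMG20A	G	A	0.350	0.382	0.687	1.07	1.04	1.11	1.3e-4	93127	1.09	1.04	1.14	4.40e-4	1.08	1.05	1.11	1.43e-7	6.41e-1	SA	1	other
15	rs11634397	ZFAND6	G	A	0.088	0.077	0.657	1.02	0.96	1.09	4.5e-1	93115	1.00	0.90	1.11	9.90e-1	1.02	0.97	1.07	5.14e-1	6.95e-1	EU	1	other
15	rs2028299	AP3S2	C	A	0.202	0.185	0.258	1.06	1.02	1.11	6.0e-3	93115	1.08	1.02	1.14	1.30e-2	1.07	1.03	1.11	1.45e-4	6.72e-1	SA	1	other
15	rs8042680	PRC1	A	C	0.990	0.998	0.283	0.88	0.74	1.05	1.5e-1	93128	1.64	1.16	2.32	4.92e-3	1.00	0.85	1.16	9.61e-1	1.60e-3	EU	1	other
16	rs9939609	FTO	A	T	0.124	0.147	0.444	1.15	1.09	1.21	5.4e-8	93123	1.13	1.07	1.18	5.26e-7	1.14	1.10	1.18	1.76e-13	5.16e-1	EU	1	other
17	rs4523957	SRR	T	G	0.707	0.702	0.641	0.98	0.94	1.02	3.2e-1	90663	1.03	0.97	1.09	2.70e-1	0.99	0.96	1.03	7.61e-1	1.85e-1	EA	1	other
17	rs4430796	HNF1B	G	A	0.279	0.260	0.475	1.09	1.05	1.14	3.8e-6	93089	1.12	1.05	1.19	8.30e-4	1.10	1.07	1.14	8.48e-9	5.66e-1	EU	1	BC
18	rs12970134	MC4R	A	G	0.188	0.173	0.288	1.06	1.02	1.11	6.8e-3	93052	1.07	1.02	1.12	2.79e-3	1.07	1.03	1.10	5.76e-5	7.82e-1	EU	1	other
20	rs6017317	HNF4A	G	T	0.426	0.394	0.177	1.05	1.01	1.08	9.9e-3	93123	1.09	1.07	1.12	1.12e-11	1.08	1.06	1.10	2.37e-15	3.89e-2	EA	1	BC
23	rs5945326	DUSP9	A	G	0.605	0.607	0.785	1.11	1.07	1.15	4.1e-7	92979	NA	NA	NA	NA	NA	NA	NA	NA	NA	EU	0	other
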